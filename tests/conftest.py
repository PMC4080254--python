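import numpy as np
import pytest

from gataswitch import figure3_parameters, find_primed_state, steady_state_set


@pytest.fixture(scope="session")
def fig3():
    """The published tristable reference parameter set."""
    return figure3_parameters()


@pytest.fixture(scope="session")
def fig3_primed(fig3):
    primed = find_primed_state(fig3, seed=0)
    assert primed is not None
    return primed


@pytest.fixture(scope="session")
def fig3_attractors(fig3):
    sset = steady_state_set(fig3, seed=0)
    assert sset.primed is not None
    return sset


def random_unconstrained_parameters(rng: np.random.Generator):
    """A random parameter set NOT built by the constrained sampler.

    Magnitudes are drawn log-uniformly around the scales seen in the
    model (synthesis rates up to 1e5, binding terms around 1e-2..1e3),
    with the basal denominators kept away from zero.
    """
    from gataswitch import RateConstants

    def lu(lo, hi, n=1):
        return 10 ** rng.uniform(np.log10(lo), np.log10(hi), n)

    vals = {
        "a1": lu(1e-1, 1e5)[0],
        "b1": lu(1e-1, 1e5)[0],
        "c1": lu(1e-1, 1e5)[0],
        "a2": lu(1e-2, 1e4)[0],
        "a3": lu(1e-1, 1e1)[0],
        "b2": lu(1e-1, 1e1)[0],
        "c2": lu(1e-1, 1e1)[0],
        "k1": lu(1e-1, 1e1)[0],
        "k2": lu(1e-1, 1e1)[0],
        "k3": lu(1e-1, 1e1)[0],
    }
    for name in ("a4", "a5", "a6", "a7", "b3", "b4", "b5", "b6", "c3", "c4", "c5", "c6", "c7"):
        vals[name] = lu(1e-2, 1e3)[0]
    return RateConstants.from_dict(vals)
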