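import numpy as np
import pytest

from gataswitch import (
    analytic_steady_states,
    find_primed_state,
    generate_fixture_parameters,
    is_stable,
    jacobian,
    rhs,
    stability_conditions,
    steady_state_set,
    stability_margins,
)

from conftest import random_unconstrained_parameters


class TestAnalyticStates:
    def test_closed_form_coordinates(self, fig3):
        trivial, erythroid, myeloid = analytic_steady_states(fig3)
        assert trivial.state == pytest.approx([0.0, 0.0, 0.0])
        assert erythroid.x == pytest.approx(659.22, abs=0.01)
        assert erythroid.y == erythroid.z == 0.0
        assert myeloid.z == pytest.approx(252.38, abs=0.01)
        assert myeloid.x == myeloid.y == 0.0

    def test_residuals_vanish_for_sampled_sets(self):
        """The closed forms are exact roots for any valid parameter set."""
        for params in generate_fixture_parameters(seed=11, n=50):
            for st in analytic_steady_states(params):
                scale = max(1.0, np.max(np.abs(st.state)))
                assert np.max(np.abs(rhs(st.state, 0.0, params))) < 1e-10 * scale

    def test_negative_branch_flagged_nonphysical(self, fig3):
        params = fig3.replace(c1=0.0)  # PU.1 synthesis off: z2 < 0
        _, _, myeloid = analytic_steady_states(params)
        assert myeloid.z < 0
        assert not myeloid.physical
        assert not myeloid.stable

    def test_degenerate_denominator_rejected(self, fig3):
        with pytest.raises(ValueError):
            analytic_steady_states(fig3.replace(a4=0.0))


class TestStabilityConditions:
    def test_reference_set_fully_tristable(self, fig3):
        cond = stability_conditions(fig3)
        assert cond == (True, True, True)
        assert len(stability_margins(fig3)) == 7

    def test_all_synthesis_below_threshold(self, fig3):
        params = fig3.replace(a1=0.0, b1=0.0, c1=0.0)
        assert not stability_conditions(params).trivial_unstable

    @pytest.mark.parametrize("n_sets", [200])
    def test_agreement_with_eigenvalue_oracle(self, n_sets):
        """The closed-form inequalities must agree with the sign of the
        leading Jacobian eigenvalue at each non-negative analytic state."""
        rng = np.random.default_rng(2024)
        margin_band = 1e-9
        checked = 0
        for _ in range(n_sets):
            params = random_unconstrained_parameters(rng)
            m = stability_margins(params)
            cond = stability_conditions(params)
            trivial, erythroid, myeloid = analytic_steady_states(params)
            cases = [
                (trivial.state, not cond.trivial_unstable,
                 [m["trivial_x"], m["trivial_y"], m["trivial_z"]]),
            ]
            if erythroid.x >= 0:
                cases.append((erythroid.state, cond.erythroid_stable,
                              [m["erythroid_y"], m["erythroid_z"]]))
            if myeloid.z >= 0:
                cases.append((myeloid.state, cond.myeloid_stable,
                              [m["myeloid_x"], m["myeloid_y"]]))
            for state, predicted_stable, margins in cases:
                if min(abs(v) for v in margins) < margin_band:
                    continue
                oracle = is_stable(state, params, check_fixed_point=False)
                assert oracle == predicted_stable, (params.to_dict(), state)
                checked += 1
        assert checked >= n_sets  # every set contributes at least the origin


class TestJacobian:
    def test_decoupled_system_is_diagonal(self, fig3):
        """With all cross-interaction coefficients zeroed the Jacobian is
        diagonal and its entries are the per-gene linearized rates."""
        p = fig3.replace(a2=0, a5=0, a6=0, a7=0, b3=0, b5=0, b6=0, c3=0, c4=0, c6=0, c7=0)
        state = np.array([2.0, 3.0, 4.0])
        J = jacobian(state, p)
        off = J - np.diag(np.diag(J))
        assert np.allclose(off, 0.0)
        x, y, z = state
        assert J[0, 0] == pytest.approx(p.a1 * p.a3 / (p.a3 + p.a4 * x) ** 2 - p.k1)
        assert J[1, 1] == pytest.approx(p.b1 * p.b2 / (p.b2 + p.b4 * y) ** 2 - p.k2)
        assert J[2, 2] == pytest.approx(p.c1 * p.c2 / (p.c2 + p.c5 * z) ** 2 - p.k3)

    def test_matches_central_differences(self, fig3):
        rng = np.random.default_rng(5)
        for _ in range(5):
            s = rng.uniform(0.1, 50.0, 3)
            J = jacobian(s, fig3)
            h = 1e-6
            for j in range(3):
                e = np.zeros(3)
                e[j] = h * max(1.0, s[j])
                col = (rhs(s + e, 0, fig3) - rhs(s - e, 0, fig3)) / (2 * e[j])
                assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-7)

    def test_is_stable_classifies_reference_states(self, fig3, fig3_primed):
        _, erythroid, _ = analytic_steady_states(fig3)
        assert is_stable(erythroid.state, fig3)
        assert not is_stable(np.zeros(3), fig3)
        assert is_stable(fig3_primed.state, fig3)

    def test_is_stable_rejects_non_fixed_point(self, fig3):
        with pytest.raises(ValueError):
            is_stable(np.array([10.0, 10.0, 10.0]), fig3)


class TestPrimedState:
    def test_reference_primed_state(self, fig3):
        primed = find_primed_state(fig3, seed=0)
        assert primed is not None
        assert primed.stable
        assert np.all(primed.state > 0)
        # low co-expression: well below both committed attractors
        assert primed.x < 0.1 * 659.22
        assert primed.z < 0.1 * 252.38

    def test_deterministic_in_seed(self, fig3):
        a = find_primed_state(fig3, seed=123)
        b = find_primed_state(fig3, seed=123)
        assert a == b

    def test_absent_when_interior_root_impossible(self, fig3):
        """b1 < k2 b2 makes any y > 0 fixed point algebraically impossible."""
        params = fig3.replace(b1=1.0)
        assert find_primed_state(params, n_restarts=50, seed=0) is None

    def test_warm_start_finds_root_quickly(self, fig3, fig3_primed):
        primed = find_primed_state(
            fig3, n_restarts=0, initial_guesses=[fig3_primed.state * 1.01]
        )
        assert primed is not None
        assert np.allclose(primed.state, fig3_primed.state, rtol=1e-6)


def test_steady_state_set_reference(fig3):
    sset = steady_state_set(fig3, seed=0)
    assert sset.tristable
    labels = {sset.trivial.label, sset.erythroid.label, sset.myeloid.label, sset.primed.label}
    assert labels == {"trivial", "erythroid", "myeloid", "primed"}
    assert not sset.trivial.stable
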