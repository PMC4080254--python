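import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gataswitch import (
    GAConfig,
    GENOME_SLOTS,
    PenaltyScore,
    UnitGenome,
    check_switching,
    evaluate_penalty,
    find_primed_state,
    generate_fixture_parameters,
    run_ga,
    sample_parameters,
    stability_conditions,
    stability_margins,
)

# Frozen genome (k = 300) whose mapped parameter set is tristable and
# validated but cannot realize genetic switching; found by scanning the
# constrained sampler at a modest synthesis scale, where switching is
# known to fail.
NON_SWITCHING_GENOME = UnitGenome(
    np.array([0.107742, 0.916011, 0.230215, 0.037413, 0.554852,
              0.370923, 0.829789, 0.808251, 0.317139, 0.952898]),
    k=300.0,
)

FAST_CFG = GAConfig(population_size=8, n_generations=3, seed=0, robustness_n=5,
                    primed_restarts=10)


class TestSampler:
    def test_invasion_coefficient_worked_example(self):
        """b3 solves b1 < k2 (b2 + b3 x1) with slack 1/r: for r = 0.5,
        b1 = 18470.6419 and x1 = 659.22 this gives b3 ~ 40.42."""
        r = np.full(10, 0.5)
        r[GENOME_SLOTS.index("a1")] = 0.6931 * 1000 / 731.7409  # pins x1 at 659.22
        r[GENOME_SLOTS.index("b1")] = 1.3863 * 1000 / 18470.6419
        params = sample_parameters(UnitGenome(r))
        assert params.b3 == pytest.approx(40.42, abs=0.01)
        assert params.b1 == pytest.approx(18470.6419, rel=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=200, deadline=None)
    def test_every_genome_satisfies_all_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        genome = UnitGenome(rng.uniform(1e-6, 1 - 1e-6, len(GENOME_SLOTS)))
        params = sample_parameters(genome)
        assert stability_conditions(params) == (True, True, True)
        margins = stability_margins(params)
        assert len(margins) == 7
        assert all(v > 0 for v in margins.values())

    def test_boundary_approach_as_r_tends_to_one(self):
        """Raising the slack samples toward 1 drives the constrained
        parameters toward their inequality boundaries."""
        margins = []
        for r_val in (0.5, 0.9, 0.999):
            r = np.full(10, 0.5)
            for slot in ("a6", "b3", "b5", "c3"):
                r[GENOME_SLOTS.index(slot)] = r_val
            m = stability_margins(sample_parameters(UnitGenome(r)))
            margins.append(m["erythroid_y"])
        assert margins[0] > margins[1] > margins[2] > 0

    def test_genome_validation(self):
        with pytest.raises(ValueError):
            UnitGenome(np.array([0.5, 1.0, 0.5]))
        with pytest.raises(ValueError):
            UnitGenome(np.full(10, 0.5), k=0.0)
        with pytest.raises(ValueError):
            sample_parameters(UnitGenome(np.full(3, 0.5)))


class TestCheckSwitching:
    def test_reference_set_switches_both_ways(self, fig3, fig3_primed):
        assert check_switching(fig3, primed=fig3_primed)

    def test_no_myeloid_attractor_fails(self, fig3, fig3_primed):
        """With PU.1 synthesis off the myeloid attractor does not exist,
        so the knockdown branch cannot succeed."""
        params = fig3.replace(c1=0.0)
        assert not check_switching(params, primed=fig3_primed)

    def test_independent_of_output_resolution(self, fig3, fig3_primed):
        a = check_switching(fig3, primed=fig3_primed)
        b = check_switching(fig3, primed=fig3_primed, tol=0.01)
        assert a == b


class TestPenalty:
    def test_score_invariants_enforced(self):
        with pytest.raises(ValueError):
            PenaltyScore(value=3.5, stage_failed="O1")
        with pytest.raises(ValueError):
            PenaltyScore(value=1.5, stage_failed="none", robustness_fraction=1.5)
        ok = PenaltyScore(value=0.25, stage_failed="none", robustness_fraction=0.25)
        assert ok.value == 0.25

    def test_penalty_ladder(self, fig3):
        """Constructed failures score exactly 4 (no primed root),
        3 (validation failure) and 2 (no switching)."""
        cfg = GAConfig()
        no_primed = fig3.replace(b1=1.0)
        assert evaluate_penalty(no_primed, cfg).value == 4.0

        unstable_erythroid = fig3.replace(b3=0.1)
        assert evaluate_penalty(unstable_erythroid, cfg).value == 3.0

        non_switching = sample_parameters(NON_SWITCHING_GENOME)
        assert evaluate_penalty(non_switching, cfg).value == 2.0

    def test_reference_set_reaches_robustness_stage(self, fig3):
        cfg = GAConfig()
        score = evaluate_penalty(fig3, cfg)
        assert score.stage_failed == "none"
        assert 0.0 <= score.value <= 1.0
        assert score.value == score.robustness_fraction

    def test_no_score_between_one_and_two(self, fig3):
        """Penalty values live in {4} u {3} u {2} u [0, 1]."""
        cfg = GAConfig(robustness_n=10)
        for params in [fig3, fig3.replace(b1=1.0), fig3.replace(b3=0.1),
                       sample_parameters(NON_SWITCHING_GENOME)]:
            v = evaluate_penalty(params, cfg).value
            assert v in (4.0, 3.0, 2.0) or 0.0 <= v <= 1.0
            assert not (1.0 < v < 2.0)


class TestRunGa:
    def test_deterministic_in_seed(self):
        a = run_ga(FAST_CFG)
        b = run_ga(FAST_CFG)
        assert a.history.equals(b.history)
        assert a.best_params == b.best_params

    def test_single_generation_returns_initial_best(self):
        cfg = GAConfig(population_size=6, n_generations=1, seed=3, robustness_n=5,
                       primed_restarts=10)
        res = run_ga(cfg)
        assert len(res.history) == 1
        assert res.best_score.value == res.history["best"].iloc[0]

    def test_best_history_non_increasing(self):
        res = run_ga(FAST_CFG)
        best = res.history["best"].to_numpy()
        assert np.all(np.diff(best) <= 0)


class TestFixtureGenerator:
    def test_reproducible_and_constraint_satisfying(self):
        a = generate_fixture_parameters(seed=9, n=5)
        b = generate_fixture_parameters(seed=9, n=5)
        assert a == b
        for params in a:
            assert stability_conditions(params) == (True, True, True)

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture_parameters(seed=0, n=0)
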