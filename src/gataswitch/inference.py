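"""Staged multi-objective parameter inference for the three-gene network.

Ten rate constants (a1, a2, a5, a6, b1, b3, b5, c1, c3, c4) are not fixed
by experimental data.  They are searched with a real-coded genetic
algorithm whose genome lives in the open unit cube: each candidate is a
vector of U(0,1) samples, and the map from genome to rate constants is
built so that the seven tristability inequalities hold *by construction*
(the synthesis rates are scaled by a large factor ``k`` to clear the
trivial-state thresholds, and the invasion coefficients b3, c3, a6, b5
are solved from the inequalities with a random slack factor).

Candidates are scored by a staged penalty:

* 4 -- no interior (primed) fixed point was found,
* 3 -- a steady state failed perturbation-return validation,
* 2 -- the model cannot realize genetic switching (GATA switch to the
  erythroid state and GATA-2 knockdown to the myeloid state),
* otherwise the fraction in [0, 1] of multiplicatively perturbed
  parameter sets that do NOT maintain tristability (smaller = more
  robust).

The same perturbation samples U_jk are shared across candidates so the
robustness stage compares like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import relative_distance, simulate_ode, validate_steady_state_by_perturbation
from .parameters import RateConstants, SwitchSchedule
from .steady_states import (
    analytic_steady_states,
    find_primed_state,
    steady_state_set,
)

__all__ = [
    "GENOME_SLOTS",
    "FIXED_FROM_DATA",
    "UnitGenome",
    "PenaltyScore",
    "GAConfig",
    "GAResult",
    "sample_parameters",
    "check_switching",
    "evaluate_penalty",
    "run_ga",
    "generate_fixture_parameters",
]

#: Genome slot order: which free rate constant each U(0,1) sample feeds.
#: Slots 0-3 are the scaled synthesis rates and the direct samples of the
#: GATA-1 equation, then GATA-2, then PU.1.
GENOME_SLOTS: tuple[str, ...] = ("a1", "a2", "a5", "a6", "b1", "b3", "b5", "c1", "c3", "c4")

#: Constants fixed before inference: the normalization a3 = b2 = c2 = 1,
#: the binding coefficients anchored to dissociation constants and the
#: shared-site equalities (b6 = a7, c7 = c6), and the degradation rates
#: from measured half-lives.
FIXED_FROM_DATA: dict[str, float] = {
    "a3": 1.0,
    "b2": 1.0,
    "c2": 1.0,
    "a4": 1.6,
    "a7": 53.0,
    "b4": 942.1939,
    "b6": 53.0,
    "c5": 170.0,
    "c6": 1700.0,
    "c7": 1700.0,
    "k1": 0.6931,
    "k2": 1.3863,
    "k3": 0.2888,
}

_VALIDATION_SCHEDULE = SwitchSchedule(k2_star=20.0, t_on=500.0, t_off=1500.0, mu=1.0)


@dataclass(frozen=True)
class UnitGenome:
    """A candidate in genome space: U(0,1) samples plus the synthesis scale k."""

    r: np.ndarray
    k: float = 1000.0

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1:
            raise ValueError("genome must be a 1-D vector")
        if np.any(r <= 0.0) or np.any(r >= 1.0):
            raise ValueError("all genome samples must lie in the open interval (0, 1)")
        if not self.k > 0:
            raise ValueError("synthesis scale k must be positive")
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class PenaltyScore:
    """Staged penalty: 4 / 3 / 2 for stage failures, else robustness in [0, 1]."""

    value: float
    stage_failed: str  # one of {"O1", "O2", "O3", "none"}
    robustness_fraction: float | None = None

    def __post_init__(self) -> None:
        expected = {"O1": 4.0, "O2": 3.0, "O3": 2.0}
        if self.stage_failed in expected:
            if self.value != expected[self.stage_failed]:
                raise ValueError(
                    f"stage {self.stage_failed} must score {expected[self.stage_failed]}"
                )
        elif self.stage_failed == "none":
            if not (0.0 <= self.value <= 1.0):
                raise ValueError("robustness-stage score must lie in [0, 1]")
            if self.robustness_fraction != self.value:
                raise ValueError("robustness-stage score must equal robustness_fraction")
        else:
            raise ValueError(f"unknown stage {self.stage_failed!r}")


@dataclass(frozen=True)
class GAConfig:
    """Configuration of the staged-penalty genetic algorithm.

    The desk-scale defaults (population 50, 10 generations, 50 robustness
    sets) keep a run to a couple of minutes; the study-scale settings are
    population 1000, 100 generations and 1000 robustness sets with
    sigma = 0.5.
    """

    population_size: int = 50
    n_generations: int = 10
    seed: int = 0
    k: float = 1000.0
    crossover_prob: float = 0.8
    mutation_sd: float = 0.1
    tournament_size: int = 3
    robustness_n: int = 50
    robustness_sigma: float = 0.5
    elitism: int = 1
    primed_restarts: int = 30

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.robustness_sigma <= 0:
            raise ValueError("robustness_sigma must be > 0")


@dataclass(frozen=True)
class GAResult:
    best_params: RateConstants
    best_score: PenaltyScore
    best_genome: UnitGenome
    history: pd.DataFrame = field(repr=False)


def sample_parameters(
    genome: UnitGenome, fixed: dict[str, float] | None = None
) -> RateConstants:
    """Map a unit-cube genome to a constraint-satisfying parameter set.

    With r the genome samples (in :data:`GENOME_SLOTS` order) and k the
    synthesis scale:

    * a1 = (k1 a3 / r) k,  b1 = (k2 b2 / r) k,  c1 = (k3 c2 / r) k force
      the trivial state to be unstable in every direction (each synthesis
      rate exceeds its threshold by the factor k / r > 1);
    * b3 = (b1/k2 - b2) / (r x1) and c3 = (c1/k3 - c2) / (r x1) force the
      erythroid state to be non-invadable; a6 = (a1/k1 - a3) / (r z2) and
      b5 = (b1/k2 - b2) / (r z2) do the same for the myeloid state, where
      x1 and z2 are the closed-form attractor coordinates;
    * a2 = r k, a5 = r k and c4 = r k are read off the genome and scaled
      by the synthesis factor (the published estimate pins a5 and c4 at
      O(k), so the occupancy competition terms share the scale of the
      synthesis rates).

    The output therefore satisfies all seven tristability inequalities for
    every genome.
    """
    fx = dict(FIXED_FROM_DATA)
    if fixed:
        fx.update(fixed)
    r = genome.r
    if r.size != len(GENOME_SLOTS):
        raise ValueError(f"genome must have {len(GENOME_SLOTS)} slots, got {r.size}")
    k = genome.k
    s = dict(zip(GENOME_SLOTS, r))

    k1, k2, k3 = fx["k1"], fx["k2"], fx["k3"]
    a3, b2, c2 = fx["a3"], fx["b2"], fx["c2"]

    a1 = (k1 * a3 / s["a1"]) * k
    b1 = (k2 * b2 / s["b1"]) * k
    c1 = (k3 * c2 / s["c1"]) * k
    x1 = (a1 - k1 * a3) / (k1 * fx["a4"])
    z2 = (c1 - k3 * c2) / (k3 * fx["c5"])

    out = dict(fx)
    out.update(
        a1=a1,
        a2=s["a2"] * k,
        a5=s["a5"] * k,
        a6=(a1 / k1 - a3) / (s["a6"] * z2),
        b1=b1,
        b3=(b1 / k2 - b2) / (s["b3"] * x1),
        b5=(b1 / k2 - b2) / (s["b5"] * z2),
        c1=c1,
        c3=(c1 / k3 - c2) / (s["c3"] * x1),
        c4=s["c4"] * k,
    )
    return RateConstants.from_dict(out)


def check_switching(
    params: RateConstants,
    primed=None,
    schedule: SwitchSchedule = _VALIDATION_SCHEDULE,
    t_end: float = 2000.0,
    tol: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> bool:
    """Can the model switch out of the primed state in both directions?

    Simulates from the primed state under the validation window
    (k2* = 20 on [500, 1500]) twice: with mu = 1 (GATA switch) the run
    must end within ``tol`` relative distance of the erythroid attractor,
    and with mu = 0 (GATA-2 knockdown) within ``tol`` of the myeloid
    attractor.
    """
    if primed is None:
        primed = find_primed_state(params)
    if primed is None:
        raise ValueError("check_switching requires a primed state")
    init = primed.state if hasattr(primed, "state") else np.asarray(primed, dtype=float)
    _, erythroid, myeloid = analytic_steady_states(params)

    from .dynamics import IntegrationError

    for mu, target in ((1.0, erythroid.state), (0.0, myeloid.state)):
        try:
            traj = simulate_ode(
                params, schedule.with_mu(mu), init, t_end, rtol=rtol, atol=atol, n_points=21
            )
        except IntegrationError:
            return False
        if relative_distance(traj.endpoint, target) > tol:
            return False
    return True


def evaluate_penalty(
    params: RateConstants,
    cfg: GAConfig,
    u_samples: np.ndarray | None = None,
    validation_trials: int = 3,
) -> PenaltyScore:
    """Staged penalty of one parameter set.

    Stage O1: locate the primed root (penalty 4 on failure).  Stage O2:
    perturbation-return validation of the erythroid, myeloid and primed
    states (penalty 3).  Stage O3: genetic-switching check (penalty 2).
    Stage O4: fraction of ``cfg.robustness_n`` multiplicatively perturbed
    parameter sets that do not maintain tristability.  Pass ``u_samples``
    (shape (23, robustness_n)) to share the perturbation samples across
    candidates.
    """
    from .robustness import PerturbationConfig, tristability_fraction

    primed = find_primed_state(params, n_restarts=cfg.primed_restarts, seed=cfg.seed)
    if primed is None:
        return PenaltyScore(value=4.0, stage_failed="O1")

    _, erythroid, myeloid = analytic_steady_states(params)
    for st in (erythroid, myeloid, primed):
        ok = st.physical and validate_steady_state_by_perturbation(
            params, st.state, strength=0.05, n_trials=validation_trials,
            seed=cfg.seed, rtol=1e-6, atol=1e-8,
        )
        if not ok:
            return PenaltyScore(value=3.0, stage_failed="O2")

    if not check_switching(params, primed=primed, rtol=1e-6, atol=1e-8):
        return PenaltyScore(value=2.0, stage_failed="O3")

    pc = PerturbationConfig(
        sigma=cfg.robustness_sigma, n_sets=cfg.robustness_n, seed=cfg.seed
    )
    frac_keep = tristability_fraction(
        params, pc, u_samples=u_samples, primed_guess=primed.state
    )
    frac_fail = 1.0 - frac_keep
    return PenaltyScore(value=frac_fail, stage_failed="none", robustness_fraction=frac_fail)


def _tournament(rng, fitness: np.ndarray, size: int) -> int:
    contenders = rng.integers(0, fitness.size, size=size)
    return int(contenders[np.argmin(fitness[contenders])])


_CLIP_LO, _CLIP_HI = 1e-6, 1.0 - 1e-6


def run_ga(cfg: GAConfig, fixed: dict[str, float] | None = None) -> GAResult:
    """Minimize the staged penalty over genome space.

    Real-coded GA on the unit cube: tournament selection, uniform
    crossover, Gaussian mutation of the U(0,1) samples (mutation acts on
    the genome, never on the mapped rate constants), elitism, and a
    per-genome evaluation cache.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_slots = len(GENOME_SLOTS)
    # shared robustness samples: one draw for the whole run
    u_samples = np.random.default_rng((cfg.seed, 777)).uniform(
        size=(len(RateConstants.__dataclass_fields__), cfg.robustness_n)
    )

    pop = rng.uniform(_CLIP_LO, _CLIP_HI, size=(cfg.population_size, n_slots))
    cache: dict[tuple, PenaltyScore] = {}

    def score(genome_row: np.ndarray) -> PenaltyScore:
        key = tuple(np.round(genome_row, 12))
        if key not in cache:
            params = sample_parameters(UnitGenome(genome_row, k=cfg.k), fixed)
            cache[key] = evaluate_penalty(params, cfg, u_samples=u_samples)
        return cache[key]

    history = []
    best_row, best_score = None, None
    for gen in range(cfg.n_generations):
        scores = [score(row) for row in pop]
        fitness = np.array([s.value for s in scores])
        order = np.argsort(fitness, kind="stable")
        if best_score is None or fitness[order[0]] < best_score.value:
            best_row = pop[order[0]].copy()
            best_score = scores[order[0]]
        history.append(
            {"generation": gen, "best": float(best_score.value), "mean": float(fitness.mean())}
        )
        if gen == cfg.n_generations - 1:
            break

        elite = [best_row.copy() for _ in range(cfg.elitism)]
        children = []
        while len(children) < cfg.population_size - len(elite):
            i = _tournament(rng, fitness, cfg.tournament_size)
            j = _tournament(rng, fitness, cfg.tournament_size)
            child = pop[i].copy()
            if rng.uniform() < cfg.crossover_prob:
                mask = rng.uniform(size=n_slots) < 0.5
                child[mask] = pop[j][mask]
            child = child + rng.normal(0.0, cfg.mutation_sd, size=n_slots)
            children.append(np.clip(child, _CLIP_LO, _CLIP_HI))
        pop = np.vstack([elite, *children[: cfg.population_size - len(elite)]])

    assert best_row is not None and best_score is not None
    best_genome = UnitGenome(best_row, k=cfg.k)
    return GAResult(
        best_params=sample_parameters(best_genome, fixed),
        best_score=best_score,
        best_genome=best_genome,
        history=pd.DataFrame(history),
    )


def generate_fixture_parameters(seed: int, n: int, k: float = 1000.0) -> list[RateConstants]:
    """Random constraint-satisfying parameter sets (reproducible from seed).

    Each set is produced by :func:`sample_parameters` from a fresh random
    genome, so every set satisfies the seven tristability inequalities by
    construction.  Intended as a test-data generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        sample_parameters(UnitGenome(rng.uniform(_CLIP_LO, _CLIP_HI, len(GENOME_SLOTS)), k=k))
        for _ in range(n)
    ]
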