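"""Discrete Poisson tau-leap simulation of the three-gene network.

The stochastic model advances integer copy numbers (X, Y, Z) of GATA-1,
GATA-2 and PU.1 over a fixed step ``tau`` by drawing independent Poisson
event counts for seven reaction channels: three Shea--Ackers synthesis
channels, three degradation channels (the GATA-2 channel carries the
combined mean ``(k2 + k2*(t)) Y tau`` during the switch window), and the
GATA-switch transfer channel ``mu k2*(t) Y tau`` feeding GATA-1.

Copy numbers and the concentration units of the deterministic model are
linked by the scale ``omega`` (molecules per concentration unit):
propensities are evaluated on concentrations ``counts / omega`` and
synthesis rates are multiplied back by ``omega``.  At the default
``omega = 1000`` (roughly molecules per nM for a ~1.7 pL nucleus) the
committed lineages hold thousands of molecules while the deciding species
pass through near-zero copy numbers inside the switch window, which is
where intrinsic noise renders the lineage outcome multimodal.

Ensembles are stepped in lock-step across runs (vectorized over the run
axis) from one dedicated RNG stream per ensemble; single trajectories use
a per-run substream derived from (seed, run_index) so any individual run
can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .parameters import RateConstants, SwitchSchedule, schedule_preset
from .steady_states import SteadyStateSet

__all__ = [
    "StochasticConfig",
    "tau_leap_step",
    "simulate_stochastic",
    "ensemble_endpoints",
    "ensemble_mean_trajectory",
    "classify_endpoint",
    "LineageFractions",
    "lineage_fractions",
]


@dataclass(frozen=True)
class StochasticConfig:
    """Tau-leap settings: stepsize, copy-number scale, horizon, ensemble."""

    tau: float = 0.01
    omega: float = 1000.0
    t_end: float | None = None  # defaults to schedule.t_off + 300
    n_runs: int = 200
    seed: int = 0
    schedule: SwitchSchedule = field(default_factory=lambda: schedule_preset("stochastic"))
    save_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def horizon(self) -> float:
        """Read-out time: explicit t_end, or 300 h after the window closes."""
        return self.t_end if self.t_end is not None else self.schedule.t_off + 300.0


def _propensity_means(S: np.ndarray, t: float, params: RateConstants,
                      schedule: SwitchSchedule, tau: float, omega: float):
    """Poisson means of the seven channels for states ``S`` (shape (..., 3))."""
    p = params
    k2s = schedule.value(t) if schedule is not None else 0.0
    mu = schedule.mu if schedule is not None else 0.0
    X, Y, Z = S[..., 0], S[..., 1], S[..., 2]
    x, y, z = X / omega, Y / omega, Z / omega
    with np.errstate(invalid="ignore"):
        sx = np.where(
            (den := p.a3 + p.a4 * x + p.a5 * y + p.a6 * z + p.a7 * x * z) > 0,
            (p.a1 * x + p.a2 * y) / np.where(den > 0, den, 1.0), 0.0,
        )
        sy = np.where(
            (den2 := p.b2 + p.b3 * x + p.b4 * y + p.b5 * z + p.b6 * y * z) > 0,
            p.b1 * y / np.where(den2 > 0, den2, 1.0), 0.0,
        )
        sz = np.where(
            (den3 := p.c2 + p.c3 * x + p.c4 * y + p.c5 * z + p.c6 * x * z + p.c7 * y * z) > 0,
            p.c1 * z / np.where(den3 > 0, den3, 1.0), 0.0,
        )
    return (
        omega * sx * tau,          # GATA-1 synthesis
        omega * sy * tau,          # GATA-2 synthesis
        omega * sz * tau,          # PU.1 synthesis
        p.k1 * X * tau,            # GATA-1 degradation
        (p.k2 + k2s) * Y * tau,    # GATA-2 degradation incl. switch removal
        p.k3 * Z * tau,            # PU.1 degradation
        mu * k2s * Y * tau,        # GATA-switch transfer into GATA-1
    )


def tau_leap_step(
    state,
    t: float,
    params: RateConstants,
    schedule: SwitchSchedule,
    tau: float,
    rng: np.random.Generator,
    omega: float = 1.0,
) -> np.ndarray:
    """One Poisson leap from integer counts ``state`` at time ``t``.

    Draws the seven channel counts in a fixed order (synthesis x, y, z;
    degradation x, y, z; transfer), applies the increments and clamps each
    coordinate at zero (independent Poisson draws can overshoot the
    available molecules).
    """
    S = np.asarray(state, dtype=float)
    px, py, pz, dx, dy, dz, tr = _propensity_means(S, t, params, schedule, tau, omega)
    inc_x = rng.poisson(px) - rng.poisson(dx)
    inc_y = rng.poisson(py) - rng.poisson(dy)
    inc_z = rng.poisson(pz) - rng.poisson(dz)
    inc_x = inc_x + rng.poisson(tr)
    out = np.array([S[0] + inc_x, S[1] + inc_y, S[2] + inc_z], dtype=float)
    return np.maximum(out, 0.0)


def simulate_stochastic(
    params: RateConstants,
    cfg: StochasticConfig,
    init,
    run_index: int = 0,
) -> Trajectory:
    """One tau-leap trajectory, reproducible from (cfg.seed, run_index).

    States (integer counts) are recorded every ``cfg.save_interval`` hours.
    """
    rng = np.random.default_rng([cfg.seed, run_index])
    S = np.asarray(init, dtype=float).copy()
    if S.shape != (3,) or np.any(S < 0):
        raise ValueError("init must be a non-negative (X, Y, Z) count triple")
    t_end = cfg.horizon
    n_steps = int(round(t_end / cfg.tau))
    record_every = max(1, int(round(cfg.save_interval / cfg.tau)))

    times = [0.0]
    states = [S.copy()]
    for i in range(n_steps):
        t = i * cfg.tau
        S = tau_leap_step(S, t, params, cfg.schedule, cfg.tau, rng, omega=cfg.omega)
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            times.append((i + 1) * cfg.tau)
            states.append(S.copy())
    return Trajectory(np.array(times), np.vstack(states), schedule=cfg.schedule)


def _ensemble_step(S, t, params, schedule, tau, omega, rng, clamp_counter):
    px, py, pz, dx, dy, dz, tr = _propensity_means(S, t, params, schedule, tau, omega)
    new = np.empty_like(S)
    new[:, 0] = S[:, 0] + rng.poisson(px) - rng.poisson(dx) + rng.poisson(tr)
    new[:, 1] = S[:, 1] + rng.poisson(py) - rng.poisson(dy)
    new[:, 2] = S[:, 2] + rng.poisson(pz) - rng.poisson(dz)
    if clamp_counter is not None:
        clamp_counter[0] += int(np.sum(new < 0))
        clamp_counter[1] += new.size
    return np.maximum(new, 0.0)


def ensemble_endpoints(
    params: RateConstants,
    cfg: StochasticConfig,
    init,
    stream: int = 0,
    return_clamp_fraction: bool = False,
):
    """Final counts of ``cfg.n_runs`` tau-leap runs, stepped in lock-step.

    One RNG stream (cfg.seed, "ensemble", stream) drives the whole
    ensemble; results are reproducible from the seed and independent of
    any other ensemble drawn with a different ``stream`` index.
    """
    rng = np.random.default_rng([cfg.seed, 10_000 + stream])
    S = np.tile(np.asarray(init, dtype=float), (cfg.n_runs, 1))
    n_steps = int(round(cfg.horizon / cfg.tau))
    clamp = [0, 0] if return_clamp_fraction else None
    for i in range(n_steps):
        S = _ensemble_step(S, i * cfg.tau, params, cfg.schedule, cfg.tau, cfg.omega, rng, clamp)
    if return_clamp_fraction:
        return S, clamp[0] / max(clamp[1], 1)
    return S


def ensemble_mean_trajectory(
    params: RateConstants,
    cfg: StochasticConfig,
    init,
    stream: int = 0,
) -> Trajectory:
    """Ensemble-mean concentration path (counts / omega), for comparison
    with the deterministic solution."""
    rng = np.random.default_rng([cfg.seed, 10_000 + stream])
    S = np.tile(np.asarray(init, dtype=float), (cfg.n_runs, 1))
    n_steps = int(round(cfg.horizon / cfg.tau))
    record_every = max(1, int(round(cfg.save_interval / cfg.tau)))
    times = [0.0]
    means = [S.mean(axis=0) / cfg.omega]
    for i in range(n_steps):
        S = _ensemble_step(S, i * cfg.tau, params, cfg.schedule, cfg.tau, cfg.omega, rng, None)
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            times.append((i + 1) * cfg.tau)
            means.append(S.mean(axis=0) / cfg.omega)
    return Trajectory(np.array(times), np.vstack(means), schedule=cfg.schedule)


_CLASS_ORDER = ("erythroid", "myeloid", "primed")


def classify_endpoint(state, attractors: SteadyStateSet, omega: float = 1.0):
    """Nearest-attractor lineage label(s) on log1p-scaled counts.

    Distances are Euclidean between ``log1p(counts)`` and
    ``log1p(omega * attractor)``; the log transform makes the comparison
    relative across the orders of magnitude separating the lineages.
    Ties break deterministically in the order erythroid > myeloid >
    primed.  Accepts a single (X, Y, Z) triple or an (n, 3) array.
    """
    if attractors.primed is None:
        raise ValueError("endpoint classification requires a primed attractor")
    S = np.atleast_2d(np.asarray(state, dtype=float))
    refs = np.stack(
        [
            np.log1p(omega * attractors.erythroid.state),
            np.log1p(omega * attractors.myeloid.state),
            np.log1p(omega * attractors.primed.state),
        ]
    )
    d = np.linalg.norm(np.log1p(S)[:, None, :] - refs[None, :, :], axis=2)
    labels = np.array(_CLASS_ORDER)[np.argmin(d, axis=1)]
    return labels[0] if np.asarray(state).ndim == 1 else labels


@dataclass(frozen=True)
class LineageFractions:
    """Per-mu lineage outcome fractions of a tau-leap ensemble sweep."""

    mu_grid: np.ndarray
    fractions: np.ndarray  # (n_mu, 3) columns: erythroid, primed, myeloid
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu": self.mu_grid,
                "frac_erythroid": self.fractions[:, 0],
                "frac_primed": self.fractions[:, 1],
                "frac_myeloid": self.fractions[:, 2],
                "n_runs": self.n_runs,
            }
        )


def lineage_fractions(
    params: RateConstants,
    cfg: StochasticConfig,
    mu_grid,
    attractors: SteadyStateSet | None = None,
    init=None,
) -> LineageFractions:
    """Lineage-outcome fractions across a sweep of the GATA-1 availability mu.

    For each mu the ensemble is run to the read-out time (300 h past the
    switch window by default) and endpoints are classified against the
    deterministic attractors.  The initial condition defaults to the
    deterministic primed state scaled to counts and rounded.  Fractions
    are exact run counts over ``cfg.n_runs`` and sum to 1.
    """
    from .steady_states import steady_state_set

    if attractors is None:
        attractors = steady_state_set(params, seed=cfg.seed)
    if attractors.primed is None:
        raise ValueError("mu sweep requires a tristable parameter set (primed state)")
    if init is None:
        init = np.round(cfg.omega * attractors.primed.state)

    mu_grid = np.asarray(mu_grid, dtype=float)
    frac = np.zeros((mu_grid.size, 3))
    for i, mu in enumerate(mu_grid):
        mu_cfg = StochasticConfig(
            tau=cfg.tau,
            omega=cfg.omega,
            t_end=cfg.t_end,
            n_runs=cfg.n_runs,
            seed=cfg.seed,
            schedule=cfg.schedule.with_mu(float(mu)),
            save_interval=cfg.save_interval,
        )
        ends = ensemble_endpoints(params, mu_cfg, init, stream=i)
        labels = classify_endpoint(ends, attractors, omega=cfg.omega)
        frac[i, 0] = np.sum(labels == "erythroid") / cfg.n_runs
        frac[i, 1] = np.sum(labels == "primed") / cfg.n_runs
        frac[i, 2] = np.sum(labels == "myeloid") / cfg.n_runs
    return LineageFractions(mu_grid=mu_grid, fractions=frac, n_runs=cfg.n_runs)
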