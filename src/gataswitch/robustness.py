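"""Robustness to parameter perturbation, and single-parameter bifurcation scans.

Robustness of a tristable parameter set is measured by multiplicatively
perturbing all 23 rate constants, ``a_jk = a_j (1 + sigma (U_jk - 0.5))``
with ``U_jk ~ U(0,1)``, and asking what fraction of the perturbed sets
still maintain three stable steady states.  Bifurcation scans re-evaluate
tristability on a grid of one rate constant from 0 to twice its estimate,
holding everything else fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import PARAM_NAMES, RateConstants
from .steady_states import (
    analytic_steady_states,
    find_primed_state,
    stability_conditions,
)

__all__ = [
    "PerturbationConfig",
    "perturb_parameters",
    "is_tristable",
    "tristability_fraction",
    "BifurcationScan",
    "bifurcation_scan",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Perturbation strength sigma, ensemble size, and RNG seed."""

    sigma: float = 0.5
    n_sets: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


def draw_u_samples(cfg: PerturbationConfig) -> np.ndarray:
    """The U_jk ~ U(0,1) sample matrix, shape (23, n_sets)."""
    rng = np.random.default_rng(cfg.seed)
    return rng.uniform(size=(len(PARAM_NAMES), cfg.n_sets))


def perturb_parameters(
    params: RateConstants,
    cfg: PerturbationConfig,
    u_samples: np.ndarray | None = None,
) -> list[RateConstants]:
    """Multiplicatively perturbed copies: a_jk = a_j (1 + sigma (U_jk - 0.5)).

    With sigma <= 2 every output is non-negative.  Pass ``u_samples`` to
    reuse one U_jk draw across different base parameter sets (the shared
    samples make robustness comparisons unbiased).
    """
    u = draw_u_samples(cfg) if u_samples is None else np.asarray(u_samples, dtype=float)
    if u.shape[0] != len(PARAM_NAMES):
        raise ValueError(f"u_samples must have {len(PARAM_NAMES)} rows")
    base = params.to_array()[:, None]
    perturbed = base * (1.0 + cfg.sigma * (u[:, : cfg.n_sets] - 0.5))
    return [RateConstants.from_array(col) for col in perturbed.T]


def is_tristable(
    params: RateConstants,
    primed_guess=None,
    n_restarts: int = 20,
    seed: int = 0,
) -> bool:
    """Does the set maintain three stable steady states?

    Operationalized as: the closed-form erythroid and myeloid states have
    non-negative coordinates and pass their stability inequalities, AND a
    strictly positive, eigenvalue-stable primed root exists.  The primed
    search warm-starts from ``primed_guess`` (typically the unperturbed
    primed state) and falls back to random restarts.
    """
    try:
        cond = stability_conditions(params)
        _, erythroid, myeloid = analytic_steady_states(params)
    except (ValueError, ZeroDivisionError):
        return False
    if not (cond.erythroid_stable and erythroid.physical):
        return False
    if not (cond.myeloid_stable and myeloid.physical):
        return False
    guesses = [primed_guess] if primed_guess is not None else None
    primed = find_primed_state(
        params, n_restarts=n_restarts, seed=seed, initial_guesses=guesses
    )
    return primed is not None and primed.stable


def tristability_fraction(
    params: RateConstants,
    cfg: PerturbationConfig,
    u_samples: np.ndarray | None = None,
    primed_guess=None,
    n_restarts: int = 20,
) -> float:
    """Fraction of perturbed parameter sets that maintain tristability.

    Reproducible from ``cfg.seed`` and invariant to the order of the
    perturbed sets.  When ``primed_guess`` is omitted it is taken from the
    unperturbed set's own primed state.
    """
    if primed_guess is None:
        primed = find_primed_state(params, seed=cfg.seed)
        primed_guess = primed.state if primed is not None else None
    sets = perturb_parameters(params, cfg, u_samples=u_samples)
    hits = sum(
        is_tristable(p, primed_guess=primed_guess, n_restarts=n_restarts, seed=cfg.seed)
        for p in sets
    )
    return hits / len(sets)


@dataclass(frozen=True)
class BifurcationScan:
    """Grid re-evaluation of tristability along one rate constant."""

    parameter_name: str
    grid: np.ndarray
    tristable: np.ndarray  # bool per grid value
    erythroid_x: np.ndarray
    myeloid_z: np.ndarray
    primed: np.ndarray = field(repr=False)  # (n, 3), NaN rows where absent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.grid,
                "tristable": self.tristable,
                "x_eryth": self.erythroid_x,
                "z_myel": self.myeloid_z,
                "primed_x": self.primed[:, 0],
                "primed_y": self.primed[:, 1],
                "primed_z": self.primed[:, 2],
            }
        )


def bifurcation_scan(
    params: RateConstants,
    parameter_name: str,
    n_grid: int = 41,
    seed: int = 0,
) -> BifurcationScan:
    """Scan one rate constant over [0, 2 x estimate] and record tristability.

    At each grid value the closed-form attractors are re-evaluated and the
    primed root is re-located, warm-starting from the primed state of the
    unperturbed estimate.
    """
    if parameter_name not in PARAM_NAMES:
        raise KeyError(f"unknown rate constant {parameter_name!r}")
    estimate = getattr(params, parameter_name)
    grid = np.linspace(0.0, 2.0 * estimate, n_grid)

    base_primed = find_primed_state(params, seed=seed)
    guess = base_primed.state if base_primed is not None else None

    tristable = np.zeros(n_grid, dtype=bool)
    ex = np.full(n_grid, np.nan)
    mz = np.full(n_grid, np.nan)
    pr = np.full((n_grid, 3), np.nan)
    for i, v in enumerate(grid):
        p = params.replace(**{parameter_name: float(v)})
        try:
            _, erythroid, myeloid = analytic_steady_states(p)
        except (ValueError, ZeroDivisionError):
            continue
        ex[i] = erythroid.x
        mz[i] = myeloid.z
        primed = find_primed_state(
            p, n_restarts=20, seed=seed, initial_guesses=[guess] if guess is not None else None
        )
        if primed is not None:
            pr[i] = primed.state
        tristable[i] = (
            erythroid.stable
            and erythroid.physical
            and myeloid.stable
            and myeloid.physical
            and primed is not None
            and primed.stable
        )
    return BifurcationScan(
        parameter_name=parameter_name,
        grid=grid,
        tristable=tristable,
        erythroid_x=ex,
        myeloid_z=mz,
        primed=pr,
    )
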