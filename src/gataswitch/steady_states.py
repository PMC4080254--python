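"""Steady states of the network: closed forms, stability, primed-state search.

With ``k2* = 0`` the model always admits the trivial state (0, 0, 0) and,
when ``k1 a4 != 0`` and ``k3 c5 != 0``, two single-gene states in closed
form:

* erythroid (high GATA-1):  x1 = (a1 - k1 a3) / (k1 a4),  y = z = 0
* myeloid   (high PU.1):    z2 = (c1 - k3 c2) / (k3 c5),  x = y = 0

Their stability is governed by seven inequalities on the rate constants
(the trivial state is unstable if any single-gene net growth rate at the
origin is positive; each committed state is stable if the other two genes
cannot invade it).  A fourth, fully interior "primed" state -- the
progenitor condition with low co-expression of all three factors -- has no
closed form and is located numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import root as _root

from .dynamics import rhs
from .parameters import RateConstants

__all__ = [
    "SteadyState",
    "SteadyStateSet",
    "StabilityConditions",
    "analytic_steady_states",
    "stability_conditions",
    "stability_margins",
    "N_INEQUALITY_CONSTRAINTS",
    "jacobian",
    "is_stable",
    "find_primed_state",
    "steady_state_set",
]

#: Residual tolerance below which a point counts as a fixed point.
RESIDUAL_TOL = 1e-8
#: Eigenvalue real parts must be below -EIG_MARGIN for "stable".
EIG_MARGIN = 1e-9
#: Number of inequality constraints governing tristability (3 + 2 + 2).
N_INEQUALITY_CONSTRAINTS = 7


@dataclass(frozen=True)
class SteadyState:
    """A located fixed point with its stability and lineage label."""

    x: float
    y: float
    z: float
    stable: bool
    label: str  # one of {"trivial", "erythroid", "myeloid", "primed"}
    physical: bool = True  # False when a closed-form coordinate is negative

    @property
    def state(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class SteadyStateSet:
    """The up-to-four steady states of one parameter set."""

    trivial: SteadyState
    erythroid: SteadyState
    myeloid: SteadyState
    primed: SteadyState | None = None

    @property
    def tristable(self) -> bool:
        """Three stable, physical, committed-plus-primed states coexist."""
        return (
            self.erythroid.stable
            and self.erythroid.physical
            and self.myeloid.stable
            and self.myeloid.physical
            and self.primed is not None
            and self.primed.stable
        )


class StabilityConditions(NamedTuple):
    trivial_unstable: bool
    erythroid_stable: bool
    myeloid_stable: bool


def analytic_steady_states(
    params: RateConstants,
) -> tuple[SteadyState, SteadyState, SteadyState]:
    """The trivial, erythroid and myeloid states in closed form.

    A negative closed-form coordinate (e.g. when a1 < k1 a3 so the
    erythroid branch has left the positive octant) is reported with
    ``stable=False`` and ``physical=False`` rather than raising, so
    parameter scans can cross existence boundaries.
    """
    p = params
    if p.k1 * p.a4 == 0 or p.k3 * p.c5 == 0:
        raise ValueError("analytic steady states require k1*a4 != 0 and k3*c5 != 0")
    x1 = (p.a1 - p.k1 * p.a3) / (p.k1 * p.a4)
    z2 = (p.c1 - p.k3 * p.c2) / (p.k3 * p.c5)
    cond = stability_conditions(params)

    trivial = SteadyState(0.0, 0.0, 0.0, stable=not cond.trivial_unstable, label="trivial")
    erythroid = SteadyState(
        x1, 0.0, 0.0,
        stable=bool(cond.erythroid_stable and x1 >= 0),
        label="erythroid",
        physical=x1 >= 0,
    )
    myeloid = SteadyState(
        0.0, 0.0, z2,
        stable=bool(cond.myeloid_stable and z2 >= 0),
        label="myeloid",
        physical=z2 >= 0,
    )
    return trivial, erythroid, myeloid


def stability_margins(params: RateConstants) -> dict[str, float]:
    """Signed margins of the seven tristability inequalities.

    A positive margin means the inequality holds.  The first three are the
    per-gene instability conditions of the trivial state (net growth at the
    origin); the remaining four are the non-invadability conditions of the
    erythroid and myeloid states.
    """
    p = params
    x1 = (p.a1 - p.k1 * p.a3) / (p.k1 * p.a4)
    z2 = (p.c1 - p.k3 * p.c2) / (p.k3 * p.c5)
    return {
        "trivial_x": p.a1 - p.a3 * p.k1,
        "trivial_y": p.b1 - p.b2 * p.k2,
        "trivial_z": p.c1 - p.c2 * p.k3,
        "erythroid_y": p.k2 * (p.b2 + p.b3 * x1) - p.b1,
        "erythroid_z": p.k3 * (p.c2 + p.c3 * x1) - p.c1,
        "myeloid_x": p.k1 * (p.a3 + p.a6 * z2) - p.a1,
        "myeloid_y": p.k2 * (p.b2 + p.b5 * z2) - p.b1,
    }


def stability_conditions(params: RateConstants) -> StabilityConditions:
    """Evaluate the closed-form stability inequalities.

    The trivial state is unstable iff any of a1 > a3 k1, b1 > b2 k2,
    c1 > c2 k3 holds.  The erythroid state is stable iff
    b1 < k2 (b2 + b3 x1) and c1 < k3 (c2 + c3 x1); the myeloid state iff
    a1 < k1 (a3 + a6 z2) and b1 < k2 (b2 + b5 z2).
    """
    m = stability_margins(params)
    return StabilityConditions(
        trivial_unstable=bool(m["trivial_x"] > 0 or m["trivial_y"] > 0 or m["trivial_z"] > 0),
        erythroid_stable=bool(m["erythroid_y"] > 0 and m["erythroid_z"] > 0),
        myeloid_stable=bool(m["myeloid_x"] > 0 and m["myeloid_y"] > 0),
    )


def jacobian(state, params: RateConstants) -> np.ndarray:
    """Analytic Jacobian of the autonomous (k2* = 0) right-hand side."""
    x, y, z = np.asarray(state, dtype=float)
    p = params
    n1 = p.a1 * x + p.a2 * y
    d1 = p.a3 + p.a4 * x + p.a5 * y + p.a6 * z + p.a7 * x * z
    n2 = p.b1 * y
    d2 = p.b2 + p.b3 * x + p.b4 * y + p.b5 * z + p.b6 * y * z
    n3 = p.c1 * z
    d3 = p.c2 + p.c3 * x + p.c4 * y + p.c5 * z + p.c6 * x * z + p.c7 * y * z
    for d, which in ((d1, "x"), (d2, "y"), (d3, "z")):
        if d == 0.0:
            raise ZeroDivisionError(f"promoter denominator of the {which} equation is zero")
    return np.array(
        [
            [
                (p.a1 * d1 - n1 * (p.a4 + p.a7 * z)) / d1**2 - p.k1,
                (p.a2 * d1 - n1 * p.a5) / d1**2,
                -n1 * (p.a6 + p.a7 * x) / d1**2,
            ],
            [
                -n2 * p.b3 / d2**2,
                (p.b1 * d2 - n2 * (p.b4 + p.b6 * z)) / d2**2 - p.k2,
                -n2 * (p.b5 + p.b6 * y) / d2**2,
            ],
            [
                -n3 * (p.c3 + p.c6 * z) / d3**2,
                -n3 * (p.c4 + p.c7 * z) / d3**2,
                (p.c1 * d3 - n3 * (p.c5 + p.c6 * x + p.c7 * y)) / d3**2 - p.k3,
            ],
        ]
    )


def is_stable(
    state,
    params: RateConstants,
    residual_tol: float = RESIDUAL_TOL,
    check_fixed_point: bool = True,
) -> bool:
    """Linear (eigenvalue) stability of an approximate fixed point.

    Raises ``ValueError`` when ``state`` is not a fixed point to within
    ``residual_tol`` (max-norm of the RHS), unless the check is disabled.
    """
    state = np.asarray(state, dtype=float)
    if check_fixed_point:
        res = np.max(np.abs(rhs(state, 0.0, params)))
        if res > residual_tol * max(1.0, float(np.max(np.abs(state)))):
            raise ValueError(f"state {state} is not a fixed point (residual {res:.3g})")
    eig = np.linalg.eigvals(jacobian(state, params))
    return bool(np.max(eig.real) < -EIG_MARGIN)


def find_primed_state(
    params: RateConstants,
    n_restarts: int = 100,
    seed: int = 0,
    residual_tol: float = RESIDUAL_TOL,
    positive_tol: float = 1e-8,
    initial_guesses=None,
) -> SteadyState | None:
    """Search for the interior ("primed") fixed point.

    Runs a damped Newton-type root finder from ``n_restarts`` random
    initial guesses drawn log-uniformly between 1e-2 and the largest
    attractor coordinate on each axis.  Roots are deduplicated at 1e-6
    relative distance, restricted to strictly positive coordinates, and
    the most interior root (largest minimum coordinate) is returned; a
    stable root is preferred over an unstable one and ends the search
    early.  Returns ``None`` when no strictly positive root is found --
    absence is a value, not an error.

    ``initial_guesses`` prepends warm-start points (used by the robustness
    scans to re-seed from an unperturbed primed state).
    """
    rng = np.random.default_rng(seed)
    _, erythroid, myeloid = analytic_steady_states(params)
    hi = max(erythroid.x, myeloid.z, 1.0)
    lo = 1e-2

    guesses = [np.asarray(g, dtype=float) for g in (initial_guesses or [])]
    guesses += [
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=3)) for _ in range(n_restarts)
    ]

    best: tuple[float, np.ndarray, bool] | None = None  # (min coord, root, stable)
    seen: list[np.ndarray] = []
    for g in guesses:
        sol = _root(lambda s: rhs(s, 0.0, params), g, method="hybr")
        r = sol.x
        if not sol.success:
            continue
        if np.max(np.abs(rhs(r, 0.0, params))) > residual_tol:
            continue
        if not np.all(r > positive_tol):
            continue
        if any(np.linalg.norm(r - s) <= 1e-6 * max(np.linalg.norm(s), 1.0) for s in seen):
            continue
        seen.append(r.copy())
        stable = is_stable(r, params, residual_tol=np.inf, check_fixed_point=False)
        cand = (float(np.min(r)), r, stable)
        if best is None or (stable, cand[0]) > (best[2], best[0]):
            best = cand
        if stable:
            break  # a stable interior root is the object of the search

    if best is None:
        return None
    _, r, stable = best
    return SteadyState(float(r[0]), float(r[1]), float(r[2]), stable=stable, label="primed")


def steady_state_set(
    params: RateConstants,
    n_restarts: int = 100,
    seed: int = 0,
    primed_guess=None,
) -> SteadyStateSet:
    """All located steady states: closed-form triple plus the primed root."""
    trivial, erythroid, myeloid = analytic_steady_states(params)
    guesses = [primed_guess] if primed_guess is not None else None
    primed = find_primed_state(params, n_restarts=n_restarts, seed=seed, initial_guesses=guesses)
    return SteadyStateSet(trivial=trivial, erythroid=erythroid, myeloid=myeloid, primed=primed)
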