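"""Deterministic dynamics: the ODE right-hand side and its simulation.

The model, with x = [GATA-1], y = [GATA-2], z = [PU.1]:

    dx/dt = (a1 x + a2 y) / (a3 + a4 x + a5 y + a6 z + a7 x z) - k1 x + mu k2*(t) y
    dy/dt =        b1 y   / (b2 + b3 x + b4 y + b5 z + b6 y z) - k2 y -    k2*(t) y
    dz/dt =        c1 z   / (c2 + c3 x + c4 y + c5 z + c6 x z + c7 y z) - k3 z

Synthesis is a Shea--Ackers occupancy ratio (basal expression is zero),
degradation is first order, and the GATA switch enters through the
time-windowed extra GATA-2 degradation rate ``k2*(t)`` with a coupled
GATA-1 influx ``mu k2*(t) y``.

``simulate_ode`` integrates piecewise over the schedule window so the
``k2*`` discontinuity always falls on a segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import RateConstants, SwitchSchedule

__all__ = [
    "rhs",
    "Trajectory",
    "IntegrationError",
    "simulate_ode",
    "relative_distance",
    "validate_steady_state_by_perturbation",
]

#: Default integration tolerances (adaptive, stiff-capable integrator).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def rhs(
    state,
    t: float,
    params: RateConstants,
    schedule: SwitchSchedule | None = None,
) -> np.ndarray:
    """Time derivative (dx/dt, dy/dt, dz/dt) at ``state`` and time ``t``.

    With no ``schedule`` (or outside its window) ``k2* = 0`` and the system
    is autonomous.  Raises ``ZeroDivisionError`` if a promoter denominator
    is exactly zero (possible only when the basal constant and the state
    are both zero).
    """
    x, y, z = state
    p = params
    k2s = schedule.value(t) if schedule is not None else 0.0
    mu = schedule.mu if schedule is not None else 0.0

    den_x = p.a3 + p.a4 * x + p.a5 * y + p.a6 * z + p.a7 * x * z
    den_y = p.b2 + p.b3 * x + p.b4 * y + p.b5 * z + p.b6 * y * z
    den_z = p.c2 + p.c3 * x + p.c4 * y + p.c5 * z + p.c6 * x * z + p.c7 * y * z

    num_x = p.a1 * x + p.a2 * y
    num_y = p.b1 * y
    num_z = p.c1 * z
    for num, den, which in ((num_x, den_x, "x"), (num_y, den_y, "y"), (num_z, den_z, "z")):
        if den == 0.0 and num != 0.0:
            raise ZeroDivisionError(f"promoter denominator of the {which} equation is zero")

    dx = (num_x / den_x if den_x != 0.0 else 0.0) - p.k1 * x + mu * k2s * y
    dy = (num_y / den_y if den_y != 0.0 else 0.0) - p.k2 * y - k2s * y
    dz = (num_z / den_z if den_z != 0.0 else 0.0) - p.k3 * z
    return np.array([dx, dy, dz])


@dataclass(frozen=True)
class Trajectory:
    """A timestamped (x, y, z) path with the schedule that produced it."""

    times: np.ndarray
    states: np.ndarray
    schedule: SwitchSchedule | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if s.shape != (t.size, 3):
            raise ValueError(f"states shape {s.shape} does not match {t.size} times")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "x": self.states[:, 0], "y": self.states[:, 1], "z": self.states[:, 2]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries segment and time reached."""

    def __init__(self, message: str, segment: tuple[float, float], t_reached: float):
        super().__init__(f"{message} (segment [{segment[0]}, {segment[1]}], reached t={t_reached})")
        self.segment = segment
        self.t_reached = t_reached


class _BudgetExceeded(Exception):
    """Internal: the RHS evaluation budget of one solver attempt ran out."""


#: RHS evaluations allowed per segment and solver attempt before falling
#: back to the next stiff method.  Normal segments need a few thousand.
_NFEV_BUDGET = 100_000

#: Solver fallback chain.  LSODA is fast on the typical mildly stiff
#: segments but can stall near collapsing boundary layers (GATA-2 driven
#: to zero inside the switch window); the implicit methods with the
#: analytic Jacobian are slower per step but robust there.
_METHOD_CHAIN = ("LSODA", "BDF", "Radau")


def _segments(schedule: SwitchSchedule | None, t_end: float) -> list[tuple[float, float]]:
    if schedule is None:
        return [(0.0, t_end)]
    cuts = [t for t in (schedule.t_on, schedule.t_off) if 0.0 < t < t_end]
    edges = [0.0, *cuts, t_end]
    return list(zip(edges[:-1], edges[1:]))


def simulate_ode(
    params: RateConstants,
    schedule: SwitchSchedule | None,
    init,
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = 501,
    method: str | None = None,
) -> Trajectory:
    """Integrate the model from ``init`` on [0, t_end].

    Integration is split at the schedule's window boundaries so the
    ``k2*`` discontinuity is never crossed inside an adaptive step.  Each
    segment is solved with the analytic Jacobian through a fallback chain
    of stiff-capable methods (LSODA, then BDF, then Radau), each attempt
    bounded by an RHS-evaluation budget; exhausting the chain raises
    :class:`IntegrationError` with the segment and time reached.  The
    recorded states are clipped at zero (the flow preserves the positive
    octant; tiny negative excursions are integrator round-off).
    ``method`` pins a single solver instead of the chain.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (3,):
        raise ValueError("init must be a length-3 state (x, y, z)")
    if np.any(init < 0):
        raise ValueError("initial state must be non-negative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")

    from .steady_states import jacobian as _jac  # local import: avoids a cycle

    t_eval = np.linspace(0.0, t_end, n_points)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    s = init.copy()
    methods = (method,) if method is not None else _METHOD_CHAIN
    for (ta, tb) in _segments(schedule, t_end):
        # evaluate k2* at the segment midpoint: constant within a segment
        tm = 0.5 * (ta + tb)
        k2s = schedule.value(tm) if schedule is not None else 0.0
        mu = schedule.mu if schedule is not None else 0.0
        # frozen-in-segment schedule avoids re-branching inside the solver
        seg_sched = _ConstantWindow(k2s, mu) if schedule is not None else None
        pts = t_eval[(t_eval >= ta) & (t_eval <= tb)]
        pts = np.unique(np.concatenate([[ta], pts, [tb]]))

        def jac(t, ss, _k2s=k2s, _mu=mu):
            j = _jac(ss, params)
            j[0, 1] += _mu * _k2s
            j[1, 1] -= _k2s
            return j

        sol = None
        last_msg = "no solver attempted"
        for m in methods:
            budget = [_NFEV_BUDGET]

            def fun(t, ss):
                budget[0] -= 1
                if budget[0] < 0:
                    raise _BudgetExceeded
                return rhs(ss, t, params, seg_sched)

            try:
                attempt = solve_ivp(
                    fun, (ta, tb), s, method=m, rtol=rtol, atol=atol, t_eval=pts, jac=jac
                )
            except _BudgetExceeded:
                last_msg = f"{m}: evaluation budget exhausted"
                continue
            if attempt.success:
                sol = attempt
                break
            last_msg = f"{m}: {attempt.message}"
        if sol is None:
            raise IntegrationError(last_msg, (ta, tb), ta)
        keep = (sol.t < tb) | np.isclose(sol.t, t_end)
        times.append(sol.t[keep])
        states.append(sol.y.T[keep])
        s = sol.y[:, -1]

    t_all = np.concatenate(times)
    s_all = np.clip(np.concatenate(states), 0.0, None)
    t_all, idx = np.unique(t_all, return_index=True)
    return Trajectory(times=t_all, states=s_all[idx], schedule=schedule)


class _ConstantWindow:
    """Schedule stand-in with a fixed k2* (used inside one ODE segment)."""

    __slots__ = ("_k2s", "mu")

    def __init__(self, k2s: float, mu: float):
        self._k2s = k2s
        self.mu = mu

    def value(self, t: float) -> float:
        return self._k2s


def relative_distance(state, reference) -> float:
    """Euclidean distance scaled by the reference norm (floored at 1).

    The floor makes the measure meaningful for the trivial state at the
    origin, where a relative measure would otherwise divide by zero.
    """
    state = np.asarray(state, dtype=float)
    reference = np.asarray(reference, dtype=float)
    return float(np.linalg.norm(state - reference) / max(np.linalg.norm(reference), 1.0))


def validate_steady_state_by_perturbation(
    params: RateConstants,
    state,
    strength: float = 0.05,
    n_trials: int = 10,
    seed: int = 0,
    t_relax: float = 200.0,
    tol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    zero_scale: float = 0.01,
) -> bool:
    """Check that perturbed copies of ``state`` relax back to it.

    Each coordinate is multiplied by ``1 + strength * u`` with
    ``u ~ U(-1, 1)``; coordinates that are exactly zero instead receive a
    small absolute kick ``strength * |u| * zero_scale`` (a multiplicative
    perturbation of zero would be no perturbation at all, and an unstable
    state at the origin must be able to fail this check).  The default
    ``zero_scale`` of 0.01 concentration units keeps the kick well inside
    the narrow off-axis basin of the committed states (a few 1e-3 units
    for the reference set) while any kick at all suffices to flush out an
    exponentially unstable origin.  Returns True iff every trial ends
    within ``tol`` relative distance of ``state``.
    """
    state = np.asarray(state, dtype=float)
    if strength == 0.0 or n_trials == 0:
        return True
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        u = rng.uniform(-1.0, 1.0, size=3)
        perturbed = np.where(
            state > 0, state * (1.0 + strength * u), strength * np.abs(u) * zero_scale
        )
        try:
            traj = simulate_ode(params, None, perturbed, t_relax, rtol=rtol, atol=atol, n_points=11)
        except IntegrationError:
            return False  # a state we cannot integrate back to is not validated
        if relative_distance(traj.endpoint, state) > tol:
            return False
    return True
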