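"""Rate constants and switch schedules for the GATA-1/GATA-2/PU.1 network.

The deterministic model tracks the concentrations ``x, y, z`` of the
transcription factors GATA-1, GATA-2 and PU.1.  Transcription of each gene
is written in the Shea--Ackers thermodynamic form (a rational function of
promoter-occupancy terms), degradation is first order, and the GATA switch
is modelled as a transient extra GATA-2 degradation rate ``k2*`` paired
with a GATA-1 influx ``mu * k2* * y`` that represents GATA-1 taking over
the chromatin sites vacated by GATA-2.

This module holds the two plain-data objects everything else consumes:

* :class:`RateConstants` -- the 23 kinetic parameters,
* :class:`SwitchSchedule` -- the time window of the GATA switch / knockdown,

plus serialization (JSON/YAML), the published reference parameter set, and
the experimentally anchored degradation-rate helper.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "RateConstants",
    "SwitchSchedule",
    "half_life_to_rate",
    "figure3_parameters",
    "schedule_preset",
    "SCHEDULE_PRESETS",
    "load_parameters",
    "save_parameters",
    "load_schedule",
]

#: Canonical ordering of the 23 rate constants.
PARAM_NAMES: tuple[str, ...] = (
    "a1", "a2", "a3", "a4", "a5", "a6", "a7",
    "b1", "b2", "b3", "b4", "b5", "b6",
    "c1", "c2", "c3", "c4", "c5", "c6", "c7",
    "k1", "k2", "k3",
)


def half_life_to_rate(half_life: float) -> float:
    """First-order degradation rate (per hour) from a protein half-life.

    ``rate = ln(2) / half_life``.  The three proteins of the network have
    measured half-lives of 1 h (GATA-1), 0.5 h (GATA-2) and ~2.4 h (PU.1),
    giving the canonical rates 0.6931, 1.3863 and 0.2888 per hour.

    Raises
    ------
    ValueError
        If ``half_life`` is not strictly positive.
    """
    if not half_life > 0:
        raise ValueError(f"half-life must be positive, got {half_life!r}")
    return math.log(2.0) / half_life


@dataclass(frozen=True)
class RateConstants:
    """The 23 kinetic parameters of the three-gene network.

    ``a*`` govern the GATA-1 equation (a1, a2 synthesis; a3 the basal
    denominator; a4--a7 promoter binding terms), ``b*`` the GATA-2
    equation, ``c*`` the PU.1 equation, and ``k1``--``k3`` are the
    first-order degradation rates (per hour).

    All values must be finite and non-negative.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float
    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    c6: float
    c7: float
    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"rate constant {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {v!r}")

    # -- views ---------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def to_array(self) -> np.ndarray:
        """Values in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateConstants":
        extra = set(d) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown rate-constant names: {sorted(extra)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing rate-constant names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_array(cls, values) -> "RateConstants":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got shape {values.shape}")
        return cls(*(float(v) for v in values))

    def replace(self, **changes: float) -> "RateConstants":
        return dataclasses.replace(self, **changes)

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())

    # -- domain checks -------------------------------------------------

    def is_inference_normalized(self, tol: float = 0.0) -> bool:
        """True if the non-dimensionalization a3 = b2 = c2 = 1 holds."""
        return all(abs(getattr(self, n) - 1.0) <= tol for n in ("a3", "b2", "c2"))

    def satisfies_equality_constraints(self, rtol: float = 1e-12) -> bool:
        """Shared-binding-site assumptions: b6 = a7 and c7 = c6.

        GATA-1 and GATA-2 compete for the same cis-elements, so their
        binding terms on the GATA-2 promoter are set equal (b6 = a7), and
        the two repressive PU.1 promoter terms share one constant (c7 = c6).
        """
        return (
            math.isclose(self.b6, self.a7, rel_tol=rtol, abs_tol=1e-12)
            and math.isclose(self.c7, self.c6, rel_tol=rtol, abs_tol=1e-12)
        )


@dataclass(frozen=True)
class SwitchSchedule:
    """Time-windowed GATA-2 degradation boost and GATA-1 availability.

    ``k2*(t) = k2_star`` for ``t`` in the closed window ``[t_on, t_off]``
    and 0 otherwise.  ``mu`` scales the GATA-1 influx ``mu * k2* * y``:
    ``mu = 0`` encodes GATA-2 knockdown with GATA-1 absent, ``mu > 0``
    encodes the GATA switch proper.
    """

    k2_star: float
    t_on: float
    t_off: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.k2_star < 0:
            raise ValueError("k2_star must be >= 0")
        if not self.t_on < self.t_off:
            raise ValueError(f"t_on must be < t_off, got [{self.t_on}, {self.t_off}]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    def value(self, t: float) -> float:
        """k2*(t); the window is treated as a closed interval."""
        return self.k2_star if self.t_on <= t <= self.t_off else 0.0

    def values(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.t_on) & (t <= self.t_off), self.k2_star, 0.0)

    def to_dict(self) -> dict[str, float]:
        return {
            "k2_star": self.k2_star,
            "t_on": self.t_on,
            "t_off": self.t_off,
            "mu": self.mu,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "SwitchSchedule":
        return cls(
            k2_star=float(d["k2_star"]),
            t_on=float(d["t_on"]),
            t_off=float(d["t_off"]),
            mu=float(d.get("mu", 0.0)),
        )

    def with_mu(self, mu: float) -> "SwitchSchedule":
        return dataclasses.replace(self, mu=mu)


#: Named switch schedules used throughout the study conditions.
#: "deterministic" is the slow window of the reference deterministic runs
#: (k2* = 6); "validation" the stronger window used when checking that a
#: parameter set can switch at all (k2* = 20); "stochastic" the short,
#: strong window of the stochastic ensembles (k2* = 25 on [50, 200]).
SCHEDULE_PRESETS: dict[str, SwitchSchedule] = {
    "deterministic": SwitchSchedule(k2_star=6.0, t_on=500.0, t_off=1500.0, mu=1.0),
    "validation": SwitchSchedule(k2_star=20.0, t_on=500.0, t_off=1500.0, mu=1.0),
    "stochastic": SwitchSchedule(k2_star=25.0, t_on=50.0, t_off=200.0, mu=0.28),
}


def schedule_preset(name: str, mu: float | None = None) -> SwitchSchedule:
    """Return a named schedule preset, optionally overriding ``mu``."""
    try:
        sched = SCHEDULE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule preset {name!r}; known: {sorted(SCHEDULE_PRESETS)}"
        ) from None
    return sched if mu is None else sched.with_mu(mu)


def _data_path(name: str):
    return resources.files("gataswitch.data").joinpath(name)


def figure3_parameters() -> RateConstants:
    """The published reference parameter set (tristable and switching).

    This is the 23-constant estimate obtained by the staged GA inference;
    it realizes three stable steady states (erythroid, myeloid, primed)
    and genetic switching under the GATA-switch schedule.
    """
    with _data_path("figure3.json").open("r") as fh:
        return RateConstants.from_dict(json.load(fh))


_FIXTURES = {"figure3": figure3_parameters}


def load_parameters(source: str | Path) -> RateConstants:
    """Load rate constants from a fixture name or a JSON/YAML file.

    ``source`` may be a known fixture name (currently ``"figure3"``) or a
    path to a JSON or YAML file whose keys are exactly a1..a7, b1..b6,
    c1..c7, k1..k3.
    """
    if isinstance(source, str) and source in _FIXTURES:
        return _FIXTURES[source]()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a known fixture ({sorted(_FIXTURES)}) nor a file"
        )
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return RateConstants.from_dict(data)


def save_parameters(params: RateConstants, path: str | Path) -> None:
    """Write rate constants to JSON or YAML (by file extension)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
    else:
        path.write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def load_schedule(source: str | Path) -> SwitchSchedule:
    """Load a switch schedule from a preset name or a JSON/YAML file."""
    if isinstance(source, str) and source in SCHEDULE_PRESETS:
        return SCHEDULE_PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a schedule preset ({sorted(SCHEDULE_PRESETS)}) nor a file"
        )
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return SwitchSchedule.from_dict(data)
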