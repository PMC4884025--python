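"""Coupled Gompertz model of *Bacillus thuringiensis* batch fermentation.

The culture is described by four "key compounds", one per dominant metabolic
phase: vegetative cells (biomass), the storage polymer poly-β-hydroxybutyrate
(PHB), dipicolinic acid (DPA, the endospore proxy) and the insecticidal Cry
protein. Each compound's *production* follows an asymmetric sigmoid (Gompertz)
term ``A·exp(−exp(−μ·(t − t_c)))``; biomass and PHB additionally carry
*consumption* terms coupled through yield coefficients:

* biomass(t) = G_x(t) − DPA(t) / Y_DPA/X            (cells die into endospores)
* PHB(t)     = G_p(t) − DPA(t)/Y_DPA/PHB − Cry(t)/Y_Cry/PHB
  (PHB is the carbon/energy source for sporulation and Cry synthesis)
* DPA(t), Cry(t) are plain Gompertz curves (parallel sporulation products).

The difference equations are not positivity-constrained: with realistic
parameter sets the biomass and PHB expressions go below zero late in the
culture (every cell has sporulated, all PHB is spent). Evaluation functions
therefore take a ``clamp`` switch that reports negative values as 0 and flags
them, which is how measured concentrations behave.

All concentrations are g/L, times are hours since inoculation, rates 1/h.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPOUNDS",
    "GompertzParams",
    "YieldCoefficients",
    "BiodynamicParameters",
    "Trajectory",
    "gompertz_value",
    "dpa_at",
    "cry_at",
    "biomass_at",
    "phb_at",
    "simulate",
]

#: canonical compound order used across the package (columns, fits, reports)
COMPOUNDS = ("biomass", "phb", "dpa", "cry")


@dataclass(frozen=True)
class GompertzParams:
    """One sigmoid term: asymptote (g/L), specific rate (1/h), critical time (h).

    The critical time is the inflection point; the curve value there is exactly
    ``asymptote / e``.
    """

    asymptote: float
    rate: float
    critical_time: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.asymptote) and self.asymptote >= 0):
            raise ValueError(f"asymptote must be finite and >= 0, got {self.asymptote}")
        if not (math.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"rate must be finite and > 0, got {self.rate}")
        if not math.isfinite(self.critical_time):
            raise ValueError(f"critical_time must be finite, got {self.critical_time}")


@dataclass(frozen=True)
class YieldCoefficients:
    """Coupling yields: g DPA per g biomass, g DPA per g PHB, g Cry per g PHB."""

    dpa_from_biomass: float
    dpa_from_phb: float
    cry_from_phb: float

    def __post_init__(self) -> None:
        for name in ("dpa_from_biomass", "dpa_from_phb", "cry_from_phb"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"yield coefficient {name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class BiodynamicParameters:
    """Full parameter set of one fermentation: four Gompertz triples + yields.

    ``initial_glucose`` / ``initial_soybean`` record the medium composition
    (g/L) when known; they drive the cross-fermentation regressions but play no
    role in the kinetic equations themselves.
    """

    biomass: GompertzParams
    phb: GompertzParams
    dpa: GompertzParams
    cry: GompertzParams
    yields: YieldCoefficients
    label: str = ""
    initial_glucose: float | None = None
    initial_soybean: float | None = None

    def __post_init__(self) -> None:
        for name, val in (("initial_glucose", self.initial_glucose),
                          ("initial_soybean", self.initial_soybean)):
            if val is not None and not (math.isfinite(val) and val >= 0):
                raise ValueError(f"{name} must be finite and >= 0 when present, got {val}")

    def gompertz(self, compound: str) -> GompertzParams:
        """The Gompertz triple of one compound ('biomass'|'phb'|'dpa'|'cry')."""
        if compound not in COMPOUNDS:
            raise KeyError(f"unknown compound {compound!r}; expected one of {COMPOUNDS}")
        return getattr(self, compound)


@dataclass(frozen=True)
class Trajectory:
    """Model-evaluated concentrations on a time grid.

    ``clamped[compound]`` flags points where a negative model value was
    reported as 0 (only ever set when clamping was requested; DPA and Cry are
    non-negative by construction and are never clamped).
    """

    times: np.ndarray
    biomass: np.ndarray
    phb: np.ndarray
    dpa: np.ndarray
    cry: np.ndarray
    clamped: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in COMPOUNDS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != times length {n}")
        for name, flags in self.clamped.items():
            if len(flags) != n:
                raise ValueError(f"clamped[{name!r}] length mismatch")

    def compound(self, name: str) -> np.ndarray:
        if name not in COMPOUNDS:
            raise KeyError(f"unknown compound {name!r}")
        return getattr(self, name)

    def to_frame(self):
        """Standard tabular form (pandas DataFrame, one row per time point)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "biomass_g_per_l": self.biomass,
                "phb_g_per_l": self.phb,
                "dpa_g_per_l": self.dpa,
                "cry_g_per_l": self.cry,
            }
        )


def _as_times(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("time values must be finite")
    return arr


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def gompertz_value(t, p: GompertzParams):
    """Evaluate ``A·exp(−exp(−μ·(t − t_c)))`` at time(s) ``t`` (hours).

    Monotone non-decreasing in ``t``; tends to 0 as t → −∞ and to the
    asymptote as t → +∞. Accepts scalars or arrays; rejects non-finite times.
    """
    arr = _as_times(t)
    scalar = arr.ndim == 0
    # inner exp may overflow for very early times; the limit (value 0) is exact
    with np.errstate(over="ignore"):
        inner = np.exp(-p.rate * (arr - p.critical_time))
    out = p.asymptote * np.exp(-inner)
    return _maybe_scalar(out, scalar)


def dpa_at(t, params: BiodynamicParameters):
    """DPA concentration (g/L): a plain Gompertz production curve."""
    return gompertz_value(t, params.dpa)


def cry_at(t, params: BiodynamicParameters):
    """Cry protein concentration (g/L): a plain Gompertz production curve."""
    return gompertz_value(t, params.cry)


def _clamp(values, scalar: bool, clamp: bool):
    """Clamp negatives to 0; return (values, clamped_flags)."""
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if not clamp:
        return _maybe_scalar(values if not scalar else np.squeeze(arr), scalar), np.zeros(arr.shape, bool)
    flags = arr < 0
    out = np.where(flags, 0.0, arr)
    return _maybe_scalar(out[0] if scalar else out, scalar), flags


def biomass_at(t, params: BiodynamicParameters, clamp: bool = False):
    """Biomass (g/L): Gompertz growth minus death into endospores.

    growth − DPA(t)/Y_DPA/X. With clamp off the two-term identity
    ``biomass + DPA/Y_DPA/X == growth term`` holds exactly (the value may be
    negative late in culture); with clamp on, negatives are reported as 0.
    """
    arr = _as_times(t)
    scalar = arr.ndim == 0
    raw = gompertz_value(arr, params.biomass) - dpa_at(arr, params) / params.yields.dpa_from_biomass
    value, _ = _clamp(raw, scalar, clamp)
    return value


def phb_at(t, params: BiodynamicParameters, clamp: bool = False):
    """PHB (g/L): Gompertz production minus consumption into DPA and Cry.

    production − DPA(t)/Y_DPA/PHB − Cry(t)/Y_Cry/PHB; clamp semantics as
    :func:`biomass_at`.
    """
    arr = _as_times(t)
    scalar = arr.ndim == 0
    raw = (
        gompertz_value(arr, params.phb)
        - dpa_at(arr, params) / params.yields.dpa_from_phb
        - cry_at(arr, params) / params.yields.cry_from_phb
    )
    value, _ = _clamp(raw, scalar, clamp)
    return value


def simulate(params: BiodynamicParameters, times, clamp: bool = False) -> Trajectory:
    """Evaluate all four compounds on a strictly increasing time grid."""
    arr = _as_times(times)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError("times must be strictly increasing")

    dpa = gompertz_value(arr, params.dpa)
    cry = gompertz_value(arr, params.cry)
    biomass_raw = gompertz_value(arr, params.biomass) - dpa / params.yields.dpa_from_biomass
    phb_raw = (
        gompertz_value(arr, params.phb)
        - dpa / params.yields.dpa_from_phb
        - cry / params.yields.cry_from_phb
    )
    clamped: dict[str, np.ndarray] = {}
    if clamp:
        clamped = {
            "biomass": biomass_raw < 0,
            "phb": phb_raw < 0,
            "dpa": np.zeros(arr.shape, bool),
            "cry": np.zeros(arr.shape, bool),
        }
        biomass_raw = np.maximum(biomass_raw, 0.0)
        phb_raw = np.maximum(phb_raw, 0.0)
    return Trajectory(times=arr, biomass=biomass_raw, phb=phb_raw, dpa=dpa, cry=cry, clamped=clamped)


def replace(obj, **changes):
    """Thin re-export of :func:`dataclasses.replace` for parameter tweaking."""
    return dataclasses.replace(obj, **changes)
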