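"""Cross-fermentation analyses.

Kinetics from heterogeneous sources (different media, reactors, assay
techniques) are made comparable by max-scaling each compound series to [0, 1].
Across a set of fermentations run at different initial glucose loads, the
fitted parameters can then be regressed on glucose: the maximum
concentrations of biomass, PHB and Cry rise linearly with substrate while
DPA_max shows no relationship, and the yield coefficients Y_Cry/PHB and
Y_DPA/PHB trend monotonically up and down, respectively (tested by Spearman
rank correlation).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import BiodynamicParameters
from .synthetic_data import KineticsSeries

__all__ = [
    "PARAMETER_NAMES",
    "RegressionResult",
    "YieldTrend",
    "normalize_series",
    "parameter_substrate_regression",
    "yield_trend",
]

#: flat parameter names accepted by the regression, mapped to accessors
PARAMETER_NAMES = {
    "x_max": lambda p: p.biomass.asymptote,
    "mu_max": lambda p: p.biomass.rate,
    "t_c": lambda p: p.biomass.critical_time,
    "phb_max": lambda p: p.phb.asymptote,
    "mu_max_p": lambda p: p.phb.rate,
    "t_c_p": lambda p: p.phb.critical_time,
    "dpa_max": lambda p: p.dpa.asymptote,
    "mu_max_d": lambda p: p.dpa.rate,
    "t_c_d": lambda p: p.dpa.critical_time,
    "cry_max": lambda p: p.cry.asymptote,
    "mu_max_c": lambda p: p.cry.rate,
    "t_c_c": lambda p: p.cry.critical_time,
    "y_dpa_x": lambda p: p.yields.dpa_from_biomass,
    "y_dpa_phb": lambda p: p.yields.dpa_from_phb,
    "y_cry_phb": lambda p: p.yields.cry_from_phb,
}


@dataclass(frozen=True)
class RegressionResult:
    """OLS of one parameter on initial glucose, with Pearson r and t-test p.

    ``small_n`` flags fits on very few fermentations (n ≤ 4), where the
    p-value carries little power.
    """

    parameter: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    small_n: bool


@dataclass(frozen=True)
class YieldTrend:
    """Spearman rank correlation of one yield coefficient with glucose."""

    yield_name: str
    spearman_rho: float
    classification: str  # "increasing" | "decreasing" | "no-trend"


def normalize_series(
    series: KineticsSeries, compound: str, normalize_time: bool = False
) -> KineticsSeries:
    """Max-scale one compound of a series to [0, 1] (censored flags kept).

    With ``normalize_time`` the time axis is additionally divided by the time
    of that compound's maximum, putting the peak at normalized time 1.
    """
    values = series.compound(compound)
    peak = float(values.max())
    if peak <= 0:
        raise ValueError(f"cannot normalize {compound!r}: series maximum is not positive")
    changes = {compound: values / peak}
    if normalize_time:
        t_peak = float(series.times[int(np.argmax(values))])
        if t_peak <= 0:
            raise ValueError("time of maximum is not positive; cannot rescale time")
        changes["times"] = series.times / t_peak
    return dataclasses.replace(series, censored=dict(series.censored), **changes)


def _glucose_pairs(sets: list[BiodynamicParameters], context: str) -> np.ndarray:
    missing = [p.label or f"#{i}" for i, p in enumerate(sets) if p.initial_glucose is None]
    if missing:
        raise ValueError(f"{context}: initial_glucose missing for {', '.join(missing)}")
    return np.array([p.initial_glucose for p in sets], dtype=float)


def parameter_substrate_regression(
    sets: list[BiodynamicParameters], which: str
) -> RegressionResult:
    """OLS of the named parameter on initial glucose over ≥ 3 fermentations."""
    if which not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter {which!r}; expected one of {sorted(PARAMETER_NAMES)}")
    if len(sets) < 3:
        raise ValueError("need at least 3 parameter sets")
    glucose = _glucose_pairs(sets, f"regression of {which}")
    response = np.array([PARAMETER_NAMES[which](p) for p in sets], dtype=float)
    fit = stats.linregress(glucose, response)
    return RegressionResult(
        parameter=which,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(sets),
        small_n=len(sets) <= 4,
    )


def _trend(name: str, values: np.ndarray, glucose: np.ndarray) -> YieldTrend:
    if np.ptp(values) == 0.0:
        return YieldTrend(name, math.nan, "no-trend")
    rho = float(stats.spearmanr(glucose, values).statistic)
    if math.isnan(rho) or rho == 0.0:
        cls = "no-trend"
    elif rho > 0:
        cls = "increasing"
    else:
        cls = "decreasing"
    return YieldTrend(name, rho, cls)


def yield_trend(sets: list[BiodynamicParameters]) -> dict[str, YieldTrend]:
    """Spearman trend of Y_Cry/PHB and Y_DPA/PHB with initial glucose."""
    if len(sets) < 3:
        raise ValueError("need at least 3 parameter sets")
    glucose = _glucose_pairs(sets, "yield trend")
    if np.unique(glucose).size != glucose.size:
        raise ValueError("tied initial_glucose values; ranks are ambiguous")
    return {
        "y_cry_phb": _trend(
            "y_cry_phb", np.array([p.yields.cry_from_phb for p in sets]), glucose
        ),
        "y_dpa_phb": _trend(
            "y_dpa_phb", np.array([p.yields.dpa_from_phb for p in sets]), glucose
        ),
    }
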