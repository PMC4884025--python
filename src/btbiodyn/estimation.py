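"""Parameter estimation by damped nonlinear least squares.

The fifteen model parameters (four Gompertz triples + three yield
coefficients) are estimated from observed kinetics by minimizing the sum of
squared residuals between predicted and measured concentrations, using a
damped (Marquardt-style) least-squares minimizer with non-negativity bounds
on asymptotes, rates and yields (critical times are unbounded).

Two strategies are provided:

* ``staged`` — exploits the model's triangular structure: DPA and Cry are
  plain sigmoids and are fitted first; the fitted DPA curve is then inserted
  into the biomass equation to fit the biomass triple together with Y_DPA/X;
  finally the fitted DPA and Cry curves are inserted into the PHB equation to
  fit the PHB triple with Y_DPA/PHB and Y_Cry/PHB.
* ``joint`` — a single least-squares problem over all fifteen parameters,
  initialized from the staged solution; its total SSE can therefore never
  exceed the staged one.

By default, residuals are computed against the *reported* model value: raw
predictions are clamped at zero (concentrations cannot be negative) and, when
the series carries known detection limits, predictions below a compound's
limit are reported as 0 — the same operator the assay applies to the true
concentration. Under the ``include`` censoring policy this lets censored
zeros enter the fit without dragging the curve below its detection window;
``exclude`` drops censored points instead. Set
``FitSettings.clamp_predictions = False`` to fit the raw two-term equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .model_core import (
    COMPOUNDS,
    BiodynamicParameters,
    GompertzParams,
    YieldCoefficients,
    gompertz_value,
)
from .synthetic_data import KineticsSeries

__all__ = [
    "InsufficientDataError",
    "UndefinedVarianceError",
    "FitSettings",
    "GompertzFit",
    "FitResult",
    "r_squared",
    "fit_gompertz",
    "fit_biodynamic",
]

_TINY_RATE = 1e-8
_TINY_YIELD = 1e-8


class InsufficientDataError(ValueError):
    """Too few usable observations, or a degenerate (constant/all-zero) series."""


class UndefinedVarianceError(ValueError):
    """R² is undefined because the observed series has zero variance."""


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration.

    ``censoring_policy`` controls how below-detection-limit points enter the
    fit: ``"include"`` keeps them as zeros (the way such points appear in
    published kinetics), ``"exclude"`` drops them.
    """

    max_iterations: int = 1000
    step_tolerance: float = 1e-8
    residual_tolerance: float = 1e-8
    strategy: str = "staged"
    censoring_policy: str = "include"
    clamp_predictions: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.step_tolerance <= 0 or self.residual_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.strategy not in ("staged", "joint"):
            raise ValueError(f"strategy must be 'staged' or 'joint', got {self.strategy!r}")
        if self.censoring_policy not in ("include", "exclude"):
            raise ValueError("censoring_policy must be 'include' or 'exclude'")


@dataclass(frozen=True)
class GompertzFit:
    """One fitted sigmoid with diagnostics."""

    params: GompertzParams
    sse: float
    r_squared: float
    n_iterations: int
    converged: bool


@dataclass(frozen=True)
class FitResult:
    """Fitted biodynamic parameter set with per-compound diagnostics.

    ``sse`` and ``r_squared`` are keyed by compound plus a ``"total"`` SSE.
    ``stage_errors`` records compounds whose stage failed (degenerate data);
    their parameter slots hold a flat-zero placeholder curve and
    ``converged`` is False.
    """

    params: BiodynamicParameters
    sse: dict[str, float]
    r_squared: dict[str, float]
    n_iterations: int
    converged: bool
    strategy: str
    stage_errors: dict[str, str] = field(default_factory=dict)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same shape")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedVarianceError("observed series is constant; R² undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _gomp(a: float, mu: float, tc: float, t: np.ndarray) -> np.ndarray:
    # inner exp may overflow for trial parameters; the limit (value 0) is exact
    with np.errstate(over="ignore"):
        return a * np.exp(-np.exp(-mu * (t - tc)))


def _gompertz_init(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Initial (A, μ, t_c): max value, max-slope identity, max-slope time."""
    a0 = float(values.max())
    slopes = np.diff(values) / np.diff(times)
    k = int(np.argmax(slopes))
    tc0 = float(0.5 * (times[k] + times[k + 1]))
    smax = float(slopes[k])
    # Gompertz max-slope identity: slope_max = μ·A/e  ⇒  μ0 = e·slope_max/A
    mu0 = math.e * smax / a0 if smax > 0 else 1.0 / max(times[-1] - times[0], 1.0)
    mu0 = max(mu0, 10 * _TINY_RATE)
    return np.array([a0, mu0, tc0])


def _check_series(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size < 4:
        raise InsufficientDataError(f"need at least 4 finite observations, got {t.size}")
    if np.ptp(v) == 0.0:
        raise InsufficientDataError("observations are constant; sigmoid is unidentifiable")
    if v.max() <= 0.0:
        raise InsufficientDataError("observations contain no positive values")
    return t, v


def _lsq(resid_fn, x0, bounds, settings: FitSettings):
    return least_squares(
        resid_fn,
        x0,
        bounds=bounds,
        method="trf",
        xtol=settings.step_tolerance,
        ftol=settings.residual_tolerance,
        gtol=1e-12,
        max_nfev=settings.max_iterations,
    )


def fit_gompertz(times, values, settings: FitSettings | None = None) -> GompertzFit:
    """Fit a single Gompertz curve ``A·exp(−exp(−μ(t−t_c)))`` to one series."""
    settings = settings or FitSettings()
    t, v = _check_series(times, values)
    x0 = _gompertz_init(t, v)

    def resid(x):
        return _gomp(x[0], x[1], x[2], t) - v

    res = _lsq(resid, x0, ([0.0, _TINY_RATE, -np.inf], [np.inf, np.inf, np.inf]), settings)
    params = GompertzParams(float(res.x[0]), float(res.x[1]), float(res.x[2]))
    pred = gompertz_value(t, params)
    sse = float(np.sum((pred - v) ** 2))
    try:
        r2 = r_squared(v, pred)
    except UndefinedVarianceError:  # pragma: no cover - excluded by _check_series
        r2 = math.nan
    return GompertzFit(params, sse, r2, int(res.nfev), bool(res.status > 0))


_ZERO_CURVE = GompertzParams(0.0, 1.0, 0.0)


def _compound_mask(series: KineticsSeries, name: str, settings: FitSettings) -> np.ndarray:
    if settings.censoring_policy == "exclude":
        return ~series.censored[name]
    return np.ones(series.times.size, dtype=bool)


def _clamp_pred(pred: np.ndarray, settings: FitSettings) -> np.ndarray:
    return np.maximum(pred, 0.0) if settings.clamp_predictions else pred


def _series_limit(series: KineticsSeries, name: str, settings: FitSettings) -> float:
    """Detection limit applied to reported predictions, 0 when not applicable."""
    if settings.censoring_policy != "include" or series.detection_limits is None:
        return 0.0
    return float(series.detection_limits.get(name, 0.0))


def _report_pred(pred: np.ndarray, limit: float, settings: FitSettings) -> np.ndarray:
    """What the assay would report for a model prediction: clamped, censored."""
    out = _clamp_pred(pred, settings)
    if limit > 0.0:
        out = np.where(out < limit, 0.0, out)
    return out


def _yield_init(consumed_end: float, product_end: float, fallback: float) -> float:
    if consumed_end > 1e-9 and product_end > 0:
        return max(product_end / consumed_end, 10 * _TINY_YIELD)
    return fallback


def _staged(series: KineticsSeries, settings: FitSettings):
    """Run the three fitting stages; returns params pieces + diagnostics."""
    stage_errors: dict[str, str] = {}
    nfev = 0
    fits: dict[str, GompertzParams] = {}
    converged: dict[str, bool] = {}

    # stage 1: DPA and Cry are plain sigmoids (seen through the assay operator)
    for name in ("dpa", "cry"):
        mask = _compound_mask(series, name, settings)
        t_s, v_s = series.times[mask], series.compound(name)[mask]
        limit = _series_limit(series, name, settings)
        try:
            t_s, v_s = _check_series(t_s, v_s)
            x0 = _gompertz_init(t_s, v_s)

            def resid_s(x, t=t_s, v=v_s, lim=limit):
                return _report_pred(_gomp(x[0], x[1], x[2], t), lim, settings) - v

            res = _lsq(resid_s, x0, ([0.0, _TINY_RATE, -np.inf], [np.inf] * 3), settings)
            fits[name] = GompertzParams(*map(float, res.x))
            converged[name] = bool(res.status > 0)
            nfev += int(res.nfev)
        except InsufficientDataError as err:
            stage_errors[name] = f"{name} stage: {err}"
            fits[name] = _ZERO_CURVE
            converged[name] = False

    # stage 2: biomass triple + Y_DPA/X with the fitted DPA curve inserted
    mask = _compound_mask(series, "biomass", settings)
    t_b, v_b = series.times[mask], series.biomass[mask]
    dpa_b = gompertz_value(t_b, fits["dpa"])
    y_dx = 0.02
    try:
        _check_series(t_b, v_b)
        x0g = _gompertz_init(t_b, v_b)
        consumed = max(x0g[0] - v_b[-1], 0.0)
        y0 = _yield_init(consumed, float(dpa_b[-1]), 0.02)

        limit_b = _series_limit(series, "biomass", settings)

        def resid_b(x):
            pred = _gomp(x[0], x[1], x[2], t_b) - dpa_b / x[3]
            return _report_pred(pred, limit_b, settings) - v_b

        res = _lsq(
            resid_b,
            np.array([*x0g, y0]),
            ([0.0, _TINY_RATE, -np.inf, _TINY_YIELD], [np.inf] * 4),
            settings,
        )
        fits["biomass"] = GompertzParams(*map(float, res.x[:3]))
        y_dx = float(res.x[3])
        converged["biomass"] = bool(res.status > 0)
        nfev += int(res.nfev)
    except InsufficientDataError as err:
        stage_errors["biomass"] = f"biomass stage: {err}"
        fits["biomass"] = _ZERO_CURVE
        converged["biomass"] = False

    # stage 3: PHB triple + Y_DPA/PHB + Y_Cry/PHB with DPA and Cry inserted
    mask = _compound_mask(series, "phb", settings)
    t_p, v_p = series.times[mask], series.phb[mask]
    dpa_p = gompertz_value(t_p, fits["dpa"])
    cry_p = gompertz_value(t_p, fits["cry"])
    y_dp, y_cp = 0.5, 1.0
    try:
        _check_series(t_p, v_p)
        x0g = _gompertz_init(t_p, v_p)
        consumed = max(x0g[0] - v_p[-1], 0.0)
        y1 = _yield_init(consumed, float(dpa_p[-1]), 0.5)
        y2 = _yield_init(consumed, float(cry_p[-1]), 1.0)

        limit_p = _series_limit(series, "phb", settings)

        def resid_p(x):
            pred = _gomp(x[0], x[1], x[2], t_p) - dpa_p / x[3] - cry_p / x[4]
            return _report_pred(pred, limit_p, settings) - v_p

        res = _lsq(
            resid_p,
            np.array([*x0g, y1, y2]),
            ([0.0, _TINY_RATE, -np.inf, _TINY_YIELD, _TINY_YIELD], [np.inf] * 5),
            settings,
        )
        fits["phb"] = GompertzParams(*map(float, res.x[:3]))
        y_dp, y_cp = float(res.x[3]), float(res.x[4])
        converged["phb"] = bool(res.status > 0)
        nfev += int(res.nfev)
    except InsufficientDataError as err:
        stage_errors["phb"] = f"phb stage: {err}"
        fits["phb"] = _ZERO_CURVE
        converged["phb"] = False

    params = BiodynamicParameters(
        biomass=fits["biomass"],
        phb=fits["phb"],
        dpa=fits["dpa"],
        cry=fits["cry"],
        yields=YieldCoefficients(y_dx, y_dp, y_cp),
        label=series.label,
    )
    return params, stage_errors, nfev, all(converged.values())


def _pack(params: BiodynamicParameters) -> np.ndarray:
    vec = []
    for name in COMPOUNDS:
        g = params.gompertz(name)
        vec += [g.asymptote, g.rate, g.critical_time]
    y = params.yields
    vec += [y.dpa_from_biomass, y.dpa_from_phb, y.cry_from_phb]
    return np.array(vec)


def _unpack(x: np.ndarray, label: str) -> BiodynamicParameters:
    triples = {
        name: GompertzParams(float(x[3 * i]), float(x[3 * i + 1]), float(x[3 * i + 2]))
        for i, name in enumerate(COMPOUNDS)
    }
    return BiodynamicParameters(
        biomass=triples["biomass"],
        phb=triples["phb"],
        dpa=triples["dpa"],
        cry=triples["cry"],
        yields=YieldCoefficients(float(x[12]), float(x[13]), float(x[14])),
        label=label,
    )


def _predict(
    params: BiodynamicParameters,
    series: KineticsSeries,
    settings: FitSettings,
) -> dict[str, np.ndarray]:
    """Reported model predictions on the series grid (clamped + censored)."""
    times = series.times
    dpa = gompertz_value(times, params.dpa)
    cry = gompertz_value(times, params.cry)
    biomass = gompertz_value(times, params.biomass) - dpa / params.yields.dpa_from_biomass
    phb = (
        gompertz_value(times, params.phb)
        - dpa / params.yields.dpa_from_phb
        - cry / params.yields.cry_from_phb
    )
    raw = {"biomass": biomass, "phb": phb, "dpa": dpa, "cry": cry}
    return {
        name: _report_pred(raw[name], _series_limit(series, name, settings), settings)
        for name in COMPOUNDS
    }


def _joint(series: KineticsSeries, init: BiodynamicParameters, settings: FitSettings):
    masks = {name: _compound_mask(series, name, settings) for name in COMPOUNDS}

    def resid(x):
        p = _unpack(x, series.label)
        pred = _predict(p, series, settings)
        return np.concatenate(
            [pred[name][masks[name]] - series.compound(name)[masks[name]] for name in COMPOUNDS]
        )

    lower = np.array([0.0, _TINY_RATE, -np.inf] * 4 + [_TINY_YIELD] * 3)
    x0 = np.maximum(_pack(init), lower + 1e-12)
    res = _lsq(resid, x0, (lower, np.full(15, np.inf)), settings)
    return _unpack(res.x, series.label), int(res.nfev), bool(res.status > 0)


def fit_biodynamic(series: KineticsSeries, settings: FitSettings | None = None) -> FitResult:
    """Estimate the full fifteen-parameter set from one kinetics series.

    Runs the staged strategy; when ``settings.strategy == "joint"`` the staged
    solution seeds one refinement over all parameters. Degenerate stages (e.g.
    a constant-zero compound) are recorded in ``stage_errors`` and leave a
    flat-zero placeholder curve for that compound.
    """
    settings = settings or FitSettings()
    for name in COMPOUNDS:
        if getattr(series, name, None) is None:
            raise ValueError(f"series is missing compound {name!r}")

    params, stage_errors, nfev, converged = _staged(series, settings)
    strategy = settings.strategy
    if strategy == "joint":
        if stage_errors:
            # refine only when every stage produced a usable starting point
            strategy = "staged"
        else:
            params, nfev_j, conv_j = _joint(series, params, settings)
            nfev += nfev_j
            converged = converged and conv_j

    masks = {name: _compound_mask(series, name, settings) for name in COMPOUNDS}
    pred = _predict(params, series, settings)
    sse: dict[str, float] = {}
    r2: dict[str, float] = {}
    for name in COMPOUNDS:
        obs = series.compound(name)[masks[name]]
        prd = pred[name][masks[name]]
        sse[name] = float(np.sum((prd - obs) ** 2))
        try:
            r2[name] = r_squared(obs, prd)
        except (UndefinedVarianceError, ValueError):
            r2[name] = math.nan
    sse["total"] = float(sum(sse[name] for name in COMPOUNDS))

    return FitResult(
        params=params,
        sse=sse,
        r_squared=r2,
        n_iterations=nfev,
        converged=converged and not stage_errors,
        strategy=strategy,
        stage_errors=stage_errors,
    )


def with_settings(settings: FitSettings | None = None, **changes) -> FitSettings:
    """Convenience: derive a FitSettings from defaults with keyword overrides."""
    return replace(settings or FitSettings(), **changes)
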