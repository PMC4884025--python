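"""Published parameter sets for the four validation fermentations F1–F4.

The four batch cultures share medium recipe and operating conditions and differ
only in initial glucose/soybean-meal load (C:N held at 7:1). Concentrations in
g/L, rates in 1/h, times in hours.
"""

from __future__ import annotations

from .model_core import BiodynamicParameters, GompertzParams, YieldCoefficients

__all__ = ["PRESETS", "preset"]


def _ps(label, glucose, soybean, x, p, d, c, ydx, ydp, ycp) -> BiodynamicParameters:
    return BiodynamicParameters(
        biomass=GompertzParams(*x),
        phb=GompertzParams(*p),
        dpa=GompertzParams(*d),
        cry=GompertzParams(*c),
        yields=YieldCoefficients(ydx, ydp, ycp),
        label=label,
        initial_glucose=glucose,
        initial_soybean=soybean,
    )


PRESETS: dict[str, BiodynamicParameters] = {
    "F1": _ps("F1", 25.1, 4.4,
              (5.58, 0.78, 4.54), (0.61, 1.07, 8.46),
              (0.17, 0.66, 14.12), (0.19, 0.20, 14.88),
              0.025, 1.02, 0.19),
    "F2": _ps("F2", 34.74, 14.73,
              (8.58, 1.06, 4.12), (0.71, 0.89, 7.90),
              (0.18, 0.72, 12.94), (0.31, 0.42, 12.77),
              0.030, 0.43, 2.53),
    "F3": _ps("F3", 44.42, 25.05,
              (10.09, 0.90, 4.95), (1.16, 0.95, 8.39),
              (0.16, 0.59, 15.77), (0.53, 0.40, 14.96),
              0.018, 0.21, 4.92),
    "F4": _ps("F4", 54.1, 35.37,
              (13.07, 0.86, 6.58), (1.41, 1.02, 8.88),
              (0.16, 0.65, 14.32), (0.78, 0.33, 16.46),
              0.0093, 0.15, 5.83),
}


def preset(label: str) -> BiodynamicParameters:
    """Look up one of the bundled fermentation parameter sets by label."""
    try:
        return PRESETS[label]
    except KeyError:
        raise KeyError(f"unknown preset {label!r}; available: {sorted(PRESETS)}") from None
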