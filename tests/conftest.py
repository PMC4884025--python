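import numpy as np
import pytest

from btbiodyn.estimation import FitSettings, fit_biodynamic
from btbiodyn.presets import PRESETS
from btbiodyn.synthetic_data import (
    DEFAULT_SEED,
    StudyDesign,
    generate_kinetics,
    generate_study_set,
)

N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def presets():
    return PRESETS


@pytest.fixture(scope="session")
def f1():
    return PRESETS["F1"]


@pytest.fixture(scope="session")
def noise_free_design():
    """Exact clamped model output: zero noise, no detection censoring."""
    return StudyDesign(
        noise_relative_sd=0.0,
        detection_limits={name: 0.0 for name in ("biomass", "phb", "dpa", "cry")},
        seed=DEFAULT_SEED,
    )


@pytest.fixture(scope="session")
def recovery_fits():
    """Staged fits of 20 noisy replicate studies per fermentation.

    Seeds are fixed offsets of the package default seed; each replicate uses
    the default study design (2-h grid over 0-20 h, 5% multiplicative noise,
    replicate averaging, detection-limit censoring).
    """
    out = {}
    for label, truth in PRESETS.items():
        fits = []
        for i in range(N_RECOVERY_SEEDS):
            series = generate_kinetics(truth, StudyDesign(seed=DEFAULT_SEED + i))
            fits.append(fit_biodynamic(series, FitSettings()))
        out[label] = fits
    return out


@pytest.fixture(scope="session")
def study_fits():
    """Staged fits of one default four-fermentation synthetic study."""
    series = generate_study_set(StudyDesign(seed=DEFAULT_SEED))
    return {label: fit_biodynamic(s, FitSettings()) for label, s in series.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
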