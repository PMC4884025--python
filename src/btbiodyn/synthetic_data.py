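"""Synthetic fermentation kinetics with the study's sampling and noise structure.

The generator emulates batch cultures sampled every 2 h over ~20 h. Each
observation is the mean of a compound-specific number of technical replicates
(quadruplicate for PHB and Cry, duplicate for DPA, single counts for biomass),
each replicate carrying multiplicative Gaussian noise ``value·(1 + ε)``,
ε ~ N(0, sd). Averaged values below the assay's detection limit are recorded
as exactly 0 and flagged censored — mirroring the early-culture windows in
which PHB (first ~6 h) and DPA/Cry (first ~10–14 h) are undetectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import COMPOUNDS, BiodynamicParameters, simulate
from .presets import PRESETS

__all__ = [
    "DEFAULT_DETECTION_LIMITS",
    "DEFAULT_REPLICATES",
    "DEFAULT_SEED",
    "StudyDesign",
    "KineticsSeries",
    "generate_kinetics",
    "generate_study_set",
]

#: assay detection limits (g/L) reproducing the reported not-detected windows
DEFAULT_DETECTION_LIMITS = {"biomass": 0.01, "phb": 0.05, "dpa": 0.01, "cry": 0.02}
#: technical replicates averaged per reported value
DEFAULT_REPLICATES = {"biomass": 1, "phb": 4, "dpa": 2, "cry": 4}
DEFAULT_SEED = 20141114


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule, noise model, detection limits and seed of one study."""

    t_start: float = 0.0
    t_end: float = 20.0
    sampling_interval: float = 2.0
    noise_relative_sd: float = 0.05
    detection_limits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_LIMITS)
    )
    replicates: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_relative_sd < 0:
            raise ValueError("noise_relative_sd must be >= 0")
        for name, lim in self.detection_limits.items():
            if lim < 0:
                raise ValueError(f"detection limit for {name} must be >= 0")
        for name, rep in self.replicates.items():
            if rep < 1:
                raise ValueError(f"replicate count for {name} must be >= 1")

    def times(self) -> np.ndarray:
        """The sampling grid t_start, t_start+Δ, … ≤ t_end."""
        n = int(math.floor((self.t_end - self.t_start) / self.sampling_interval + 1e-9))
        return self.t_start + self.sampling_interval * np.arange(n + 1)


@dataclass
class KineticsSeries:
    """Observed (or generated) concentrations of the four compounds over time.

    Values are non-negative; ``censored[compound]`` marks points recorded as 0
    because they fell below the detection limit — those values are exactly 0.
    """

    times: np.ndarray
    biomass: np.ndarray
    phb: np.ndarray
    dpa: np.ndarray
    cry: np.ndarray
    censored: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""
    #: detection limits (g/L) under which values were recorded as 0, if known
    detection_limits: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        if n == 0:
            raise ValueError("times must be non-empty")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in COMPOUNDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} shape {arr.shape} != times shape {self.times.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} observations must be >= 0")
        if not self.censored:
            self.censored = {name: np.zeros(n, dtype=bool) for name in COMPOUNDS}
        for name in COMPOUNDS:
            flags = np.asarray(self.censored.get(name, np.zeros(n, bool)), dtype=bool)
            if flags.shape != self.times.shape:
                raise ValueError(f"censored[{name!r}] shape mismatch")
            if np.any(getattr(self, name)[flags] != 0.0):
                raise ValueError(f"censored {name} values must be exactly 0")
            self.censored[name] = flags

    def compound(self, name: str) -> np.ndarray:
        if name not in COMPOUNDS:
            raise KeyError(f"unknown compound {name!r}")
        return getattr(self, name)

    def to_frame(self):
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


def generate_kinetics(
    params: BiodynamicParameters,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
) -> KineticsSeries:
    """Draw one noisy, censored kinetics series from the model.

    The clamped model trajectory is evaluated on the design grid; per point,
    ``replicates[compound]`` noisy draws are averaged, negatives clamped to 0,
    and averages below the detection limit recorded as 0 and flagged. With the
    same seed the output is bitwise identical.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    times = design.times()
    traj = simulate(params, times, clamp=True)

    observed: dict[str, np.ndarray] = {}
    censored: dict[str, np.ndarray] = {}
    for name in COMPOUNDS:
        true = traj.compound(name)
        reps = design.replicates.get(name, 1)
        eps = rng.normal(0.0, design.noise_relative_sd, size=(reps, times.size))
        mean = (true[None, :] * (1.0 + eps)).mean(axis=0)
        mean = np.maximum(mean, 0.0)
        limit = design.detection_limits.get(name, 0.0)
        below = mean < limit
        mean[below] = 0.0
        observed[name] = mean
        censored[name] = below
    return KineticsSeries(
        times=times,
        biomass=observed["biomass"],
        phb=observed["phb"],
        dpa=observed["dpa"],
        cry=observed["cry"],
        censored=censored,
        label=params.label,
        detection_limits=dict(design.detection_limits),
    )


def generate_study_set(design: StudyDesign) -> dict[str, KineticsSeries]:
    """One noisy series per bundled fermentation F1–F4.

    Per-label generators are spawned deterministically from ``design.seed``, so
    the labels differ from each other but the whole set is reproducible.
    """
    children = np.random.SeedSequence(design.seed).spawn(len(PRESETS))
    out: dict[str, KineticsSeries] = {}
    for child, (label, params) in zip(children, sorted(PRESETS.items())):
        out[label] = generate_kinetics(params, design, rng=np.random.default_rng(child))
    return out
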