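"""Derived fermentation quantities: unit conversions, phase timing, yield bound.

* Cell counts are converted to biomass with the per-cell dry mass of
  *B. thuringiensis* (2.3 pg/cell).
* Storage-compound content is conventionally reported as percent of dry cell
  weight, from the maximum compound and biomass concentrations of a culture.
* Culture phases (lag → vegetative growth → transition → sporulation) are
  timed by a closed-form onset criterion on the Gompertz production terms: a
  compound's phase "starts" when its production term crosses a small fraction
  f of the asymptote, at t = t_c − ln(−ln f)/μ. Biomass onset ends the lag
  phase, PHB onset ends vegetative growth (transition start), and DPA onset —
  the endospore proxy — marks sporulation.
* A stoichiometric upper bound on the biomass-per-glucose yield follows from a
  carbon balance with every substrate carbon fixed into biomass (no CO₂): the
  ratio of the C-mol masses of biomass and substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_core import BiodynamicParameters, GompertzParams

__all__ = [
    "ATOMIC_MASSES",
    "CELL_MASS_G",
    "BIOMASS_COMPOSITION",
    "GLUCOSE_COMPOSITION",
    "PhaseBoundaries",
    "ElementalComposition",
    "cfu_to_biomass",
    "percent_dry_weight",
    "gompertz_onset_time",
    "phase_boundaries",
    "max_anaerobic_yield",
    "check_yield_bound",
]

#: IUPAC standard atomic weights, rounded to 3 decimals (g/mol)
ATOMIC_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

#: dry mass of one B. thuringiensis cell, grams (2.3 pg)
CELL_MASS_G = 2.3e-12
_CM3_PER_L = 1000.0


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental formula normalized to one carbon atom (C-mol basis)."""

    hydrogen: float
    oxygen: float = 0.0
    nitrogen: float = 0.0
    carbon: float = 1.0

    def __post_init__(self) -> None:
        if self.carbon != 1.0:
            raise ValueError("composition must be carbon-normalized (carbon subscript 1)")
        for name in ("hydrogen", "oxygen", "nitrogen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} subscript must be >= 0")

    @classmethod
    def from_counts(cls, c: float, h: float, o: float = 0.0, n: float = 0.0):
        """Normalize an arbitrary C_c H_h O_o N_n formula to one carbon."""
        if c <= 0:
            raise ValueError("carbon count must be positive")
        return cls(hydrogen=h / c, oxygen=o / c, nitrogen=n / c)

    def cmol_mass(self) -> float:
        """Mass of one C-mol (g)."""
        return (
            ATOMIC_MASSES["C"] * self.carbon
            + ATOMIC_MASSES["H"] * self.hydrogen
            + ATOMIC_MASSES["O"] * self.oxygen
            + ATOMIC_MASSES["N"] * self.nitrogen
        )


#: generic microbial biomass CH1.8O0.5N0.2 and glucose as CH2O (one C-mol)
BIOMASS_COMPOSITION = ElementalComposition(hydrogen=1.8, oxygen=0.5, nitrogen=0.2)
GLUCOSE_COMPOSITION = ElementalComposition(hydrogen=2.0, oxygen=1.0)


@dataclass(frozen=True)
class PhaseBoundaries:
    """Phase onset times (h): end of lag, of vegetative growth, of transition."""

    lag_end: float
    vegetative_end: float
    transition_end: float
    onset_fraction: float

    def __post_init__(self) -> None:
        if not (self.lag_end <= self.vegetative_end <= self.transition_end):
            raise ValueError(
                "phase boundaries out of order: "
                f"{self.lag_end:.3f}, {self.vegetative_end:.3f}, {self.transition_end:.3f} h"
            )


def cfu_to_biomass(count: float) -> float:
    """Convert a cell count (CFU/cm³) to biomass concentration (g/L)."""
    if count < 0:
        raise ValueError("cell count must be >= 0")
    return count * CELL_MASS_G * _CM3_PER_L


def percent_dry_weight(compound_max: float, biomass_max: float) -> float:
    """Compound content as percent of dry cell weight: 100·max/max_biomass."""
    if biomass_max <= 0:
        raise ValueError("biomass_max must be positive")
    return 100.0 * compound_max / biomass_max


def gompertz_onset_time(p: GompertzParams, fraction: float) -> float:
    """Time at which a Gompertz term reaches ``fraction`` of its asymptote.

    Closed form t = t_c − ln(−ln f)/μ; at f = 1/e this is the critical time.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("onset fraction must lie strictly between 0 and 1")
    return p.critical_time - math.log(-math.log(fraction)) / p.rate


def phase_boundaries(
    params: BiodynamicParameters, onset_fraction: float = 0.05
) -> PhaseBoundaries:
    """Closed-form culture phase boundaries from a fitted parameter set.

    The biomass production onset ends the lag phase, the PHB onset ends
    vegetative growth, and the DPA onset (sporulation start) ends the
    transition phase.
    """
    return PhaseBoundaries(
        lag_end=gompertz_onset_time(params.biomass, onset_fraction),
        vegetative_end=gompertz_onset_time(params.phb, onset_fraction),
        transition_end=gompertz_onset_time(params.dpa, onset_fraction),
        onset_fraction=onset_fraction,
    )


def max_anaerobic_yield(
    biomass: ElementalComposition = BIOMASS_COMPOSITION,
    substrate: ElementalComposition = GLUCOSE_COMPOSITION,
) -> float:
    """Stoichiometric ceiling on Y_X/S (g biomass / g substrate).

    Carbon balance with all substrate carbon routed to biomass and no CO₂
    formation: the ratio of C-mol masses. Any respiring culture must stay
    below this bound; measured yields above it mean the substrate considered
    is not the limiting one.
    """
    return biomass.cmol_mass() / substrate.cmol_mass()


def check_yield_bound(y_xs: float, bound: float | None = None) -> str:
    """Classify a measured Y_X/S against a stoichiometric bound.

    Returns ``"within"`` (y ≤ bound, closed) or ``"exceeds"``. The default
    bound is the carbon-balance ceiling for generic biomass on glucose.
    """
    if y_xs < 0:
        raise ValueError("yield must be >= 0")
    if bound is None:
        bound = max_anaerobic_yield()
    return "within" if y_xs <= bound else "exceeds"
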