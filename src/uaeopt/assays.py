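"""Spectrophotometric assay quantification for extract characterization.

Implements the four response calculations used to characterize
ultrasound-assisted extracts:

* total phenolic content (Folin-Ciocalteu, gallic-acid calibration,
  mg GAE / g dry weight),
* antioxidant activity (DPPH radical scavenging, % inhibition),
* total anthocyanin content (pH-differential method at 510/700 nm,
  mg / g dry weight),
* total flavonoid content (AlCl3 colorimetry, quercetin calibration,
  mg QE / g dry weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "AbsorbanceSet",
    "AnthocyaninConstants",
    "fit_calibration",
    "invert_absorbance",
    "total_phenolic",
    "dpph_inhibition",
    "anthocyanin_content",
    "total_flavonoid",
    "DEFAULT_SOLVENT_TO_SOLID_ML_PER_G",
]

#: Extraction solvent-to-solid ratio (mL solvent per g dry sample) used to
#: convert a solution concentration (mg/L) to a per-gram-dry-weight yield.
DEFAULT_SOLVENT_TO_SOLID_ML_PER_G = 25.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares calibration line A = slope * c + intercept."""

    slope: float
    intercept: float
    r_squared: float
    standard_name: str = "gallic acid"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class AbsorbanceSet:
    """pH-differential absorbance readings (510 and 700 nm at pH 1.0/4.5)."""

    a510_ph1: float
    a700_ph1: float
    a510_ph45: float
    a700_ph45: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        readings = (self.a510_ph1, self.a700_ph1, self.a510_ph45, self.a700_ph45)
        if any(not np.isfinite(a) or a < 0 for a in readings):
            raise ValueError("absorbance readings must be finite and >= 0")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")


@dataclass(frozen=True)
class AnthocyaninConstants:
    """Physical constants of the pH-differential quantification.

    Defaults are for cyanidin-3-glucoside: molecular weight 449.2 g/mol
    and molar extinction coefficient 26900 L/(cm*mol) at 1 cm path.
    """

    molecular_weight: float = 449.2
    extinction_coefficient: float = 26900.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if min(self.molecular_weight, self.extinction_coefficient,
               self.path_length) <= 0:
            raise ValueError("anthocyanin constants must be strictly positive")


def fit_calibration(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    standard_name: str = "gallic acid",
) -> CalibrationCurve:
    """Ordinary least-squares calibration line through standard readings."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape:
        raise ValueError("concentrations and absorbances must have equal length")
    if c.size < 2:
        raise ValueError("at least two calibration points are required")
    if np.ptp(c) == 0:
        raise ValueError("all concentrations identical; line is underdetermined")
    res = stats.linregress(c, a)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standard_name=standard_name,
    )


def invert_absorbance(curve: CalibrationCurve, absorbance: float) -> float:
    """Concentration (mg/mL) corresponding to an absorbance reading."""
    return (absorbance - curve.intercept) / curve.slope


def total_phenolic(concentration: float, volume_ml: float, mass_g: float) -> float:
    """Total phenolic content, mg GAE / g d.w.: YPC = c * V / w."""
    if volume_ml <= 0 or mass_g <= 0:
        raise ValueError("volume and mass must be positive")
    return concentration * volume_ml / mass_g


def dpph_inhibition(a_blank: float, a_sample: float) -> float:
    """DPPH radical scavenging, percent: (A_blank - A_sample)/A_blank * 100."""
    if a_blank <= 0:
        raise ValueError("blank absorbance must be positive")
    return (a_blank - a_sample) / a_blank * 100.0


def anthocyanin_content(
    readings: AbsorbanceSet,
    constants: AnthocyaninConstants = AnthocyaninConstants(),
    extract_volume_l: float = DEFAULT_SOLVENT_TO_SOLID_ML_PER_G / 1000.0,
    dry_mass_g: float = 1.0,
) -> float:
    """Total anthocyanin content, mg / g dry weight (pH-differential).

    The corrected absorbance A = (A510 - A700)|pH1 - (A510 - A700)|pH4.5
    gives the pigment solution concentration
    ``c [mg/L] = A * mw * DF * 1000 / (eps * l)`` which is scaled to the
    dry sample mass by the extract volume.  A negative corrected
    absorbance (possible at near-zero pigment due to noise) is clamped
    to zero with a warning.
    """
    if dry_mass_g <= 0 or extract_volume_l <= 0:
        raise ValueError("dry mass and extract volume must be positive")
    a = (readings.a510_ph1 - readings.a700_ph1) - (
        readings.a510_ph45 - readings.a700_ph45
    )
    if a < 0:
        warnings.warn(
            f"negative corrected absorbance {a:.4g} clamped to 0 "
            "(near-zero pigment)", stacklevel=2,
        )
        a = 0.0
    conc_mg_per_l = (
        a
        * constants.molecular_weight
        * readings.dilution_factor
        * 1000.0
        / (constants.extinction_coefficient * constants.path_length)
    )
    return conc_mg_per_l * extract_volume_l / dry_mass_g


def total_flavonoid(concentration: float, volume_ml: float, mass_g: float) -> float:
    """Total flavonoid content, mg QE / g d.w. (same form as total_phenolic,
    with the quercetin calibration curve supplying the concentration)."""
    if volume_ml <= 0 or mass_g <= 0:
        raise ValueError("volume and mass must be positive")
    return concentration * volume_ml / mass_g
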