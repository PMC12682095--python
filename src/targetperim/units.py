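"""Perimetric units and reference fields.

The perimetric decibel scale used here follows the Humphrey/Compass
convention: 100% Weber contrast is written as 25 dB, and each decibel is a
0.1 log-unit step in contrast.  Higher dB therefore means a dimmer stimulus,
and an eye with higher sensitivity can see higher-dB stimuli.

The normative "hill of vision" is a parametric stand-in for a device
normative database: a foveal peak that falls off linearly with eccentricity
and declines linearly with age past a reference age.  An individual's
*reference field* is this normative surface shifted by their general height
(GH), the eye's overall sensitivity offset (negative when globally
depressed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

# dB value assigned to 100% Weber contrast on this device convention.
DB_AT_FULL_CONTRAST = 25.0


class FieldLocation(NamedTuple):
    """A visual-field point in degrees, fovea at the origin, right-eye format
    (positive x toward the blind spot)."""

    x: float
    y: float

    def distance_to(self, other: "FieldLocation") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x, self.y)


def db_to_weber(level_db: float) -> float:
    """Percent Weber contrast of a stimulus at ``level_db`` decibels.

    25 dB -> 100%; 1 dB lower -> 0.1 log unit higher contrast.
    """
    if not math.isfinite(level_db):
        raise ValueError(f"stimulus level must be finite, got {level_db}")
    return 100.0 * 10.0 ** ((DB_AT_FULL_CONTRAST - level_db) / 10.0)


def weber_to_db(contrast_pct: float) -> float:
    """Decibel level of a stimulus with ``contrast_pct`` percent Weber contrast."""
    if not contrast_pct > 0:
        raise ValueError(f"Weber contrast must be positive, got {contrast_pct}")
    return DB_AT_FULL_CONTRAST - 10.0 * math.log10(contrast_pct / 100.0)


def stimulus_db_for_offset(ref_threshold_db: float, offset_db: float) -> float:
    """Suprathreshold stimulus level for a reference threshold and offset.

    The stimulus is presented ``offset_db`` decibels *brighter* (higher
    contrast, lower dB) than the expected threshold, e.g. reference 30 dB and
    offset 5 dB give a 25 dB stimulus.
    """
    if offset_db < 0:
        raise ValueError(f"offset must be non-negative, got {offset_db}")
    return ref_threshold_db - offset_db


class EccentricityError(ValueError):
    """Location outside the range covered by the normative model."""


@dataclass(frozen=True)
class NormativeModel:
    """Parametric age-corrected normal threshold surface.

    Radially symmetric hill of vision: ``foveal_db`` at the fovea, falling by
    ``eccentricity_slope`` dB per degree of eccentricity, and by ``age_slope``
    dB per year beyond ``age_reference``.  Valid out to ``max_eccentricity``
    (the usual limit of perimetric normative data).
    """

    foveal_db: float = 33.0
    eccentricity_slope: float = 0.25  # dB per degree
    age_reference: float = 45.0  # years
    age_slope: float = 0.06  # dB of decline per year past the reference age
    max_eccentricity: float = 30.0  # degrees

    def threshold(self, loc: FieldLocation, age: float, extrapolate: bool = False) -> float:
        """Mean normal threshold in dB at ``loc`` for an eye of ``age`` years.

        Locations beyond ``max_eccentricity`` raise unless ``extrapolate`` is
        set (used by ground-truth simulation, where a real eye still responds
        beyond the normative-data limit).
        """
        ecc = FieldLocation(*loc).eccentricity
        if ecc > self.max_eccentricity + 1e-9 and not extrapolate:
            raise EccentricityError(
                f"location {tuple(loc)} is {ecc:.1f} deg from the fovea, beyond "
                f"the {self.max_eccentricity:.0f} deg normative limit"
            )
        age_loss = self.age_slope * max(0.0, age - self.age_reference)
        return self.foveal_db - self.eccentricity_slope * ecc - age_loss


@dataclass(frozen=True)
class ReferenceField:
    """Expected thresholds for a healthy eye of the same age and GH:
    the normative surface shifted by the general height."""

    normative: NormativeModel
    gh: float  # dB, signed; negative when the eye is globally depressed
    age: float  # years

    def __call__(self, loc: FieldLocation) -> float:
        return self.normative.threshold(loc, self.age) + self.gh
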