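"""Simulated observers.

A simulated observer stands in for a participant seated at the perimeter:
it owns a ground-truth sensitivity field (what the eye can actually see) and
answers each stimulus presentation with a stochastic yes/no drawn from a
frequency-of-seeing curve.  The ground-truth fields emulate the features of
real eyes that matter to the algorithms here:

* a hill-of-vision normative surface shifted by a uniform general height;
* an absolute physiological blind spot (elliptical, sensitivity -inf);
* angioscotomata — shallow troughs along vessel-like arcs near the disc;
* glaucomatous arcuate defects occupying a band of nerve-fibre-bundle
  entry angles over a range of distances from the blind spot.

The response rule is the standard cumulative-Gaussian frequency-of-seeing
model with false-positive and false-negative asymptotes:
``P(seen) = fp + (1 - fp - fn) * Phi((t - s) / slope_sd)`` for true
threshold t and stimulus level s (both dB).  One shared random stream per
observer means presentation order affects the draws, as in a human session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .bundles import BundleCoords, BundleModel
from .units import FieldLocation, NormativeModel

SensitivityField = Callable[[FieldLocation], float]


@dataclass(frozen=True)
class PresentationRecord:
    """One stimulus presentation and its outcome."""

    loc: FieldLocation
    stimulus_db: float
    seen: bool
    tag: str = ""  # free-form context, e.g. "horizontal", "retest", "stage2"


@dataclass(frozen=True)
class BlindSpotSpec:
    """Elliptical absolute scotoma at the optic nerve head."""

    centre: FieldLocation = FieldLocation(15.0, -1.5)
    horizontal_radius: float = 2.7  # degrees
    vertical_radius: float = 3.5  # degrees

    def __post_init__(self):
        if self.horizontal_radius <= 0 or self.vertical_radius <= 0:
            raise ValueError("blind-spot radii must be positive")

    def contains(self, loc: FieldLocation) -> bool:
        u = (loc[0] - self.centre.x) / self.horizontal_radius
        v = (loc[1] - self.centre.y) / self.vertical_radius
        return u * u + v * v <= 1.0


@dataclass(frozen=True)
class VesselShadowSpec:
    """Angioscotoma: sensitivity depressed by ``depth`` dB within
    ``width``/2 degrees of a vessel polyline."""

    path: tuple[FieldLocation, ...]
    width: float = 1.0  # degrees
    depth: float = 3.0  # dB

    def __post_init__(self):
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("shadow width and depth must be positive")

    def distance_to(self, loc: FieldLocation) -> float:
        from shapely.geometry import LineString, Point

        return LineString([tuple(p) for p in self.path]).distance(Point(*loc))

    def covers(self, loc: FieldLocation) -> bool:
        return self.distance_to(loc) <= self.width / 2.0


@dataclass(frozen=True)
class ArcuateDefectSpec:
    """Glaucomatous arcuate defect in bundle coordinates: a band of disc
    entry angles ``bundle_angle_centre`` +/- ``bundle_angle_halfwidth`` over
    distances ``distance_range`` from the blind-spot centre, depressed by
    ``depth`` dB."""

    bundle_angle_centre: float  # degrees; >0 superior family, <0 inferior
    bundle_angle_halfwidth: float  # degrees
    distance_range: tuple[float, float]  # degrees from blind-spot centre
    depth: float  # dB of sensitivity loss

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("defect depth must be positive")
        lo, hi = self.distance_range
        if not (0 <= lo < hi):
            raise ValueError("distance_range must be an increasing pair >= 0")

    def covers(self, bc: BundleCoords) -> bool:
        lo, hi = self.distance_range
        if not (lo <= bc.d <= hi):
            return False
        diff = abs(bc.theta - self.bundle_angle_centre)
        diff = min(diff, 360.0 - diff)
        return diff <= self.bundle_angle_halfwidth


def default_vessel_shadows(
    bundle_model: BundleModel | None = None,
    depth: float = 3.0,
    width: float = 1.0,
) -> tuple[VesselShadowSpec, ...]:
    """Two vessel-like arcs leaving the disc superiorly and inferiorly,
    following nerve-fibre-bundle trajectories (major retinal vessels run
    roughly along the arcuate bundles)."""
    model = bundle_model or BundleModel()
    shadows = []
    for theta in (115.0, -115.0):
        path = tuple(
            model.from_bundle(BundleCoords(d, theta)) for d in np.arange(1.0, 13.0, 1.0)
        )
        shadows.append(VesselShadowSpec(path=path, width=width, depth=depth))
    return tuple(shadows)


@dataclass(frozen=True)
class HealthyField:
    """Normative surface + GH, carved by the blind spot and vessel shadows."""

    normative: NormativeModel
    age: float
    gh: float
    blind_spot: BlindSpotSpec
    shadows: tuple[VesselShadowSpec, ...] = ()

    def __call__(self, loc: FieldLocation) -> float:
        loc = FieldLocation(*loc)
        if self.blind_spot.contains(loc):
            return -math.inf
        # ground truth extends beyond the normative-data limit: the simulated
        # eye responds wherever the search algorithms may wander
        value = self.normative.threshold(loc, self.age, extrapolate=True) + self.gh
        covering = [s.depth for s in self.shadows if s.covers(loc)]
        if covering:
            value -= max(covering)  # overlapping shadows do not stack
        return value


def make_healthy_field(
    normative: NormativeModel | None = None,
    age: float = 45.0,
    gh: float = 0.0,
    blind_spot: BlindSpotSpec | None = None,
    shadows: Sequence[VesselShadowSpec] | None = None,
) -> HealthyField:
    """Ground-truth field of a healthy eye.  ``shadows=None`` uses the two
    default vessel arcs; pass ``()`` for a shadow-free field."""
    if shadows is None:
        shadows = default_vessel_shadows()
    return HealthyField(
        normative=normative or NormativeModel(),
        age=age,
        gh=gh,
        blind_spot=blind_spot or BlindSpotSpec(),
        shadows=tuple(shadows),
    )


@dataclass(frozen=True)
class GlaucomaField:
    """A base field with arcuate defects subtracted; never increases
    sensitivity anywhere."""

    base: SensitivityField
    defects: tuple[ArcuateDefectSpec, ...]
    bundle_model: BundleModel

    def __call__(self, loc: FieldLocation) -> float:
        value = self.base(loc)
        if not self.defects or not math.isfinite(value):
            return value
        bc = self.bundle_model.to_bundle(loc)
        for defect in self.defects:
            if defect.covers(bc):
                value -= defect.depth
        return value


def make_glaucoma_field(
    base: SensitivityField,
    defects: Sequence[ArcuateDefectSpec],
    bundle_model: BundleModel | None = None,
) -> GlaucomaField:
    return GlaucomaField(
        base=base,
        defects=tuple(defects),
        bundle_model=bundle_model or BundleModel(),
    )


class MirroredField:
    """Left-eye field expressed through a right-eye-format field (x negated)."""

    def __init__(self, base: SensitivityField):
        self.base = base

    def __call__(self, loc: FieldLocation) -> float:
        return self.base(FieldLocation(-loc[0], loc[1]))


@dataclass
class Observer:
    """Stochastic yes/no responder over a ground-truth sensitivity field."""

    true_field: SensitivityField
    slope_sd: float = 1.5  # dB; spread of the frequency-of-seeing curve
    fp_rate: float = 0.01
    fn_rate: float = 0.01
    rng_seed: int = 0
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if not (0 <= self.fp_rate <= 0.5 and 0 <= self.fn_rate <= 0.5):
            raise ValueError("fp and fn rates must be in [0, 0.5]")
        if self.slope_sd <= 0:
            raise ValueError("psychometric slope_sd must be positive")
        self.rng = np.random.default_rng(self.rng_seed)

    def p_seen(self, loc: FieldLocation, stimulus_db: float) -> float:
        """Probability of a 'seen' response to a stimulus at this location."""
        if not math.isfinite(stimulus_db):
            raise ValueError("stimulus level must be finite")
        t = self.true_field(loc)
        if t == -math.inf:
            upper = 0.0
        else:
            upper = norm.cdf((t - stimulus_db) / self.slope_sd)
        return self.fp_rate + (1.0 - self.fp_rate - self.fn_rate) * upper

    def respond(self, loc: FieldLocation, stimulus_db: float) -> bool:
        """One Bernoulli draw from the shared per-observer random stream."""
        return bool(self.rng.random() < self.p_seen(loc, stimulus_db))

    def reset(self) -> None:
        """Rewind the response stream to the start of the session."""
        self.rng = np.random.default_rng(self.rng_seed)

    def mirrored(self) -> "Observer":
        """The same eye expressed in the other eye's coordinate convention."""
        return replace(self, true_field=MirroredField(self.true_field))


# ---------------------------------------------------------------------------
# Synthetic cohorts: the study conditions for the simulation protocols.
# ---------------------------------------------------------------------------


def healthy_cohort(
    n: int,
    seed: int,
    normative: NormativeModel | None = None,
    gh_sd: float = 1.0,
    age_range: tuple[float, float] = (45.0, 75.0),
    centre_jitter_sd: float = 0.5,
) -> list[tuple[Observer, dict]]:
    """``n`` healthy simulated eyes: GH ~ N(0, gh_sd), ages uniform over
    ``age_range``, blind-spot centre jittered by ``centre_jitter_sd`` per
    axis, default vessel shadows.  Returns (observer, truth-metadata) pairs.
    """
    normative = normative or NormativeModel()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        gh = float(rng.normal(0.0, gh_sd))
        age = float(rng.uniform(*age_range))
        centre = FieldLocation(
            15.0 + float(rng.normal(0.0, centre_jitter_sd)),
            -1.5 + float(rng.normal(0.0, centre_jitter_sd)),
        )
        fld = make_healthy_field(
            normative=normative, age=age, gh=gh, blind_spot=BlindSpotSpec(centre=centre)
        )
        obs = Observer(true_field=fld, rng_seed=int(rng.integers(2**31 - 1)))
        cohort.append((obs, {"gh": gh, "age": age, "bs_centre": centre}))
    return cohort


def glaucoma_cohort(
    n: int,
    seed: int,
    normative: NormativeModel | None = None,
    gh_mean: float = -2.0,
    gh_sd: float = 1.5,
    depth_range: tuple[float, float] = (8.0, 20.0),
    bundle_model: BundleModel | None = None,
) -> list[tuple[Observer, dict]]:
    """``n`` glaucomatous simulated eyes, each with one arcuate defect in a
    random hemifield along a random bundle band, on a depressed base field."""
    normative = normative or NormativeModel()
    model = bundle_model or BundleModel()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        gh = float(rng.normal(gh_mean, gh_sd))
        age = float(rng.uniform(55.0, 85.0))
        hemi = 1.0 if rng.random() < 0.5 else -1.0
        defect = ArcuateDefectSpec(
            bundle_angle_centre=hemi * float(rng.uniform(100.0, 140.0)),
            bundle_angle_halfwidth=float(rng.uniform(10.0, 20.0)),
            distance_range=(6.0, float(rng.uniform(15.0, 24.0))),
            depth=float(rng.uniform(*depth_range)),
        )
        base = make_healthy_field(normative=normative, age=age, gh=gh)
        fld = make_glaucoma_field(base, [defect], bundle_model=model)
        obs = Observer(true_field=fld, rng_seed=int(rng.integers(2**31 - 1)))
        cohort.append((obs, {"gh": gh, "age": age, "defect": defect}))
    return cohort
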