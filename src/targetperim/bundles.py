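"""Nerve-fibre-bundle ("Jansonius-space") coordinate geometry.

Retinal ganglion-cell axons run from their receptive field to the optic
nerve head along arcuate trajectories.  For scotoma delineation it is
convenient to index a visual-field point not by (x, y) but by *bundle
coordinates*: ``d``, the Euclidean distance from the blind-spot centre, and
``theta``, the angle at which the bundle passing through the point enters
the optic nerve head.  An arcuate defect that follows one bundle occupies a
narrow band of theta over a range of d, so its edges become straight lines
in (d, theta) space and can be fitted by ordinary least squares.

The default trajectory model follows the published average nerve-fibre
bundle model: in a polar frame centred on the blind spot, a bundle entering
the disc at angle phi0 follows ``phi(r) = phi0 + b(phi0) * (r - r0)**c(phi0)``
for r beyond a peripapillary radius r0, with separate coefficient maps for
the superior and inferior hemifields.  Here the frame is the visual field of
a right eye (fovea at the origin, blind spot temporal): phi = 0 points from
the blind-spot centre toward the fovea and phi increases into the superior
field.  Trajectories are truncated at the nasal horizontal so that the map
(x, y) -> (d, theta) stays single-valued over the tested region.

``theta`` uses the field convention of this package: theta = 0 is the
nasal horizontal reference bundle (pointing away from the fovea), theta in
(0, 180) is the superior family, theta in (-180, 0) the inferior family.
Internally theta = wrap(180 - phi0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import math

import numpy as np
from scipy.optimize import brentq

from .units import FieldLocation


class BundleCoords(NamedTuple):
    d: float  # degrees from the blind-spot centre
    theta: float  # entry angle at the optic nerve head, degrees in (-180, 180]


class BundleDomainError(ValueError):
    """Requested point or (d, theta) pair outside the trajectory chart."""


def wrap180(angle: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _superior_bc(phi0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Coefficient maps of the average trajectory model, superior hemifield.
    b = np.exp(-1.9 + 3.9 * np.tanh(-(phi0 - 121.0) / 14.0))
    c = 1.9 + 1.4 * np.tanh((phi0 - 121.0) / 14.0)
    return b, c


def _inferior_bc(phi0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Inferior hemifield (phi0 < 0); b is negative: bundles bow inferiorly.
    b = -np.exp(0.7 + 1.5 * np.tanh(-(-phi0 - 90.0) / 25.0))
    c = 1.0 + 0.5 * np.tanh((-phi0 - 90.0) / 25.0)
    return b, c


@dataclass(frozen=True)
class BundleModel:
    """Chart between Cartesian field coordinates and bundle coordinates.

    ``kind`` selects the trajectory family: ``"jansonius"`` (default) is the
    published average power-law spiral model; ``"spiral"`` is a simplified
    linear spiral (constant curvature ``spiral_rate`` deg per deg of radius)
    with the same interface, useful as a transparent fallback.
    """

    bs_centre: FieldLocation = FieldLocation(15.0, -1.5)
    kind: Literal["jansonius", "spiral"] = "jansonius"
    r0: float = 4.0  # peripapillary radius inside which bundles run radially
    spiral_rate: float = 1.5  # deg of phi per deg of r for kind="spiral"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- trajectory evaluation -------------------------------------------------

    def _phi_at(self, phi0: np.ndarray, r: float) -> np.ndarray:
        """phi along the bundle(s) with disc entry angle(s) phi0 at radius r."""
        phi0 = np.asarray(phi0, dtype=float)
        if r <= self.r0:
            return phi0.copy()
        dr = r - self.r0
        if self.kind == "spiral":
            return phi0 + np.sign(phi0) * self.spiral_rate * dr
        sup = phi0 > 0
        out = np.empty_like(phi0)
        if np.any(sup):
            b, c = _superior_bc(phi0[sup])
            out[sup] = phi0[sup] + b * dr ** c
        if np.any(~sup):
            b, c = _inferior_bc(phi0[~sup])
            out[~sup] = phi0[~sup] + b * dr ** c
        return out

    # -- coordinate transforms -------------------------------------------------

    def to_bundle(self, loc: FieldLocation) -> BundleCoords:
        """Bundle coordinates (d, theta) of a field location."""
        loc = FieldLocation(*loc)
        dx = loc.x - self.bs_centre.x
        dy = loc.y - self.bs_centre.y
        d = math.hypot(dx, dy)
        if d < 1e-12:
            raise BundleDomainError("theta is undefined at the blind-spot centre")
        key = (round(loc.x, 9), round(loc.y, 9))
        if key in self._cache:
            return BundleCoords(d, self._cache[key])
        psi = math.degrees(math.atan2(dy, dx))  # 0 = nasal, +90 = superior
        phi = wrap180(180.0 - psi)  # 0 = toward the fovea
        # hemifield: by y-sign temporal to the fovea (the anatomical raphe
        # follows the foveal horizontal there), else by position about the
        # disc horizontal
        if loc.x < 0:
            target = 1.0 if loc.y >= 0 else -1.0
        else:
            target = 1.0 if phi >= 0 else -1.0
        if phi != 0.0 and (phi > 0) != (target > 0):
            # thin strip between the disc and foveal horizontals that the
            # assigned family cannot reach: clamp to its most arcuate bundle
            theta = target * (180.0 - 1e-6)
        else:
            theta = wrap180(180.0 - self._solve_phi0(phi if phi != 0.0 else 180.0 * target, d))
        self._cache[key] = theta
        return BundleCoords(d, theta)

    def _solve_phi0(self, phi: float, r: float) -> float:
        if r <= self.r0 or phi == 0.0:
            return phi if phi != 0.0 else 180.0
        sign = 1.0 if phi > 0 else -1.0
        if phi == 180.0:
            sign = 1.0
        lo, hi = 1e-6 * sign, 180.0 * sign
        grid = sign * np.linspace(1e-6, 180.0, 361)
        g = self._phi_at(grid, r) - phi
        if sign > 0:
            reachable = g[0] <= 0  # smallest-|phi0| bundle undershoots target
        else:
            reachable = g[0] >= 0
        if not reachable:
            # raphe-adjacent zone below the most arcuate bundle: clamp to it
            return float(grid[0])
        idx = np.nonzero((g[:-1] * g[1:]) <= 0)[0]
        if idx.size == 0:
            # beyond the straightest bundle (|phi| = 180 truncation)
            return float(grid[-1])
        i = idx[0]
        a, b = float(grid[i]), float(grid[i + 1])
        if g[i] == 0:
            return a
        f = lambda p: float(self._phi_at(np.array([p]), r)[0]) - phi
        return float(brentq(f, a, b, xtol=1e-12))

    def from_bundle(self, bc: BundleCoords) -> FieldLocation:
        """Field location at distance d along the bundle with entry angle theta."""
        d, theta = bc
        if not d > 0:
            raise BundleDomainError(f"d must be positive, got {d}")
        phi0 = wrap180(180.0 - theta)
        if phi0 == 0.0:
            raise BundleDomainError("theta = 180 lies on the raphe; no unique bundle")
        phi = float(self._phi_at(np.array([phi0]), d)[0])
        if abs(phi) > 180.0:
            # the trajectory crosses the nasal horizontal before reaching d;
            # the chart is truncated there to stay single-valued
            raise BundleDomainError(
                f"bundle theta={theta:.2f} leaves the chart before d={d:.2f}"
            )
        psi = math.radians(180.0 - phi)
        return FieldLocation(
            self.bs_centre.x + d * math.cos(psi),
            self.bs_centre.y + d * math.sin(psi),
        )

    def bundle_path(
        self, theta: float, d_values: Iterable[float]
    ) -> list[FieldLocation]:
        """Polyline of the bundle with entry angle theta sampled at d_values."""
        return [self.from_bundle(BundleCoords(d, theta)) for d in d_values]


@dataclass(frozen=True)
class BundleLineFit:
    """Ordinary-least-squares line theta = intercept + slope * d in bundle space."""

    intercept: float
    slope: float

    def theta_at(self, d: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(d, dtype=float)

    def curve(self, model: BundleModel, d_values: Iterable[float]) -> list[FieldLocation]:
        """The fitted curve mapped back to Cartesian field coordinates."""
        return [
            model.from_bundle(BundleCoords(d, wrap180(float(self.theta_at(d)))))
            for d in d_values
        ]


class SingularFitError(ValueError):
    """Line fit attempted on points with no spread in d."""


def fit_line_in_bundle_space(points: Sequence[BundleCoords]) -> BundleLineFit:
    """OLS regression of entry angle theta on distance d.

    Two points give exact interpolation; with all d equal the fit is
    singular and an error is raised.
    """
    if len(points) < 2:
        raise SingularFitError("need at least two points to fit a line")
    d = np.array([p.d for p in points], dtype=float)
    theta = np.array([p.theta for p in points], dtype=float)
    if np.ptp(d) < 1e-12:
        raise SingularFitError("all points share the same d; slope is undefined")
    slope, intercept = np.polyfit(d, theta, 1)
    return BundleLineFit(intercept=float(intercept), slope=float(slope))


def constant_fit(points: Sequence[BundleCoords]) -> BundleLineFit:
    """Degenerate zero-slope fit through the mean theta (used when a cluster
    spans a single annulus and the OLS slope is undefined)."""
    theta = np.array([p.theta for p in points], dtype=float)
    return BundleLineFit(intercept=float(theta.mean()), slope=0.0)
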