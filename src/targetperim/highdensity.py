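"""Adaptive high-density perimetry: staged delineation of scotoma shape.

Runs only after circle perimetry has flagged at least one scotoma cluster,
with the same GH and offset.  Stage 1 retests the cluster members and their
immediate grid neighbourhood (6-10 degrees from the blind-spot centre).
Each later stage extends the test region 4 degrees farther from the
blind-spot centre (stage k reaches 6 + 4k degrees) and, per scotoma:

1. projects the scotoma 4 degrees farther from the blind-spot centre,
2. expands both edges 4 degrees outward orthogonally to its middle path,
3. selects untested grid locations inside the expanded edges,
4. presents stimuli there (with the circle-perimetry retest rule), and
5. refits the edge and middle curves.

Curve fitting happens in bundle coordinates (distance from the blind-spot
centre, bundle entry angle at the disc), where arcuate defects are straight
bands: the minimum- and maximum-theta non-seen points per distance bin form
the two edges, each fitted by least squares as theta = a + b*d; the middle
path is the same fit over all non-seen points.  The algorithm stops when no
new locations are selected, when the scotoma reaches the boundary of the
test region (30 degrees from the fovea, the usual normative limit), or at a
configurable maximum stage standing in for an operator stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bundles import (
    BundleCoords,
    BundleDomainError,
    BundleLineFit,
    BundleModel,
    SingularFitError,
    constant_fit,
    fit_line_in_bundle_space,
    wrap180,
)
from .circle import (
    CircleGrid,
    CirclePresentation,
    GridIndex,
    LocationCategory,
    ScotomaCluster,
    neighbours,
)
from .observer import Observer, PresentationRecord
from .units import FieldLocation, ReferenceField, stimulus_db_for_offset

INNER_RADIUS = 6.0  # degrees; inner boundary of the tested annulus
STAGE_STEP = 4.0  # degrees of radial growth per stage
EXPANSION = 4.0  # degrees of orthogonal edge expansion per stage


class NoClustersError(ValueError):
    """High-density perimetry requires at least one scotoma cluster."""


@dataclass(frozen=True)
class ScotomaFit:
    edge_low: BundleLineFit  # minimum-theta edge
    edge_high: BundleLineFit  # maximum-theta edge
    middle: BundleLineFit
    d_range: tuple[float, float]  # d span of the fitted non-seen points


@dataclass
class StageState:
    """Snapshot of the algorithm between stages."""

    stage_number: int  # completed stages (>= 1)
    tested: list[FieldLocation]
    fits: list[ScotomaFit]

    @property
    def outer_radius(self) -> float:
        return INNER_RADIUS + STAGE_STEP * self.stage_number


@dataclass
class DelineatedScotoma:
    non_seen_locations: frozenset[FieldLocation]
    fit: ScotomaFit | None
    termination_reason: str  # no-new-locations | reached-boundary | operator-stop
    stages_completed: int


@dataclass(frozen=True)
class HighDensityResult:
    scotomata: tuple[DelineatedScotoma, ...]
    presentations: tuple[CirclePresentation, ...]  # idx is (-1, serial) for new locs
    categories: dict[FieldLocation, LocationCategory]
    offset: float


def initial_region(
    clusters: list[ScotomaCluster], grid: CircleGrid
) -> set[FieldLocation]:
    """Stage-1 retest region: cluster members plus their grid neighbours,
    all within the 6-10 degree circle-perimetry annulus."""
    if not clusters:
        raise NoClustersError("high-density perimetry needs >= 1 scotoma cluster")
    indices: set[GridIndex] = set()
    for cluster in clusters:
        for idx in cluster.member_indices:
            indices.add(idx)
            indices.update(neighbours(idx))
    return {grid.location(idx) for idx in indices}


def identify_edge_points(
    non_seen: list[BundleCoords], bin_width: float = 2.0
) -> tuple[list[BundleCoords], list[BundleCoords]]:
    """Minimum- and maximum-theta non-seen points per distance bin.

    A single point degenerates to both edges; collinear single-file points
    give identical edges.
    """
    if not non_seen:
        raise ValueError("no non-seen points to delineate")
    bins: dict[int, list[BundleCoords]] = {}
    for bc in non_seen:
        bins.setdefault(int(bc.d // bin_width), []).append(bc)
    low, high = [], []
    for key in sorted(bins):
        pts = bins[key]
        low.append(min(pts, key=lambda p: p.theta))
        high.append(max(pts, key=lambda p: p.theta))
    return low, high


def _fit_or_constant(points: list[BundleCoords]) -> BundleLineFit:
    try:
        return fit_line_in_bundle_space(points)
    except SingularFitError:
        return constant_fit(points)


def fit_scotoma(
    non_seen_bc: list[BundleCoords], bin_width: float = 2.0
) -> ScotomaFit:
    """Edge and middle line fits in bundle space for a set of non-seen points."""
    low, high = identify_edge_points(non_seen_bc, bin_width)
    d_vals = [bc.d for bc in non_seen_bc]
    return ScotomaFit(
        edge_low=_fit_or_constant(low),
        edge_high=_fit_or_constant(high),
        middle=_fit_or_constant(non_seen_bc),
        d_range=(min(d_vals), max(d_vals)),
    )


def _middle_tangent(
    fit: ScotomaFit, model: BundleModel, d: float, h: float = 0.25
) -> tuple[float, float] | None:
    """Unit tangent of the middle curve at distance d, in Cartesian space."""
    try:
        p0 = model.from_bundle(BundleCoords(max(d - h, 0.5), wrap180(float(fit.middle.theta_at(d - h)))))
        p1 = model.from_bundle(BundleCoords(d + h, wrap180(float(fit.middle.theta_at(d + h)))))
    except BundleDomainError:
        return None
    tx, ty = p1.x - p0.x, p1.y - p0.y
    n = math.hypot(tx, ty)
    if n < 1e-12:
        return None
    return tx / n, ty / n


def _displaced_edges(
    fit: ScotomaFit,
    model: BundleModel,
    d_values: np.ndarray,
    expansion: float = EXPANSION,
) -> tuple[BundleLineFit, BundleLineFit] | None:
    """Both edge curves displaced ``expansion`` degrees outward orthogonally
    to the middle path, re-expressed as line fits in bundle space."""
    low_pts: list[BundleCoords] = []
    high_pts: list[BundleCoords] = []
    for d in d_values:
        tangent = _middle_tangent(fit, model, float(d))
        if tangent is None:
            continue
        nx, ny = -tangent[1], tangent[0]  # unit normal
        for edge, sink in ((fit.edge_low, low_pts), (fit.edge_high, high_pts)):
            try:
                e = model.from_bundle(
                    BundleCoords(float(d), wrap180(float(edge.theta_at(d))))
                )
            except BundleDomainError:
                continue
            candidates = []
            for s in (1.0, -1.0):
                p = FieldLocation(e.x + s * expansion * nx, e.y + s * expansion * ny)
                try:
                    candidates.append(model.to_bundle(p))
                except BundleDomainError:
                    continue
            if not candidates:
                continue
            outward = (min if sink is low_pts else max)(
                candidates, key=lambda bc: bc.theta
            )
            sink.append(outward)
    if len(low_pts) < 1 or len(high_pts) < 1:
        return None
    return _fit_or_constant(low_pts), _fit_or_constant(high_pts)


def next_stage_locations(
    state: StageState,
    bundle_model: BundleModel,
    grid_spacing: float = 2.0,
    fovea_limit: float = 30.0,
    dedup_tol: float = 0.5,
    fit: ScotomaFit | None = None,
) -> set[FieldLocation]:
    """Untested grid locations inside the projected and expanded scotoma.

    The previous stage's fits are projected to the new outer radius
    (``state.outer_radius`` already reflects the 4 degree growth) and both
    edges are displaced 4 degrees outward orthogonally to the middle path;
    candidates on a regular ``grid_spacing`` Cartesian grid are kept when
    their bundle angle lies between the displaced edges, their distance from
    the blind-spot centre is within [6, outer_radius], they are within
    ``fovea_limit`` of the fovea and at least ``dedup_tol`` from every
    already-tested location.  An empty result triggers termination.
    """
    fits = [fit] if fit is not None else state.fits
    out: set[FieldLocation] = set()
    bs = bundle_model.bs_centre
    tested = np.array([[p.x, p.y] for p in state.tested]) if state.tested else None
    for f in fits:
        # project the scotoma 4 degrees beyond its current extent, capped by
        # the stage's outer radius
        d_hi = min(f.d_range[1] + STAGE_STEP, state.outer_radius)
        d_samples = np.arange(INNER_RADIUS, d_hi + 1e-9, 1.0)
        displaced = _displaced_edges(f, bundle_model, d_samples)
        if displaced is None:
            continue
        lo_fit, hi_fit = displaced
        # candidate Cartesian grid over the annulus
        n_cells = int(math.ceil((abs(bs.x) + state.outer_radius) / grid_spacing)) + 1
        coords = np.arange(-n_cells, n_cells + 1) * grid_spacing
        for x in coords:
            for y in coords:
                loc = FieldLocation(float(x), float(y))
                d = loc.distance_to(bs)
                if not (INNER_RADIUS <= d <= d_hi):
                    continue
                if loc.eccentricity > fovea_limit:
                    continue
                try:
                    bc = bundle_model.to_bundle(loc)
                except BundleDomainError:
                    continue
                t_lo = float(lo_fit.theta_at(d))
                t_hi = float(hi_fit.theta_at(d))
                if not (min(t_lo, t_hi) <= bc.theta <= max(t_lo, t_hi)):
                    continue
                if tested is not None and len(tested):
                    if np.min(np.hypot(tested[:, 0] - loc.x, tested[:, 1] - loc.y)) < dedup_tol:
                        continue
                out.add(loc)
    return out


@dataclass
class _ActiveScotoma:
    non_seen: set[FieldLocation] = field(default_factory=set)
    fit: ScotomaFit | None = None
    seed_clusters: list[ScotomaCluster] = field(default_factory=list)


def _present_with_retest(
    obs: Observer,
    locations: list[FieldLocation],
    reference: ReferenceField,
    offset: float,
    rng: np.random.Generator,
    log: list[CirclePresentation],
    categories: dict[FieldLocation, LocationCategory],
    tag: str,
    min_gap: int = 5,
) -> None:
    order = [locations[i] for i in rng.permutation(len(locations))]
    queue: list[tuple[FieldLocation, bool]] = [(loc, False) for loc in order]
    i = 0
    while i < len(queue):
        loc, is_retest = queue[i]
        stim = stimulus_db_for_offset(reference(loc), offset)
        seen = obs.respond(loc, stim)
        log.append(
            CirclePresentation(
                (-1, len(log)),
                PresentationRecord(loc, stim, seen, f"{tag}{'-retest' if is_retest else ''}"),
                is_retest,
            )
        )
        if is_retest:
            categories[loc] = (
                LocationCategory.MISSED_THEN_SEEN if seen
                else LocationCategory.MISSED_TWICE
            )
        elif seen:
            categories[loc] = LocationCategory.SEEN_FIRST
        else:
            lo = i + 1 + min_gap
            pos = len(queue) if lo >= len(queue) else int(rng.integers(lo, len(queue) + 1))
            queue.insert(pos, (loc, True))
        i += 1


def run_high_density(
    obs: Observer,
    reference: ReferenceField,
    offset: float,
    clusters: list[ScotomaCluster],
    grid: CircleGrid,
    bundle_model: BundleModel | None = None,
    grid_spacing: float = 2.0,
    fovea_limit: float = 30.0,
    max_stage: int = 6,
    rng: np.random.Generator | None = None,
) -> HighDensityResult:
    """Full staged delineation run.  A location counts as non-seen when it is
    missed on both of its presentations.  Scotomata whose selected regions
    overlap are merged.  Refitting is cumulative over all stages."""
    if not clusters:
        raise NoClustersError("high-density perimetry needs >= 1 scotoma cluster")
    bundle_model = bundle_model or BundleModel(bs_centre=grid.bs_centre)
    rng = rng if rng is not None else obs.rng

    log: list[CirclePresentation] = []
    categories: dict[FieldLocation, LocationCategory] = {}
    tested: list[FieldLocation] = []
    active = [_ActiveScotoma(seed_clusters=[c]) for c in clusters]
    done: list[DelineatedScotoma] = []

    for stage in range(1, max_stage + 1):
        state = StageState(stage_number=stage, tested=tested,
                           fits=[s.fit for s in active if s.fit is not None])
        # select this stage's locations per scotoma
        selections: list[set[FieldLocation]] = []
        for sc in active:
            if stage == 1:
                sel = {
                    loc for loc in initial_region(sc.seed_clusters, grid)
                    if not tested or min(loc.distance_to(t) for t in tested) >= 1e-6
                }
            elif sc.fit is None:
                sel = set()
            else:
                sel = next_stage_locations(
                    state, bundle_model, grid_spacing, fovea_limit, fit=sc.fit
                )
            selections.append(sel)

        # merge scotomata whose selected regions intersect
        merged = True
        while merged:
            merged = False
            for i in range(len(active)):
                for j in range(i + 1, len(active)):
                    if selections[i] & selections[j] or (
                        active[i].non_seen & active[j].non_seen
                    ):
                        selections[i] |= selections.pop(j)
                        keep, absorb = active[i], active.pop(j)
                        keep.non_seen |= absorb.non_seen
                        keep.seed_clusters += absorb.seed_clusters
                        merged = True
                        break
                if merged:
                    break

        # retire scotomata with nothing to test
        still_active, still_sel = [], []
        for sc, sel in zip(active, selections):
            if not sel:
                done.append(_finalize(sc, "no-new-locations", stage - 1))
            else:
                still_active.append(sc)
                still_sel.append(sel)
        active, selections = still_active, still_sel
        if not active:
            break

        new_locs = sorted(set().union(*selections))
        _present_with_retest(
            obs, new_locs, reference, offset, rng, log, categories, f"stage{stage}"
        )
        tested.extend(new_locs)

        # update non-seen sets and refit, then check the boundary rule
        still_active = []
        for sc, sel in zip(active, selections):
            sc.non_seen |= {
                loc for loc in sel
                if categories[loc] is LocationCategory.MISSED_TWICE
            }
            if sc.non_seen:
                sc.fit = fit_scotoma(
                    sorted(bundle_model.to_bundle(loc) for loc in sc.non_seen),
                    bin_width=grid_spacing,
                )
            if not sc.non_seen and stage >= 1:
                done.append(_finalize(sc, "no-new-locations", stage))
            elif any(
                loc.eccentricity >= fovea_limit - grid_spacing for loc in sc.non_seen
            ):
                done.append(_finalize(sc, "reached-boundary", stage))
            else:
                still_active.append(sc)
        active = still_active
        if not active:
            break

    for sc in active:
        done.append(_finalize(sc, "operator-stop", max_stage))

    return HighDensityResult(
        scotomata=tuple(done),
        presentations=tuple(log),
        categories=categories,
        offset=offset,
    )


def _finalize(sc: _ActiveScotoma, reason: str, stages: int) -> DelineatedScotoma:
    return DelineatedScotoma(
        non_seen_locations=frozenset(sc.non_seen),
        fit=sc.fit,
        termination_reason=reason,
        stages_completed=stages,
    )
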