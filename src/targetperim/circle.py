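"""Suprathreshold circle perimetry around the blind spot.

Seventy-five locations — three concentric circles of 25 equally spaced
locations each at radii 6, 8 and 10 degrees from the blind-spot centre —
receive one suprathreshold presentation each, at a fixed offset below the
individual's reference threshold (e.g. reference 30 dB, offset 5 dB gives a
25 dB stimulus).  A location missed on the first presentation is retested
once with an identical stimulus later in the test (never immediately after).
Each location ends in one of three categories: seen on the first
presentation, missed then seen, or missed twice.

Scotoma detection runs a nearest-neighbour cluster analysis on the polar
grid (same ring, adjacent angle; adjacent ring, same angle index).  A
scotoma is a connected cluster of locations with at least one non-seen
trial, containing either two neighbouring missed-twice locations or at
least three connected locations missed on the first presentation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .observer import Observer, PresentationRecord
from .units import FieldLocation, ReferenceField, stimulus_db_for_offset

RING_RADII = (6.0, 8.0, 10.0)
LOCATIONS_PER_RING = 25
ANGLE_STEP = 360.0 / LOCATIONS_PER_RING  # 14.4 degrees


class LocationCategory(enum.Enum):
    SEEN_FIRST = "seen_first"
    MISSED_THEN_SEEN = "missed_then_seen"
    MISSED_TWICE = "missed_twice"

    @property
    def missed_first(self) -> bool:
        return self is not LocationCategory.SEEN_FIRST


GridIndex = tuple[int, int]  # (ring index 0..2, angle index 0..24)


@dataclass(frozen=True)
class CircleGrid:
    """The 75 test locations, indexed by (ring, angle index).

    Angle origin is the temporal horizontal through the blind-spot centre
    (pointing toward the fovea in right-eye format), increasing superiorly.
    """

    bs_centre: FieldLocation
    eye: str = "right"

    def location(self, idx: GridIndex) -> FieldLocation:
        ring, angle_idx = idx
        radius = RING_RADII[ring]
        # temporal = toward the fovea = -x for a right eye, +x for a left eye
        temporal_sign = -1.0 if self.eye == "right" else 1.0
        a = math.radians(ANGLE_STEP * angle_idx)
        return FieldLocation(
            self.bs_centre.x + temporal_sign * radius * math.cos(a),
            self.bs_centre.y + radius * math.sin(a),
        )

    @property
    def indices(self) -> list[GridIndex]:
        return [(r, a) for r in range(len(RING_RADII))
                for a in range(LOCATIONS_PER_RING)]

    @property
    def locations(self) -> dict[GridIndex, FieldLocation]:
        return {idx: self.location(idx) for idx in self.indices}


def circle_locations(bs_centre: FieldLocation, eye: str = "right") -> CircleGrid:
    if eye not in ("right", "left"):
        raise ValueError(f"eye must be 'right' or 'left', got {eye!r}")
    return CircleGrid(bs_centre=FieldLocation(*bs_centre), eye=eye)


def neighbours(idx: GridIndex) -> set[GridIndex]:
    """4-neighbourhood on the polar grid: same ring, angle +/-1 (mod 25);
    adjacent ring, same angle index."""
    ring, angle = idx
    if not (0 <= ring < len(RING_RADII) and 0 <= angle < LOCATIONS_PER_RING):
        raise ValueError(f"invalid grid index {idx}")
    out = {
        (ring, (angle - 1) % LOCATIONS_PER_RING),
        (ring, (angle + 1) % LOCATIONS_PER_RING),
    }
    if ring > 0:
        out.add((ring - 1, angle))
    if ring < len(RING_RADII) - 1:
        out.add((ring + 1, angle))
    return out


@dataclass(frozen=True)
class CirclePresentation:
    """A circle-perimetry presentation with its grid index attached."""

    idx: GridIndex
    record: PresentationRecord
    is_retest: bool


@dataclass(frozen=True)
class CircleResult:
    grid: CircleGrid
    categories: dict[GridIndex, LocationCategory]
    presentations: tuple[CirclePresentation, ...]
    offset: float

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)


def run_circle_perimetry(
    obs: Observer,
    grid: CircleGrid,
    reference: ReferenceField,
    offset: float,
    rng: np.random.Generator | None = None,
    min_gap: int = 5,
) -> CircleResult:
    """Present all 75 locations in seeded random order, retesting first-pass
    misses with an identical stimulus at least ``min_gap`` presentations
    later (re-queue position randomized beyond the gap)."""
    rng = rng if rng is not None else obs.rng
    indices = grid.indices
    order = [indices[i] for i in rng.permutation(len(indices))]
    queue: list[tuple[GridIndex, bool]] = [(idx, False) for idx in order]

    log: list[CirclePresentation] = []
    categories: dict[GridIndex, LocationCategory] = {}
    i = 0
    while i < len(queue):
        idx, is_retest = queue[i]
        loc = grid.location(idx)
        stim = stimulus_db_for_offset(reference(loc), offset)
        seen = obs.respond(loc, stim)
        log.append(
            CirclePresentation(
                idx, PresentationRecord(loc, stim, seen, "retest" if is_retest else "first"),
                is_retest,
            )
        )
        if is_retest:
            categories[idx] = (
                LocationCategory.MISSED_THEN_SEEN if seen
                else LocationCategory.MISSED_TWICE
            )
        elif seen:
            categories[idx] = LocationCategory.SEEN_FIRST
        else:
            # schedule an identical retest after at least min_gap others
            lo = i + 1 + min_gap
            pos = len(queue) if lo >= len(queue) else int(rng.integers(lo, len(queue) + 1))
            queue.insert(pos, (idx, True))
        i += 1

    return CircleResult(
        grid=grid, categories=categories, presentations=tuple(log), offset=offset
    )


@dataclass(frozen=True)
class ScotomaCluster:
    member_indices: frozenset[GridIndex]
    trigger: str  # "missed_twice_pair", "missed_first_triplet" or both


def _connected_components(
    nodes: set[GridIndex],
) -> list[set[GridIndex]]:
    components = []
    remaining = set(nodes)
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for nb in neighbours(cur):
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components


def detect_scotomata(
    categories: dict[GridIndex, LocationCategory],
    mutual_pair: bool = True,
) -> list[ScotomaCluster]:
    """Clusters of locations with non-seen trials satisfying the scotoma rule.

    ``mutual_pair=True`` (default) requires the two missed-twice locations to
    be direct neighbours; ``False`` accepts any two missed-twice locations in
    one connected component.
    """
    damaged = {idx for idx, cat in categories.items() if cat.missed_first}
    clusters = []
    for comp in _connected_components(damaged):
        twice = [idx for idx in comp if categories[idx] is LocationCategory.MISSED_TWICE]
        if mutual_pair:
            pair = any(
                other in neighbours(idx)
                for i, idx in enumerate(twice)
                for other in twice[i + 1:]
            )
        else:
            pair = len(twice) >= 2
        triplet = len(comp) >= 3  # all component members were missed at least once
        if pair or triplet:
            trigger = "+".join(
                t for t, ok in
                (("missed_twice_pair", pair), ("missed_first_triplet", triplet))
                if ok
            )
            clusters.append(
                ScotomaCluster(member_indices=frozenset(comp), trigger=trigger)
            )
    clusters.sort(key=lambda c: sorted(c.member_indices)[0])
    return clusters


def false_positive_rate(categories: dict[GridIndex, LocationCategory]) -> float:
    """Percent of the 75 locations for which the stimulus was not seen at
    least once."""
    if len(categories) != len(RING_RADII) * LOCATIONS_PER_RING:
        raise ValueError(f"expected 75 categories, got {len(categories)}")
    missed = sum(1 for cat in categories.values() if cat.missed_first)
    return 100.0 * missed / len(categories)
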