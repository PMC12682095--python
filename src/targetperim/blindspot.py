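"""Sequential search for the centre of the physiological blind spot.

All presentations use a fixed suprathreshold stimulus of 17 dB (631% Weber
contrast) and a 0.43 degree diameter spot.  The search first spans the blind
spot horizontally along y = -3: marching temporally in 2 degree steps from
x = 6 (right eye) until a stimulus is not seen, then nasally in 1 degree
steps until seen, then temporally in 1 degree steps until seen again.  The
horizontal edges are the midpoints of the seen/not-seen pairs on each side,
and their midpoint gives the horizontal centre.  A vertical pass at that x
starts at y = -18 and marches superiorly in 3 degree steps until a miss,
then inferiorly in 1 degree steps until seen, then superiorly in 1 degree
steps until seen again; the vertical centre is the midpoint of the vertical
edges.  The vertical 1 degree march crosses the whole blind spot from below,
so the first seen response above it defines the superior boundary pair.

Left eyes are handled by mirroring into right-eye format, running the same
search, and mirroring the result back.
"""

from __future__ import annotations

from dataclasses import dataclass

from .observer import Observer, PresentationRecord
from .units import FieldLocation

SEARCH_STIMULUS_DB = 17.0  # 631% Weber contrast
STIMULUS_DIAMETER_DEG = 0.43


class NoBlindSpotError(RuntimeError):
    """The march ran out of range without bracketing a blind spot."""


@dataclass(frozen=True)
class BlindSpotResult:
    centre: FieldLocation
    horizontal_edges: tuple[float, float]  # nasal-side x, temporal-side x
    vertical_edges: tuple[float, float]  # inferior y, superior y
    presentations: tuple[PresentationRecord, ...]
    stimulus_db: float = SEARCH_STIMULUS_DB
    stimulus_diameter: float = STIMULUS_DIAMETER_DEG


def _march(
    obs: Observer,
    log: list[PresentationRecord],
    start: float,
    step: float,
    make_loc,
    tag: str,
    until_seen: bool,
    bound: float,
):
    """March from ``start`` in ``step`` increments until the response equals
    ``until_seen``; returns (stop position, previous position)."""
    pos = start
    prev = None
    while abs(pos - start) <= bound:
        loc = make_loc(pos)
        seen = obs.respond(loc, SEARCH_STIMULUS_DB)
        log.append(PresentationRecord(loc, SEARCH_STIMULUS_DB, seen, tag))
        if seen == until_seen:
            return pos, prev
        prev = pos
        pos += step
    raise NoBlindSpotError(
        f"no response transition within {bound:.0f} deg during {tag} march"
    )


def locate_blind_spot(
    obs: Observer, eye: str = "right", search_bound: float = 25.0
) -> BlindSpotResult:
    """Estimate the blind-spot centre of a simulated observer.

    ``eye`` is ``"right"`` or ``"left"``; left-eye searches run on the
    mirrored observer and results are mirrored back at the interface.
    Raises :class:`NoBlindSpotError` if a march exceeds ``search_bound``
    degrees without the required response transition.
    """
    if eye not in ("right", "left"):
        raise ValueError(f"eye must be 'right' or 'left', got {eye!r}")
    if eye == "left":
        res = locate_blind_spot(obs.mirrored(), "right", search_bound)
        return BlindSpotResult(
            centre=FieldLocation(-res.centre.x, res.centre.y),
            horizontal_edges=(-res.horizontal_edges[0], -res.horizontal_edges[1]),
            vertical_edges=res.vertical_edges,
            presentations=tuple(
                PresentationRecord(
                    FieldLocation(-p.loc.x, p.loc.y), p.stimulus_db, p.seen, p.tag
                )
                for p in res.presentations
            ),
        )

    log: list[PresentationRecord] = []
    y_line = -3.0
    h_loc = lambda x: FieldLocation(x, y_line)

    # -- horizontal pass -----------------------------------------------------
    start = 6.0
    first_seen = obs.respond(h_loc(start), SEARCH_STIMULUS_DB)
    log.append(PresentationRecord(h_loc(start), SEARCH_STIMULUS_DB, first_seen, "horizontal"))
    if not first_seen:
        # uncovered branch in the written procedure: back off nasally until a
        # seen response, then begin the temporal march from there
        start, _ = _march(obs, log, start - 2.0, -2.0, h_loc, "horizontal-backoff",
                          until_seen=True, bound=search_bound)
    # temporally in 2 deg steps until not seen
    x_miss, _ = _march(obs, log, start + 2.0, 2.0, h_loc, "horizontal",
                       until_seen=False, bound=search_bound)
    # nasally in 1 deg steps until seen -> nasal edge pair
    x_nasal_seen, x_nasal_miss = _march(obs, log, x_miss - 1.0, -1.0, h_loc,
                                        "horizontal", until_seen=True, bound=search_bound)
    if x_nasal_miss is None:
        x_nasal_miss = x_miss
    nasal_edge = (x_nasal_seen + x_nasal_miss) / 2.0
    # temporally in 1 deg steps across the blind spot until seen again
    x_temp_seen, x_temp_miss = _march_across(
        obs, log, x_nasal_seen + 1.0, 1.0, h_loc, "horizontal", search_bound
    )
    temporal_edge = (x_temp_seen + x_temp_miss) / 2.0
    centre_x = (nasal_edge + temporal_edge) / 2.0

    # -- vertical pass -------------------------------------------------------
    v_loc = lambda y: FieldLocation(centre_x, y)
    y_miss, _ = _march(obs, log, -18.0, 3.0, v_loc, "vertical",
                       until_seen=False, bound=search_bound + 15.0)
    y_inf_seen, y_inf_miss = _march(obs, log, y_miss - 1.0, -1.0, v_loc,
                                    "vertical", until_seen=True, bound=search_bound)
    if y_inf_miss is None:
        y_inf_miss = y_miss
    inferior_edge = (y_inf_seen + y_inf_miss) / 2.0
    # continuous 1 deg march superiorly across the whole blind spot until seen
    y_sup_seen, y_sup_miss = _march_across(
        obs, log, y_inf_seen + 1.0, 1.0, v_loc, "vertical", search_bound
    )
    superior_edge = (y_sup_seen + y_sup_miss) / 2.0
    centre_y = (inferior_edge + superior_edge) / 2.0

    return BlindSpotResult(
        centre=FieldLocation(centre_x, centre_y),
        horizontal_edges=(nasal_edge, temporal_edge),
        vertical_edges=(inferior_edge, superior_edge),
        presentations=tuple(log),
    )


def _march_across(obs: Observer, log, start: float, step: float, make_loc,
                  tag: str, bound: float):
    """March that first enters the not-seen region and then continues until
    the stimulus is seen again; returns (seen pos, last not-seen pos)."""
    pos = start
    last_miss = None
    entered = False
    while abs(pos - start) <= bound:
        loc = make_loc(pos)
        seen = obs.respond(loc, SEARCH_STIMULUS_DB)
        log.append(PresentationRecord(loc, SEARCH_STIMULUS_DB, seen, tag))
        if not seen:
            entered = True
            last_miss = pos
        elif entered:
            return pos, last_miss
        pos += step
    raise NoBlindSpotError(
        f"stimulus never seen again within {bound:.0f} deg during {tag} march"
    )
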