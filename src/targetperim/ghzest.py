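"""General-height (GH) estimation with a 12-presentation ZEST procedure.

The GH is the eye's overall sensitivity offset relative to the age-corrected
mean normal field (negative when globally depressed).  It is estimated from
a single shared Bayesian threshold posterior over responses at eight
locations on a circle 6 degrees from the blind-spot centre, at polar angles
0, 45, ..., 315, where sensitivity is assumed roughly uniform.

ZEST: a probability density over candidate thresholds (prior Gaussian,
mean 25 dB, SD 6 dB) is multiplied after every presentation by the
likelihood of the observed response under a cumulative-Gaussian
frequency-of-seeing curve, and the next stimulus is placed at the posterior
mean.  The first eight stimuli visit the circle in the fixed order 0, 180,
90, 270, 45, 135, 225, 315 degrees.  To keep damaged locations from biasing
the estimate, the four locations where the participant responded to the
dimmest (highest dB) stimuli are then selected (seen locations first; if
fewer than four were seen, the locations with the dimmest presentations fill
the remainder), and four more presentations are made, one at each selected
location, in a random spatial order.  The posterior is shared throughout and
never reset.  The final GH is the posterior mean minus the average
age-corrected normal threshold at the eight locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.stats import norm

from .observer import Observer, PresentationRecord
from .units import FieldLocation, NormativeModel

GH_CIRCLE_RADIUS = 6.0  # degrees from the blind-spot centre
GH_ANGLES = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
GH_PRESENTATION_ORDER = (0.0, 180.0, 90.0, 270.0, 45.0, 135.0, 225.0, 315.0)


class ZestUnderflowError(ArithmeticError):
    """All posterior mass was lost in an update."""


@dataclass(frozen=True)
class ZestState:
    """Posterior over candidate thresholds, plus the presentation history."""

    domain: np.ndarray  # candidate thresholds, dB
    pdf: np.ndarray  # probability mass over domain, sums to 1
    history: tuple[tuple[FieldLocation, float, bool], ...] = ()
    likelihood_slope: float = 1.0  # dB
    fp_asymptote: float = 0.03
    fn_asymptote: float = 0.03

    @property
    def mean(self) -> float:
        return float(np.dot(self.domain, self.pdf))

    def p_seen_given_threshold(self, stimulus_db: float) -> np.ndarray:
        """Response likelihood at each candidate threshold."""
        upper = norm.cdf((self.domain - stimulus_db) / self.likelihood_slope)
        return self.fp_asymptote + (1 - self.fp_asymptote - self.fn_asymptote) * upper


def make_prior(
    prior_mean: float = 25.0,
    prior_sd: float = 6.0,
    domain_lo: float = -5.0,
    domain_hi: float = 45.0,
    resolution: float = 0.1,
    **likelihood_kwargs,
) -> ZestState:
    """Gaussian prior over a [-5, 45] dB candidate grid at 0.1 dB resolution."""
    domain = np.arange(domain_lo, domain_hi + resolution / 2, resolution)
    pdf = norm.pdf(domain, prior_mean, prior_sd)
    pdf = pdf / pdf.sum()
    return ZestState(domain=domain, pdf=pdf, **likelihood_kwargs)


def zest_step(
    state: ZestState, seen: bool, stimulus_db: float,
    loc: FieldLocation = FieldLocation(0.0, 0.0),
) -> ZestState:
    """One Bayes update: multiply the pdf by the response likelihood and
    renormalize."""
    like = state.p_seen_given_threshold(stimulus_db)
    if not seen:
        like = 1.0 - like
    pdf = state.pdf * like
    total = pdf.sum()
    if not total > 0 or not math.isfinite(total):
        raise ZestUnderflowError("posterior mass vanished in ZEST update")
    return replace(
        state,
        pdf=pdf / total,
        history=state.history + ((loc, stimulus_db, seen),),
    )


def gh_locations(bs_centre: FieldLocation) -> tuple[FieldLocation, ...]:
    """The eight test locations, 6 degrees from the blind-spot centre, in
    angle order 0, 45, ..., 315 (0 = nasal horizontal, angles
    counter-clockwise in right-eye field coordinates)."""
    bs_centre = FieldLocation(*bs_centre)
    return tuple(
        FieldLocation(
            bs_centre.x + GH_CIRCLE_RADIUS * math.cos(math.radians(a)),
            bs_centre.y + GH_CIRCLE_RADIUS * math.sin(math.radians(a)),
        )
        for a in GH_ANGLES
    )


@dataclass(frozen=True)
class GhResult:
    gh: float
    zest_estimate: float
    mean_normal: float
    presentations: tuple[PresentationRecord, ...]
    selected_locations: tuple[float, ...]  # polar angles of the 4 selected


def estimate_gh(
    obs: Observer,
    bs_centre: FieldLocation,
    normative: NormativeModel | None = None,
    age: float = 45.0,
    rng: np.random.Generator | None = None,
    prior: ZestState | None = None,
) -> GhResult:
    """Run the 12-presentation GH procedure on a simulated observer.

    ``rng`` orders the final four presentations; by default the observer's
    own response stream is used so a fixed observer seed fixes the whole run.
    """
    normative = normative or NormativeModel()
    rng = rng if rng is not None else obs.rng
    locs = gh_locations(bs_centre)
    by_angle = dict(zip(GH_ANGLES, locs))

    state = prior if prior is not None else make_prior()
    log: list[PresentationRecord] = []
    outcomes: dict[float, tuple[float, bool]] = {}  # angle -> (stimulus, seen)

    for angle in GH_PRESENTATION_ORDER:
        loc = by_angle[angle]
        stim = state.mean
        seen = obs.respond(loc, stim)
        state = zest_step(state, seen, stim, loc)
        log.append(PresentationRecord(loc, stim, seen, f"gh-{angle:g}"))
        outcomes[angle] = (stim, seen)

    # select the four locations with the dimmest seen stimuli; if fewer than
    # four were seen, seen locations first, then dimmest-presented others
    # stable sort over presentation order breaks dB ties by order of testing
    seen_angles = sorted(
        (a for a in GH_PRESENTATION_ORDER if outcomes[a][1]),
        key=lambda a: -outcomes[a][0],
    )
    unseen_angles = sorted(
        (a for a in GH_PRESENTATION_ORDER if not outcomes[a][1]),
        key=lambda a: -outcomes[a][0],
    )
    selected = tuple((seen_angles + unseen_angles)[:4])

    for angle in rng.permutation(selected):
        loc = by_angle[float(angle)]
        stim = state.mean
        seen = obs.respond(loc, stim)
        state = zest_step(state, seen, stim, loc)
        log.append(PresentationRecord(loc, stim, seen, f"gh-{angle:g}"))

    zest_estimate = state.mean
    mean_normal = float(
        np.mean([normative.threshold(loc, age) for loc in locs])
    )
    return GhResult(
        gh=zest_estimate - mean_normal,
        zest_estimate=zest_estimate,
        mean_normal=mean_normal,
        presentations=tuple(log),
        selected_locations=selected,
    )
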