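# Methods

This note documents the models, parameter choices and numerical decisions
behind `targetperim`, and what the simulation results do and do not show.

## Units

Perimetric decibels follow the Humphrey/Compass convention: 100% Weber
contrast is written 25 dB and each dB is a 0.1 log-unit contrast step, so
`weber% = 100·10^((25 − dB)/10)`.  Decibel values are continuous
internally; rounding happens only at presentation/reporting (CLI output is
rounded to 10⁻⁶ for byte-stable files).

## Normative surface and reference field

The normative model is a radially symmetric hill of vision:
`threshold = foveal_db − eccentricity_slope·ecc − age_slope·max(0, age − age_reference)`
with defaults 33 dB, 0.25 dB/deg, 0.06 dB/yr past 45 y.  These are
plausible values for white-on-white perimetry at these eccentricities; all
four are configuration parameters, since any device-specific normative
database is outside the package's scope.  The model raises beyond 30
degrees of eccentricity (the usual limit of normative data); ground-truth
simulation extrapolates past that limit because a real eye keeps responding
wherever a search algorithm wanders.

GH sign convention: GH = measured overall sensitivity − age-corrected
normal, so a depressed eye has negative GH, and the reference field is
`normative + GH`.  With this convention the suprathreshold stimulus for
offset Δ is `normative + GH − Δ`, matching the worked rule
(reference 30 dB, Δ = 5 → stimulus 25 dB).

## Simulated observers

Responses follow the frequency-of-seeing model
`P(seen) = fp + (1 − fp − fn)·Φ((t − s)/σ)` with defaults σ = 1.5 dB and
fp = fn = 0.01 — mid-range values from the perimetric literature; the
algorithms under test specify no observer, so these are the package's
choice and are fully configurable.  Each observer owns one seeded random
stream shared across all presentations, so presentation order affects the
draws, as it would for a human session.  A location inside the blind spot
has t = −∞ and is seen only via false positives.

Ground-truth features:

* **Blind spot**: ellipse centred (15, −1.5) degrees (right-eye format),
  radii 2.7 × 3.5 degrees — anatomically typical values.
* **Angioscotomata**: polyline shadows, default two vessel-like arcs
  leaving the disc superiorly and inferiorly along bundle trajectories
  (θ = ±115 degrees, d = 1–12), width 1 degree, depth 3 dB.  Overlapping
  shadows do not stack (the deepest applies).
* **Arcuate defects**: bands in bundle coordinates
  (|θ − centre| ≤ halfwidth, d in range) with a fixed depth in dB.
  Defects only subtract sensitivity.

Synthetic cohorts define the study conditions for the protocol harnesses:
healthy eyes draw GH ~ N(0, 1 dB), age uniform 45–75 y, blind-spot centre
jittered by 0.5 degrees per axis; glaucomatous eyes add one arcuate defect
with entry angle ±(100–140) degrees, halfwidth 10–20 degrees, extent from 6
to 15–24 degrees, depth 8–20 dB, on a base with GH ~ N(−2, 1.5 dB).  These
are realistic single-defect approximations; no attempt is made to match any
human cohort's demographics, and the human-measured quantities (absolute
false-positive percentages, GH repeatability of 2.4–2.6 dB, protocol
trigger counts) are therefore reproduced in *shape* but not asserted in
value.

## Blind-spot search

Implemented exactly as specified by the march rules (17 dB stimuli, 0.43
degree diameter; 2/1 degree horizontal steps at y = −3 from x = 6; 3/1
degree vertical steps from y = −18).  Decisions where the procedure text is
silent:

* If the very first stimulus is not seen, the search backs off nasally in
  2 degree steps until a seen response before starting the temporal march.
* The final vertical march is a continuous 1 degree march crossing the
  whole blind spot from below; the first seen response above it defines the
  superior boundary pair.
* A march exceeding 25 degrees (configurable) without the required response
  transition raises a no-blind-spot error.  Noise-corrupted searches are
  allowed to return wrong answers, as with human observers; no retest logic
  is added.

For a noiseless observer the error is bounded by the step size (1 degree)
per axis; the test suite checks recovery within 1 degree over 50 random
ellipse placements that span the y = −3 search line, as the physiological
blind spot does.

## GH ZEST

Candidate-threshold domain [−5, 45] dB at 0.1 dB resolution; prior Gaussian
N(25, 6) truncated to the domain (truncation moves the prior mean by about
0.01 dB).  Likelihood is a cumulative Gaussian of slope 1.0 dB with 0.03
asymptotes — standard ZEST choices, configurable.  Stimuli are placed at
the posterior mean.  "Dimmest seen" means seen presentations with the
highest dB; ties break by presentation order.  The shared posterior is not
reset after the four retest locations are selected, and responses from
non-selected locations are not purged.  The final four presentations are
ordered by the run's seeded generator.

Parameter recovery on the default simulated conditions is within ±1 dB of
truth (mean over 100 seeds) for GH of 0, −3 and −6 dB, and the dimmest-seen
selection keeps two deeply damaged circle locations from dragging the
estimate below −2 dB when true GH is 0.

## Circle perimetry

Angle 0 of the 25-per-ring layout points along the temporal horizontal
(toward the fovea), increasing superiorly — an arbitrary but fixed
convention.  The first 75 presentations run in a seeded random order; a
missed location is re-queued at a random position at least 5 presentations
later (the procedure requires only "not immediately after"; 5 is the
package's choice).  The neighbour relation is the 4-neighbourhood on the
polar grid (same ring ± one angle step, adjacent ring at the same angle
index), the conservative reading of "nearest neighbour"; the two
missed-twice locations of the cluster rule must be mutual neighbours
(a component-wide mode is available via a flag).  The "three neighbouring
missed on first presentation" clause counts locations missed at least once,
since a missed-twice location was also missed on its first presentation.

## Bundle coordinates

The default trajectory model uses the published average nerve-fibre-bundle
functional form: in a blind-spot-centred polar frame,
`φ(r) = φ0 + b(φ0)·(r − r0)^c(φ0)` with r0 = 4 degrees and separate
superior/inferior coefficient maps (hyperbolic-tangent functions of the
disc entry angle), re-expressed in right-eye visual-field coordinates.
Entry angles use θ = 0 for the nasal horizontal reference bundle, superior
family θ ∈ (0, 180).  Within r0 the bundles run radially.  Numerical
details:

* `to_bundle` inverts the trajectory map by bracketing on a 0.5 degree
  φ0 grid followed by Brent root finding (tolerance 10⁻¹²); results are
  cached per location.  Round-trip error is below 10⁻⁶ degrees on the
  tested domain.
* Trajectories are truncated at the nasal horizontal so the chart stays
  single-valued; a (d, θ) pair whose trajectory would cross it raises a
  domain error.
* Raphe handling: temporal to the fovea the hemifield is assigned by the
  sign of y (the anatomical raphe follows the foveal horizontal); the thin
  strip between the foveal and disc horizontals that the assigned family
  cannot reach, and the raphe-adjacent zone below the most arcuate bundle,
  clamp to that family's most arcuate bundle.  θ is discontinuous across
  the raphe by construction.
* A simplified linear-spiral family (constant curvature 1.5 deg/deg) is
  selectable via configuration and satisfies the same interface; all
  downstream code depends only on the (d, θ) contract.

Because the exact published parameterization is not restated in the test
procedures themselves, the model here is a faithful functional-form
implementation rather than a digit-for-digit copy; individualized,
per-eye trajectory fitting is out of scope.

## High-density delineation

A location counts as *non-seen* when it is missed on both presentations
(the retest rule applies to high-density locations too).  Edge
identification bins non-seen points by distance (bin width = grid spacing,
one bin per sampled annulus) and takes the min-/max-θ point per bin; edges
and middle path are ordinary least squares of θ on d (an exact
interpolation for two points; a zero-slope fit through the mean θ when all
points share one annulus).  Stage geometry:

* Projection extends the candidate region to `max d of non-seen + 4`
  degrees, capped by the stage radius 6 + 4k, so the region stops growing
  when the defect does — this is what makes the no-new-locations stop
  reachable.
* Orthogonal expansion is computed in Cartesian space against the local
  tangent of the middle curve (finite differences, h = 0.25 degrees);
  displaced edge points are re-expressed in bundle space and refitted, and
  candidate membership is tested between the displaced-edge lines.
* Candidates live on a fixed 2 degree Cartesian grid (the procedure never
  states a spacing; 2 degrees is "high density" relative to conventional 6
  degree grids), deduplicated against all tested locations at 0.5 degrees,
  and clipped at 30 degrees from the fovea.
* Previous-stage fits drive projection/expansion; refitting is cumulative
  over all accumulated non-seen points.  Scotomata whose selected regions
  intersect are merged.  The operator stop is a maximum stage count
  (default 6).
* Termination reasons: `no-new-locations` (empty selection, or no non-seen
  points survive stage 1), `reached-boundary` (a non-seen location within
  one grid spacing of the 30 degree limit), `operator-stop` (max stage).

On the default glaucoma conditions (15 dB defect over d = 6–20), the
delineated non-seen set overlaps the ground-truth band with Jaccard ≥ 0.5
in at least 80% of seeds (typically ≈ 1.0), and false-positive-triggered
runs in healthy eyes collapse early with few non-seen locations.

## Study statistics

The repeatability index is 1.96 × the sample SD (n − 1 denominator) of
test-retest differences; Bland-Altman limits are the mean difference ∓ the
index.  `fp_by_offset` locates the blind spot and estimates GH once per eye
and reuses the reference field across offsets, as the specificity protocol
does.  The packaged clinical table ships as CSV with a SHA-256 checksum
verified on load; minus signs were normalized to ASCII in transcription.
In the protocol harnesses, a cluster is labelled superior-temporal if the
mean bundle entry angle of its members is positive, inferior-temporal
otherwise.  The harnesses apply an operator-plausibility rule: a blind-spot
estimate more than 5 degrees from the anatomically expected centre (deep
scotomata crossing the march lines can corrupt the search) is replaced by
the expected centre, as an operator would reposition a live test.

## Problem sizes

Simulation-based validation uses the sizes stated with each property:
50 ellipse placements for the blind-spot search, 100 seeds per GH level,
1,000 random category maps for the detection oracle, 20 seeds for
delineation overlap, 50 eyes for specificity monotonicity, 100 random
datasets for repeatability arithmetic.  These sizes give comfortable
margins on every asserted bound while keeping the full suite fast.

## Known limitations

* Fixation instability, response times and tracker pauses are not
  modelled; neither is threshold mapping inside a scotoma, multi-session
  merging, or progression analysis.
* The normative surface is radially symmetric; real hills of vision are
  not, and the GH circle's "roughly uniform sensitivity" assumption is
  exactly true here but only approximate in real eyes.
* Vessel-shadow and defect geometry are idealized bands; passing tests
  show algorithmic correctness under the stated observer model, not
  clinical performance.
* θ fits near the raphe (|θ| → 180) can wrap; simulated defects keep away
  from the raphe, and the fits are not wrap-aware.
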