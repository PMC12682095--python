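"""Suprathreshold circle perimetry and scotoma-cluster detection.

A glaucomatous simulated eye carries a 15 dB arcuate defect along the
superior bundle band (entry angles 105-135 degrees, 6-20 degrees from the
blind spot).  Stimuli at 75 locations on the 6/8/10 degree circles are set
5 dB brighter than the GH-adjusted reference threshold; misses are retested
once.  The nearest-neighbour cluster rule (two adjacent missed-twice, or
three connected missed-once locations) should flag the defect where the
band crosses the circles.
"""

from targetperim import (
    ArcuateDefectSpec,
    BundleModel,
    FieldLocation,
    NormativeModel,
    Observer,
    ReferenceField,
    circle_locations,
    detect_scotomata,
    false_positive_rate,
    make_glaucoma_field,
    make_healthy_field,
    run_circle_perimetry,
)

bs_centre = FieldLocation(15.0, -1.5)
normative = NormativeModel()
bundles = BundleModel(bs_centre=bs_centre)
defect = ArcuateDefectSpec(
    bundle_angle_centre=120.0, bundle_angle_halfwidth=15.0,
    distance_range=(6.0, 20.0), depth=15.0,
)
field = make_glaucoma_field(make_healthy_field(normative=normative), [defect], bundles)
observer = Observer(true_field=field, rng_seed=11)

grid = circle_locations(bs_centre)
reference = ReferenceField(normative, gh=0.0, age=45.0)
result = run_circle_perimetry(observer, grid, reference, offset=5.0)
clusters = detect_scotomata(result.categories)

print(f"presentations: {result.n_presentations} "
      f"(75 first passes + {result.n_presentations - 75} retests)")
print(f"missed at least once: {false_positive_rate(result.categories):.1f}% of locations")
for i, cluster in enumerate(clusters, 1):
    members = sorted(cluster.member_indices)
    print(f"scotoma {i}: {len(members)} locations, rule = {cluster.trigger}")
    for ring, angle in members:
        loc = grid.location((ring, angle))
        print(f"  ring {ring} ({[6, 8, 10][ring]} deg), angle {angle * 14.4:5.1f} deg "
              f"-> ({loc.x:6.2f}, {loc.y:6.2f}), {result.categories[(ring, angle)].value}")
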