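"""Delineate an arcuate scotoma with staged high-density perimetry.

After circle perimetry flags a cluster, the high-density algorithm retests
the cluster and its neighbourhood (stage 1), then repeatedly: fits the
scotoma's two edges and middle path as lines in bundle coordinates
(distance from the blind spot, bundle entry angle), projects the scotoma
4 degrees farther from the blind spot, expands both edges 4 degrees
orthogonally, and tests the untested 2-degree grid locations inside.  It
stops when no new locations are selected or the 30 degree test boundary is
reached.  The printed Jaccard index compares the delineated non-seen set
with the ground-truth defect band over all tested locations.
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
    make_glaucoma_field,
    make_healthy_field,
    run_circle_perimetry,
    run_high_density,
)

bs_centre = FieldLocation(15.0, -1.5)
normative = NormativeModel()
bundles = BundleModel(bs_centre=bs_centre)
defect = ArcuateDefectSpec(120.0, 15.0, (6.0, 20.0), depth=15.0)
field = make_glaucoma_field(make_healthy_field(normative=normative), [defect], bundles)
observer = Observer(true_field=field, rng_seed=3)

grid = circle_locations(bs_centre)
reference = ReferenceField(normative, gh=0.0, age=45.0)
circle_result = run_circle_perimetry(observer, grid, reference, offset=5.0)
clusters = detect_scotomata(circle_result.categories)
print(f"circle perimetry flagged {len(clusters)} cluster(s)")

hd = run_high_density(observer, reference, 5.0, clusters, grid, bundles)
scotoma = max(hd.scotomata, key=lambda s: len(s.non_seen_locations))

tested = set(hd.categories)
truth = {loc for loc in tested if defect.covers(bundles.to_bundle(loc))}
pred = set(scotoma.non_seen_locations)
jaccard = len(pred & truth) / len(pred | truth)

print(f"high-density presentations: {len(hd.presentations)}")
print(f"stages completed: {scotoma.stages_completed}, "
      f"termination: {scotoma.termination_reason}")
print(f"non-seen locations: {len(pred)} (truth band covers {len(truth)} tested)")
print(f"Jaccard overlap with truth: {jaccard:.2f}")
fit = scotoma.fit
print(f"edge fits (theta = a + b*d): low ({fit.edge_low.intercept:.1f}, "
      f"{fit.edge_low.slope:+.2f}), high ({fit.edge_high.intercept:.1f}, "
      f"{fit.edge_high.slope:+.2f}), middle ({fit.middle.intercept:.1f}, "
      f"{fit.middle.slope:+.2f})")
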