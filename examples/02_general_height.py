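"""Estimate the general height (GH) of a globally depressed eye.

The simulated eye sits 3 dB below the age-corrected normal surface.  Twelve
ZEST presentations at eight locations on a 6 degree circle around the blind
spot (prior N(25 dB, 6 dB), shared posterior, four dimmest-seen locations
retested) recover the depression: GH is the posterior mean minus the mean
normal threshold at those locations, so a healthy eye gives ~0 dB and this
one should give about -3 dB.
"""

from targetperim import FieldLocation, NormativeModel, Observer, estimate_gh, make_healthy_field

normative = NormativeModel()
true_gh = -3.0
field = make_healthy_field(normative=normative, gh=true_gh, age=60.0)
observer = Observer(true_field=field, rng_seed=7)

result = estimate_gh(observer, FieldLocation(15.0, -1.5), normative, age=60.0)

print(f"true GH:           {true_gh:+.1f} dB")
print(f"estimated GH:      {result.gh:+.2f} dB")
print(f"ZEST estimate:     {result.zest_estimate:.2f} dB "
      f"(mean normal {result.mean_normal:.2f} dB)")
print(f"selected angles:   {result.selected_locations} deg (dimmest seen)")
print("presentation log:")
for p in result.presentations:
    print(f"  ({p.loc.x:6.2f}, {p.loc.y:6.2f})  {p.stimulus_db:5.2f} dB  "
          f"{'seen' if p.seen else 'not seen'}")
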