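"""Cohort-level statistics: specificity, repeatability and the clinical table.

Three quick studies on synthetic cohorts plus the packaged clinical table:

* false positive rate of circle perimetry as a function of the
  suprathreshold offset (specificity falls off sharply below ~4 dB);
* test-retest repeatability of GH, summarised by the repeatability index
  (1.96 x SD of the differences, the half-width of Bland-Altman limits);
* counting summaries of the packaged table of glaucoma circle-perimetry
  outcomes (26 eyes of 18 patients).
"""

from targetperim import (
    count_deep_pd_sectors,
    count_rnfl_flags,
    count_scotoma_eyes,
    count_scotoma_sectors,
    fp_by_offset,
    healthy_cohort,
    load_glaucoma_table,
    run_protocol,
)

print("-- false positives by offset (20 healthy simulated eyes) --")
table = fp_by_offset(healthy_cohort(20, seed=42), offsets=[2.0, 3.0, 4.0, 5.0])
for row in table.itertuples(index=False):
    print(f"  offset {row.offset:.0f} dB: {row.mean_fp_pct:5.2f}% "
          f"+/- {2 * row.sem_fp_pct:.2f} (2 SEM)")

print("-- GH test-retest (protocol 2, 15 healthy simulated eyes) --")
report = run_protocol(2, n_eyes=15, seed=42)
for pairing, rep in report.gh_repeatability.items():
    print(f"  {pairing}: mean difference {rep.mean_difference:+.2f} dB, "
          f"repeatability index {rep.repeatability_index:.2f} dB")

print("-- packaged glaucoma circle-perimetry table --")
rows = load_glaucoma_table()
print(f"  eyes tested: {len(rows)}, patients: {len({r.patient_id for r in rows})}")
print(f"  scotoma sectors: {count_scotoma_sectors(rows)} "
      f"in {count_scotoma_eyes(rows)} eyes")
print(f"  sectors with 24-2 PD <= -5 dB near disc: "
      f"{count_deep_pd_sectors(rows, -5.0)}")
print(f"  RNFL flags among scotoma sectors: "
      f"ONL {count_rnfl_flags(rows, 'ONL')}, BL {count_rnfl_flags(rows, 'BL')}")
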