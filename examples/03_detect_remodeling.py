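"""Detect and quantify a planted bone-remodeling lesion end to end.

Generates a 35-subject cohort with a known -12% lesion over 15% of the
bone area, runs the full pipeline (segment, landmark, register, paired
t-test, Benjamini-Hochberg), and prints the recovered area and magnitude
in the standard remodeling summary layout.
"""

from dxarfa import CohortSpec, LesionSpec, generate_cohort
from dxarfa.pipeline import analyze_cohort_scans

spec = CohortSpec(
    n_subjects=35,
    visit_months=(0, 24),
    lesions=(
        LesionSpec(
            region="lesser_trochanter",
            magnitude_pct=-12.0,
            target_area_fraction=0.15,
        ),
    ),
    noise_sd_gcm2=0.05,
    shape_jitter_mm=2.0,
    rng_seed=7,
)
analysis = analyze_cohort_scans(generate_cohort(spec).scans)
s = analysis.summaries[24.0]
tm = analysis.test_maps[24.0]

print(f"tested pixels N = {tm.N} (bone pixels with >= 5 subjects)")
print("                         Area (%)   Mean BMD change (%)")
print(f"  total significant      {s.area_total_pct:7.1f}")
print(f"  increased BMD          {s.area_increase_pct:7.1f}   {s.mean_change_increase_pct:10.1f}")
print(f"  decreased BMD          {s.area_decrease_pct:7.1f}   {s.mean_change_decrease_pct:10.1f}")
print()
print("The decreased-BMD row should recover the planted lesion: "
      "~15% of bone area at ~-12% of baseline BMD. Any increased-BMD "
      "area is false discovery and should be near zero.")
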