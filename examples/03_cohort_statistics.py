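"""Longitudinal paired-limb statistics on a simulated cohort.

Simulates a 12-animal cohort whose group means/SDs follow the published
trabecular separation (Tb.Sp) summaries — MIA-injected limb vs
contralateral saline control at 2, 6, and 10 weeks — then runs the full
inferential recipe: normality screen, two-way repeated-measures ANOVA,
ANOVA-gated paired t-tests, Holm stepdown adjustment.
"""

import osteoct as o
from osteoct import reference_tables as rt

design = rt.reference_cohort_design(parameters=["Tb.Sp"], seed=20)
cohort = o.simulate_cohort(design)
dataset = o.LongitudinalDataset(cohort)

sample = dataset.matrix("Tb.Sp", "total")[(2, "MIA")]
print(f"Shapiro-Wilk normality p = {o.check_normality(sample):.3f} "
      "(> 0.05: no evidence against normality)")

a = o.rm_anova(dataset, "Tb.Sp", "total")
print(f"time effect           F = {a.f_time:7.2f}, p = {a.p_time:.2g}")
print(f"time x group effect   F = {a.f_interaction:7.2f}, "
      f"p = {a.p_interaction:.2g}")

print("\nper-timepoint paired t-tests (Holm-adjusted):")
for r in o.paired_tests(dataset, "Tb.Sp", "total"):
    flag = "*" if r.significant else " "
    print(f"  week {r.week:>2}: MIA {r.mean_mia:5.1f} vs control "
          f"{r.mean_control:5.1f} μm, %d = {r.pct_diff:+5.1f}, "
          f"p_holm = {r.p_holm:.4f} {flag}")

print("\nThe MIA limb shows the designed higher Tb.Sp (trabecular "
      "erosion) at every timepoint; the growth-driven decrease over time "
      "appears as the large time-effect F.")
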