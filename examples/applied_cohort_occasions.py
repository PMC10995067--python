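"""Cubic meta-regression of a cohort-by-occasion table (FTO/BMI-style).

Builds an emulated table shaped like an early-life SNP/BMI meta-analysis
input — 8 cohorts reporting per-allele effects at 10 ages from 0 to 13 years,
with follow-up attrition — whose generating effect is negative in infancy and
positive from mid-childhood.  The pipeline pools all rows by fixed-effect
meta-analysis (which averages the sign change away), then fits an uncentred
cubic meta-regression with overlap-adjusted SEs (the same cohort contributes
correlated rows at several ages) and reports heterogeneity before and after
the age moderators.
"""

from agemeta import AppliedConfig, run_applied
from agemeta.synthdata import emulate_applied_table

table = emulate_applied_table(n_cohorts=8, occasions_per_cohort=10, seed=1)
report = run_applied(AppliedConfig(table=table))

print(report.text_summary())
print()
print("The fixed-effect pool hides the age-varying association; the cubic")
print("meta-regression recovers the sign change and the age moderators absorb")
print(f"most of the heterogeneity ({report.i2_unadjusted:.1f}% -> "
      f"{report.i2_residual:.1f}% residual I^2).")
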