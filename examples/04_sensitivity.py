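"""Sensitivity analyses: Year-2 censoring and complete-records restriction.

Re-runs the g-computation ATE for unplanned hospitalisation after (a)
truncating every pupil's follow-up at the end of Year 2 and (b) keeping
only pupils with fully observed confounders (instead of the
missing-indicator expansion).  Under the generator's conditions both should
move the estimate only within sampling noise.
"""

import warnings

import emultrial as et
from emultrial.prep import complete_records_filter, restrict_followup
from emultrial.propensity import TreatmentContrast

warnings.simplefilter("ignore")
CON = TreatmentContrast("Support", "None")

cohort = et.generate_cohort(et.default_config(), seed=5).data
table = et.build_analysis_table(cohort)

base = et.estimate_gcomp(table, "hospital", CON).point
print(f"full follow-up, MCIM design       : RaR_g = {base:.3f}")

year2 = et.build_analysis_table(restrict_followup(cohort, horizon_year=2))
e2 = et.estimate_gcomp(year2, "hospital", CON).point
print(f"censored at end of Year 2         : RaR_g = {e2:.3f}")

cr, retained = complete_records_filter(table)
ecr = et.estimate_gcomp(cr, "hospital", CON).point
print(f"complete records ({100 * retained:.0f}% retained)    : RaR_g = {ecr:.3f}")
print("\nStable estimates across these restrictions mirror the robustness "
      "checks an analyst would run before trusting the main result.")
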