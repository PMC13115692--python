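"""Sex/gonadectomy modifier analyses among risk-allele carriers.

Simulates a carrier survival cohort with known effects (male HR 3.0,
gonadectomy HR 2.7 under the 5-year landmark), then runs the full modifier
pipeline: onset summaries by sex, the Firth logistic modifier model, the
counting-process construction, the time-varying Cox fit with robust errors
clustered by dog, and the proportional-hazards check.
"""

import numpy as np

import riskhapscan as rhs
from riskhapscan.survival import ExposureDefinition

cohort = rhs.simulate_survival_cohort(
    400, seed=11, male_log_HR=np.log(3.0), gonadectomy_log_HR=np.log(2.7),
    censor_age=5.0)
carriers = cohort.table.assign(dosage=1)  # everyone carries >= 1 risk allele

for s in rhs.onset_summary(carriers):
    print(f"onset, sex {s.group}: n = {s.n}, median {s.median:.2f} y "
          f"(IQR {s.q25:.2f}-{s.q75:.2f})")

definition = ExposureDefinition(landmark_years=5.0)
logit = rhs.firth_modifier_model(carriers, definition)
print("\nFirth modifier model (status ~ exposure + sex):")
print(logit.summary().round(3).to_string(index=False))

cp = rhs.build_counting_process(carriers, definition)
fit = rhs.cox_tv_fit(cp)
print(f"\ntime-varying Cox ({fit.n_events} events):")
for j, term in enumerate(fit.terms):
    print(f"  {term}: HR = {fit.hr[j]:.2f} "
          f"(95% CI {fit.ci_low[j]:.2f}-{fit.ci_high[j]:.2f}, "
          f"robust p = {fit.p_values[j]:.3g})")

print("\nproportional-hazards check (Schoenfeld):")
print(rhs.ph_check(fit, cp).round(3).to_string(index=False))
# The Cox HRs should bracket the configured values (3.0 male, 2.7
# gonadectomy); non-significant PH checks mean the proportionality
# assumption is consistent with the data that generated them.
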