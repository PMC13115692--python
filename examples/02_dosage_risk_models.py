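"""Dosage-risk modeling on the published lead-marker count table.

Expands the pooled genotype-count table (discovery + follow-up cohorts,
170 dogs) into an additive dosage design with a cohort indicator, then fits
the Firth-penalized model (primary: finite even though no control is a
risk-allele homozygote) and the ML logistic sensitivity fit.
"""

import riskhapscan as rhs
from riskhapscan.datasets import lead_marker_dosage_table

table = lead_marker_dosage_table()
X, y, w, terms = rhs.expand_table(table)

firth = rhs.firth_logistic(X, y, w, terms=terms)
mle = rhs.mle_logistic(X, y, w, terms=terms)

print("Firth-penalized fit:")
print(firth.summary().round(4).to_string(index=False))
print(f"\nper-allele OR = {firth.or_('dosage'):.1f} "
      f"(beta = {firth.coef('dosage'):.2f}, "
      f"penalized-LRT p = {firth.p_values[terms.index('dosage')]:.2e})")
print(f"ML sensitivity fit: OR = {mle.or_('dosage'):.1f} "
      f"(beta = {mle.coef('dosage'):.2f})")

s = rhs.contingency_summaries(table.pooled)
print(f"\npooled dosage-1 penetrance: {100 * s['penetrance_by_dosage'][1]:.0f}%")
print(f"pooled control carrier fraction: "
      f"{100 * s['control_carrier_fraction']:.1f}%")
# Each extra risk allele multiplies the odds of epilepsy ~6.6-fold under the
# penalized fit (~7.0 unpenalized); heterozygote penetrance is ~61%.
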