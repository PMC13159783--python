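"""Generate a synthetic very-preterm cohort and inspect its structure.

The generator draws gestational-age strata, perinatal covariates, a latent
maturation delay at 34 weeks PMA per infant, and ASQ-3 outcomes under a
logistic model in that delay.
"""

import numpy as np

from neomat.synthetic import CohortGenConfig, cohort_frame, generate_cohort

config = CohortGenConfig(n_infants=132, seed=7)
records = generate_cohort(config)
df = cohort_frame(records)

print(f"cohort of {len(df)} infants")
print("\nGA strata (fraction):")
print(df["ga_stratum"].value_counts(normalize=True).round(3).to_string())
print("\nlatent ΔHRV at 34 weeks by stratum (median weeks):")
print(df.groupby("ga_stratum")["latent_delta34"].median().round(2).to_string())
print(f"\nASQ follow-up available: {df['followup'].mean():.0%}")

# The stratum medians show the maturation-delay gradient the delay model is
# calibrated to: the least mature stratum (<26 weeks GA) carries the
# largest delay, the most mature (>=28 weeks) the smallest.
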