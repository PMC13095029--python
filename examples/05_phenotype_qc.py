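"""Phenotype QC: gestation window, self-report cleaning, SD outliers.

Plants one violation of each exclusion rule in a 500-pair cohort and runs
the QC chain. The audit names exactly the planted records, and the
sample-size rule reproduces the published per-cohort SD multipliers
(k = 3 at n = 625, k = 4 at n = 4,550).
"""

import numpy as np
import pandas as pd

from kirhla import apply_qc, sd_k_from_n

rng = np.random.default_rng(1)
n = 500
pairs = pd.DataFrame({
    "pair_id": [f"P{i:03d}" for i in range(n)],
    "birth_weight": rng.normal(3500, 470, n),
    "gestational_age": rng.uniform(37.5, 42.5, n),
})
pairs.loc[0, "gestational_age"] = 34.0                  # preterm
pairs.loc[1, "gestational_age"] = 43.0                  # post-term boundary
pairs.loc[2, "birth_weight"] = 3500 + 7 * 470           # gross outlier

kept, audit = apply_qc(pairs, k=4)
print(f"kept {len(kept)} of {n}; exclusions:")
print(audit.to_string(index=False))

print("\nSD multipliers from the sample-size rule:")
for n_cohort in (625, 4550):
    print(f"  n = {n_cohort:5d} -> k = {sd_k_from_n(n_cohort)}")
print("Cohorts whose published k differs from the rule take an explicit "
      "override (apply_qc(..., k=4)).")
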