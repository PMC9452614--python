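"""Remove the acquisition batch effect from a feature table with ComBat.

Fits the parametric empirical-Bayes location/scale model per batch and
feature, then compares the between-batch separation of a gain-sensitive
feature before and after correction.
"""

import numpy as np
from scipy import stats

from lipomics.combat import harmonize
from lipomics.features import extract_cohort_in_memory
from lipomics.phantom import small_spec

table = extract_cohort_in_memory(small_spec(seed=3, n_cases=24, confounding=0.0))
corrected, model = harmonize(table)

print(f"fitted batches: {model.batch_levels}; EB iterations per batch: {model.n_iter.tolist()}\n")
print(f"{'feature':16s} {'raw p (Welch)':>14s} {'corrected p':>12s}")
for f in ["hist_mean", "hist_variance", "glcm_contrast", "gabor_mean_theta000"]:
    p_raw = stats.ttest_ind(table.loc[table.batch == 0, f], table.loc[table.batch == 1, f],
                            equal_var=False).pvalue
    p_cor = stats.ttest_ind(corrected.loc[corrected.batch == 0, f],
                            corrected.loc[corrected.batch == 1, f], equal_var=False).pvalue
    print(f"{f:16s} {p_raw:14.2e} {p_cor:12.3f}")

print("\nraw intensity features separate the batches almost perfectly "
      "(tiny p values); after harmonization the batch means are "
      "statistically indistinguishable, while class labels pass through untouched:",
      bool((corrected.label == table.label).all()))
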