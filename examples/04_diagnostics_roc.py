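"""Can the CTC count distinguish patients from healthy donors?

Empirical ROC with Mann-Whitney AUC and Hanley-McNeil CI, plus
sensitivity/specificity with Wilson score intervals at a fixed cutoff.
"""

import numpy as np

from ctcher2 import diagnostic_metrics, roc_curve

rng = np.random.default_rng(0)
patient_counts = np.concatenate([np.zeros(4), rng.geometric(0.05, 16)])  # skewed, some zeros
donor_counts = rng.integers(0, 3, 10).astype(float)

scores = np.concatenate([patient_counts, donor_counts])
labels = np.concatenate([np.ones(20, int), np.zeros(10, int)])
roc = roc_curve(scores, labels)
t, j = roc.youden_optimal()
print(f"AUC = {roc.auc:.3f}, 95% CI ({roc.auc_ci[0]:.3f}, {roc.auc_ci[1]:.3f})")
print(f"Youden-optimal count threshold = {t:g} (J = {j:.2f})")

# metrics at the >=3 cutoff
tp = int((patient_counts >= 3).sum())
fn = len(patient_counts) - tp
fp = int((donor_counts >= 3).sum())
tn = len(donor_counts) - fp
m = diagnostic_metrics(tp, fp, tn, fn)
print(
    f"at >=3 CTCs: sensitivity {m.sensitivity:.1%} "
    f"({m.sensitivity_ci[0]:.1%}-{m.sensitivity_ci[1]:.1%}), "
    f"specificity {m.specificity:.1%} "
    f"({m.specificity_ci[0]:.1%}-{m.specificity_ci[1]:.1%})"
)
# sensitivity is limited by patients who genuinely shed few CTCs;
# specificity is high because healthy donors rarely exceed the cutoff.
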