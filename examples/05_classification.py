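"""Sparse classification of group membership from the metric features.

Simulates a 40 + 40 cohort with effects on four axes, assembles the
43-column feature pool (gamma > 35 Hz and DFA excluded), trains the
L1-penalized logistic model on a stratified 70/30 split with the 1-SE rule
and reports held-out performance and the selected features.
"""

import numpy as np

from eegcrit import (
    CohortSpec,
    assemble_features,
    evaluate,
    fit_lasso_classifier,
    gen_cohort,
    split_stratified,
)
from eegcrit.metrics import metric_table

spec = CohortSpec(
    n_hc=40, n_mdd=40, n_channels=2, fs=250.0,
    effects={(4, "bis"): -1.2, (6, "ei_hls"): -1.2, (8, "ei_hlp"): 1.2,
             (7, "fei"): -1.2},
    seed=6,
)
recordings, _ = gen_cohort(spec)
table = metric_table(recordings)

fm = assemble_features(table)  # 43 columns
rng = np.random.default_rng(0)
train, test = split_stratified(fm.y, train_frac=0.7, rng=rng)
model = fit_lasso_classifier(fm, train, folds=5, rule="1se", rng=rng)
report = evaluate(model, fm.X[test], fm.y[test])

print(f"features: {len(fm.columns)}; training subjects: {train.size}; "
      f"test subjects: {test.size}")
print(f"selected lambda = {model.lam:.4f}; nonzero coefficients: {len(model.nonzero)}")
for name, weight in sorted(model.nonzero, key=lambda t: -abs(t[1])):
    print(f"  {name:22s} {weight:+.3f}")
print(f"test AUC = {report.auc:.3f}, accuracy = {report.accuracy:.3f}, "
      f"sensitivity = {report.sensitivity:.3f}, specificity = {report.specificity:.3f}")
# The nonzero weights should concentrate on the implanted axes; held-out AUC
# well above chance indicates the multivariate signature generalizes.
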