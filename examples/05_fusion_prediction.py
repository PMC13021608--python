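"""Stack radiomic and clinical gradient-boosting models into a fusion model.

Both component models are tuned by random search over the printed grid on
an identical stratified 5-fold split; their out-of-fold probabilities are
combined by logistic regression, and the operating threshold is frozen
from the training OOF probabilities (Youden's J) before test evaluation.
"""

import numpy as np

from lesionbai.fusion import (
    SearchSpace, evaluate_classifier, fit_fusion, oof_probabilities,
    random_search, youden_threshold,
)

rng = np.random.default_rng(0)
n = 240
y = (rng.random(n) < 0.3).astype(int)
X_rad = rng.normal(size=(n, 12)); X_rad[:, 0] += 0.9 * y   # radiomic block
X_cli = rng.normal(size=(n, 3));  X_cli[:, 0] += 1.1 * y   # clinical block (e.g. BAI)

train, test = np.arange(0, 180), np.arange(180, n)
space = SearchSpace(n_draws=8, seed=0)
best_rad, _ = random_search(X_rad[train], y[train], space, seed=0)
best_cli, _ = random_search(X_cli[train], y[train], space, seed=0)

p_rad, folds = oof_probabilities(best_rad, X_rad[train], y[train], seed=0)
p_cli, _ = oof_probabilities(best_cli, X_cli[train], y[train], seed=0, fold_map=folds)
model = fit_fusion(p_rad, p_cli, y[train], radiomic_params=best_rad,
                   clinical_params=best_cli, X_radiomic=X_rad[train],
                   X_clinical=X_cli[train], fold_map=folds, seed=0)

from lesionbai.fusion import stacked_probabilities
threshold = youden_threshold(stacked_probabilities(model, p_rad, p_cli), y[train])
report = evaluate_classifier(model.predict_proba(X_rad[test], X_cli[test]),
                             y[test], threshold=threshold, seed=0)
print(f"test AUC {report['auc']:.3f} "
      f"(95% CI {report['auc_ci'][0]:.3f}-{report['auc_ci'][1]:.3f})")
print(f"sensitivity {report['sensitivity']:.2f}, specificity "
      f"{report['specificity']:.2f} at threshold {report['threshold']:.2f}")
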