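"""Clinic-radiomic fusion model of glioma-related epilepsy.

Two gradient-boosted tree classifiers (radiomic features; clinical
variables including the Brain Age Index) are tuned by random search over a
printed hyperparameter grid, maximizing mean AUC over a fixed stratified
5-fold split. Their out-of-fold (OOF) predicted probabilities — each
subject's probability produced by a model that never saw it — are stacked
by a logistic regression, giving the combined model. Both component models
share the identical fold map and seed so the stacking never leaks
in-fold information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SearchSpace",
    "FusionModel",
    "random_search",
    "oof_probabilities",
    "fit_fusion",
    "evaluate_classifier",
    "youden_threshold",
]

_LGBM_FIXED = dict(n_estimators=100, verbosity=-1, n_jobs=1)


@dataclass
class SearchSpace:
    """The random-search grid for the gradient-boosting classifiers."""

    learning_rate: tuple = (0.01, 0.05, 0.1)
    num_leaves: tuple = (31, 63, 127)
    max_depth: tuple = (5, 7, 10, -1)
    min_data_in_leaf: tuple = (20, 50)
    lambda_l1: tuple = (0.0, 0.1, 0.01)
    lambda_l2: tuple = (0.0, 0.1, 0.01)
    feature_fraction: tuple = (0.8, 0.9, 1.0)
    n_draws: int = 50
    seed: int = 0

    def grid(self) -> list[dict]:
        keys = [
            "learning_rate", "num_leaves", "max_depth", "min_data_in_leaf",
            "lambda_l1", "lambda_l2", "feature_fraction",
        ]
        values = [getattr(self, k) for k in keys]
        return [dict(zip(keys, combo)) for combo in itertools.product(*values)]

    def sample(self) -> list[dict]:
        """Draw ``n_draws`` configurations, without replacement if possible."""
        grid = self.grid()
        rng = np.random.default_rng(self.seed)
        if self.n_draws >= len(grid):
            return grid
        idx = rng.choice(len(grid), size=self.n_draws, replace=False)
        return [grid[int(i)] for i in idx]


def _make_lgbm(params: dict, seed: int) -> LGBMClassifier:
    p = dict(params)
    p["min_child_samples"] = p.pop("min_data_in_leaf", 20)
    p["reg_alpha"] = p.pop("lambda_l1", 0.0)
    p["reg_lambda"] = p.pop("lambda_l2", 0.0)
    p["colsample_bytree"] = p.pop("feature_fraction", 1.0)
    return LGBMClassifier(random_state=seed, **_LGBM_FIXED, **p)


def random_search(
    X: np.ndarray,
    y: np.ndarray,
    space: SearchSpace,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Random hyperparameter search maximizing mean 5-fold CV AUC.

    The stratified fold split is fixed by the seed and reused for every
    sampled configuration, so trial AUCs are directly comparable. Returns
    the argmax configuration and the full trial table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < folds:
        raise ValueError(f"need two classes with >= {folds} members each")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(skf.split(X, y))
    rows = []
    for params in space.sample():
        aucs = []
        for tr, va in split:
            clf = _make_lgbm(params, seed).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[va], clf.predict_proba(X[va])[:, 1]))
        rows.append({**params, "mean_cv_auc": float(np.mean(aucs))})
    trials = pd.DataFrame(rows)
    best = trials.loc[trials["mean_cv_auc"].idxmax()]
    best_params = {k: best[k] for k in rows[0] if k != "mean_cv_auc"}
    for k in ("num_leaves", "max_depth", "min_data_in_leaf"):
        best_params[k] = int(best_params[k])
    return best_params, trials


def oof_probabilities(
    model_params: dict,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    fold_map: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold probabilities: each subject scored by a model that never saw it.

    Returns (probabilities, fold_map); pass the fold map back in to score a
    second feature block on the identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < folds:
        raise ValueError(f"need >= {folds} subjects for {folds}-fold OOF")
    if fold_map is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_map = np.empty(n, dtype=int)
        for f, (_, va) in enumerate(skf.split(X, y)):
            fold_map[va] = f
    probs = np.empty(n)
    for f in np.unique(fold_map):
        tr = fold_map != f
        va = ~tr
        clf = _make_lgbm(model_params, seed).fit(X[tr], y[tr])
        probs[va] = clf.predict_proba(X[va])[:, 1]
    return probs, fold_map


@dataclass
class FusionModel:
    """Stacked clinic-radiomic classifier.

    The stacking logistic regression was fitted only on out-of-fold
    probabilities (recorded in ``oof_record``); at inference the two
    refitted component models score new data and the stacker combines their
    probabilities.
    """

    radiomic_params: dict
    clinical_params: dict
    stacker: LogisticRegression
    radiomic_model: LGBMClassifier
    clinical_model: LGBMClassifier
    fold_map: np.ndarray
    seed: int
    oof_record: dict = field(default_factory=dict)

    def predict_proba(self, X_radiomic: np.ndarray, X_clinical: np.ndarray) -> np.ndarray:
        p_rad = self.radiomic_model.predict_proba(np.asarray(X_radiomic, dtype=float))[:, 1]
        p_cli = self.clinical_model.predict_proba(np.asarray(X_clinical, dtype=float))[:, 1]
        return self.stacker.predict_proba(np.column_stack([p_rad, p_cli]))[:, 1]


def fit_fusion(
    oof_radiomic: np.ndarray,
    oof_clinical: np.ndarray,
    y: np.ndarray,
    *,
    radiomic_params: dict | None = None,
    clinical_params: dict | None = None,
    X_radiomic: np.ndarray | None = None,
    X_clinical: np.ndarray | None = None,
    fold_map: np.ndarray | None = None,
    seed: int = 0,
) -> FusionModel:
    """Logistic stacking of the two OOF probability streams.

    The stacker sees only out-of-fold probabilities. When the training
    feature blocks and component hyperparameters are supplied, the two
    component models are refitted on the full training set so the returned
    model can score new subjects.
    """
    p_rad = np.asarray(oof_radiomic, dtype=float)
    p_cli = np.asarray(oof_clinical, dtype=float)
    y = np.asarray(y).astype(int)
    if not (len(p_rad) == len(p_cli) == len(y)):
        raise ValueError("OOF streams and labels must have equal length")
    if np.any((p_rad < 0) | (p_rad > 1) | (p_cli < 0) | (p_cli > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.ptp(p_rad) == 0 and np.ptp(p_cli) == 0:
        import warnings

        warnings.warn("both probability streams are constant; fusion is intercept-only")
    stacker = LogisticRegression(max_iter=1000).fit(
        np.column_stack([p_rad, p_cli]), y
    )
    rad_model = cli_model = None
    if X_radiomic is not None and radiomic_params is not None:
        rad_model = _make_lgbm(radiomic_params, seed).fit(np.asarray(X_radiomic, dtype=float), y)
    if X_clinical is not None and clinical_params is not None:
        cli_model = _make_lgbm(clinical_params, seed).fit(np.asarray(X_clinical, dtype=float), y)
    return FusionModel(
        radiomic_params=radiomic_params or {},
        clinical_params=clinical_params or {},
        stacker=stacker,
        radiomic_model=rad_model,
        clinical_model=cli_model,
        fold_map=np.asarray(fold_map) if fold_map is not None else np.array([]),
        seed=seed,
        oof_record={"oof_radiomic": p_rad, "oof_clinical": p_cli, "y": y},
    )


def stacked_probabilities(model: FusionModel, p_rad: np.ndarray, p_cli: np.ndarray) -> np.ndarray:
    """Combine two probability streams with the learned stacking weights."""
    return model.stacker.predict_proba(np.column_stack([p_rad, p_cli]))[:, 1]


def youden_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    cand = np.unique(p)
    best_t, best_j = 0.5, -np.inf
    for t in cand:
        pred = p >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_classifier(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """AUC (rank-based) with stratified-bootstrap 95% CI, plus threshold metrics.

    ``threshold`` should normally be frozen beforehand (e.g. Youden's J on
    the training OOF probabilities); if omitted it is derived from the data
    being evaluated, which is optimistic and flagged in the report.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    auc = float(roc_auc_score(y, p))

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        boot[b] = roc_auc_score(y[idx], p[idx])
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    derived = threshold is None
    t = youden_threshold(p, y) if derived else float(threshold)
    pred = p >= t
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return {
        "auc": auc,
        "auc_ci": (float(ci_low), float(ci_high)),
        "threshold": t,
        "threshold_derived_in_sample": derived,
        "accuracy": float((tp + tn) / y.size),
        "sensitivity": float(tp / (y == 1).sum()),
        "specificity": float(tn / (y == 0).sum()),
        "n": int(y.size),
    }
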