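"""Lesion radiomics and the feature-selection chain for epilepsy prediction.

A compact, fully specified 19-feature radiomic set is computed from the
lesion region (first-order statistics, shape descriptors, and gray-level
co-occurrence texture at distance 1 over the 13 unique 3D directions).
Externally computed feature tables (CSV) flow through the same selection
chain:

    Mann-Whitney filter (raw p < 0.05)
      -> Spearman correlation pruning (|rho| > 0.9, one representative)
      -> iterative redundancy reduction (greedy mean-|rho| rule)
      -> LASSO logistic regression, lambda by 10-fold CV minimum deviance

Features with nonzero LASSO coefficients form the radiomic signature; the
radiomic score is their weighted linear combination on the standardized
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .imaging import LesionMask, Volume

__all__ = [
    "RadiomicSignature",
    "FEATURE_NAMES",
    "extract_features",
    "extract_feature_table",
    "mwu_filter",
    "correlation_prune",
    "iterative_redundancy_reduction",
    "lasso_select",
    "radiomic_score",
    "select_clinical",
    "run_selection_chain",
]

N_GLCM_LEVELS = 32
N_HIST_BINS = 32

#: the 13 unique co-occurrence directions of a 3D 26-neighborhood
_GLCM_OFFSETS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

FEATURE_NAMES = [
    # first order (11)
    "fo_mean", "fo_sd", "fo_skewness", "fo_kurtosis", "fo_median",
    "fo_p10", "fo_p90", "fo_entropy", "fo_energy", "fo_range", "fo_iqr",
    # shape (4)
    "sh_volume_mm3", "sh_surface_voxels", "sh_sphericity", "sh_max_diameter_mm",
    # texture (4)
    "tx_glcm_contrast", "tx_glcm_correlation", "tx_glcm_energy", "tx_glcm_homogeneity",
]


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=int)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def _glcm_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Symmetric distance-1 GLCM averaged over 13 directions, 32 levels."""
    q = np.full(volume.shape, -1, dtype=int)
    q[mask] = _quantize(volume[mask], N_GLCM_LEVELS)
    glcm = np.zeros((N_GLCM_LEVELS, N_GLCM_LEVELS))
    for dz, dy, dx in _GLCM_OFFSETS:
        a = q[
            max(dz, 0) : q.shape[0] + min(dz, 0),
            max(dy, 0) : q.shape[1] + min(dy, 0),
            max(dx, 0) : q.shape[2] + min(dx, 0),
        ]
        b = q[
            max(-dz, 0) : q.shape[0] + min(-dz, 0),
            max(-dy, 0) : q.shape[1] + min(-dy, 0),
            max(-dx, 0) : q.shape[2] + min(-dx, 0),
        ]
        ok = (a >= 0) & (b >= 0)
        np.add.at(glcm, (a[ok], b[ok]), 1.0)
    glcm = glcm + glcm.T  # symmetric
    if glcm.sum() == 0:  # isolated voxels only
        return {
            "tx_glcm_contrast": 0.0,
            "tx_glcm_correlation": 1.0,
            "tx_glcm_energy": 1.0,
            "tx_glcm_homogeneity": 1.0,
        }
    p = glcm / glcm.sum()
    i = np.arange(N_GLCM_LEVELS)[:, None]
    j = np.arange(N_GLCM_LEVELS)[None, :]
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    sd_i = np.sqrt((p * (i - mu_i) ** 2).sum())
    sd_j = np.sqrt((p * (j - mu_j) ** 2).sum())
    if sd_i > 0 and sd_j > 0:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / (sd_i * sd_j))
    else:
        correlation = 1.0  # single gray level: perfectly predictable
    return {
        "tx_glcm_contrast": float((p * (i - j) ** 2).sum()),
        "tx_glcm_correlation": correlation,
        "tx_glcm_energy": float((p**2).sum()),
        "tx_glcm_homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
    }


def extract_features(volume: Volume, mask: LesionMask) -> pd.Series:
    """The 19 named radiomic features of the lesion region (deterministic)."""
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask geometry differ")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty lesion mask: no voxels to extract features from")
    vals = volume.data[m].astype(np.float64)
    spacing = np.asarray(volume.spacing)

    hist, _ = np.histogram(vals, bins=N_HIST_BINS)
    p_hist = hist[hist > 0] / hist.sum()
    entropy = float(-(p_hist * np.log2(p_hist)).sum())

    # surface voxels: lesion voxels with at least one 6-neighbor outside
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
    surface = m & ~eroded
    n_surface = int(surface.sum())
    vol_mm3 = float(m.sum() * spacing.prod())
    # sphericity proxy: ideal-sphere area over the voxelized surface area
    area_mm2 = n_surface * float(np.mean(spacing) ** 2)
    sphericity = float(np.pi ** (1 / 3) * (6 * vol_mm3) ** (2 / 3) / area_mm2)

    coords = np.argwhere(surface) * spacing
    max_diam = float(pdist(coords).max()) if coords.shape[0] > 1 else 0.0

    feats = {
        "fo_mean": float(vals.mean()),
        "fo_sd": float(vals.std()),
        "fo_skewness": float(stats.skew(vals)) if vals.std() > 0 else 0.0,
        "fo_kurtosis": float(stats.kurtosis(vals)) if vals.std() > 0 else 0.0,
        "fo_median": float(np.median(vals)),
        "fo_p10": float(np.percentile(vals, 10)),
        "fo_p90": float(np.percentile(vals, 90)),
        "fo_entropy": entropy,
        "fo_energy": float(np.mean(vals**2)),
        "fo_range": float(np.ptp(vals)),
        "fo_iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
        "sh_volume_mm3": vol_mm3,
        "sh_surface_voxels": float(n_surface),
        "sh_sphericity": sphericity,
        "sh_max_diameter_mm": max_diam,
    }
    feats.update(_glcm_features(volume.data.astype(np.float64), m))
    return pd.Series(feats, index=FEATURE_NAMES)


def extract_feature_table(
    volumes: list[Volume], masks: list[LesionMask], ids: list[str]
) -> pd.DataFrame:
    """Radiomic feature table for the glioma subjects of a cohort."""
    rows = {sid: extract_features(v, m) for sid, v, m in zip(ids, volumes, masks)}
    table = pd.DataFrame(rows).T
    table.attrs["provenance"] = {c: "radiomic" for c in table.columns}
    return table


def _mwu_pvalues(table: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    y = np.asarray(labels)
    pvals = {}
    for col in table.columns:
        x0 = table[col].to_numpy()[y == 0]
        x1 = table[col].to_numpy()[y == 1]
        if np.ptp(table[col].to_numpy()) == 0:
            pvals[col] = 1.0
        else:
            pvals[col] = float(
                stats.mannwhitneyu(x1, x0, alternative="two-sided").pvalue
            )
    return pd.Series(pvals)


def mwu_filter(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Keep features with raw two-sided Mann-Whitney p < alpha.

    No multiplicity correction is applied at this stage; the filter is a
    deliberately permissive first pass ahead of the redundancy and LASSO
    steps.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 members each")
    pvals = _mwu_pvalues(table, y)
    return [c for c in table.columns if pvals[c] < alpha]


def correlation_prune(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    threshold: float = 0.9,
) -> list[str]:
    """Collapse clusters of features with |Spearman rho| > threshold (strict).

    Features are nodes; edges join pairs with |rho| strictly above the
    threshold. Within each connected component exactly one representative is
    kept: the feature with the smallest Mann-Whitney p against the labels
    (ties broken lexicographically); without labels, the lexicographically
    first name.
    """
    if table.shape[1] == 0:
        return []
    keep_cols = []
    for c in table.columns:
        if np.ptp(table[c].to_numpy()) == 0:
            warnings.warn(f"dropping constant feature '{c}' before correlation pruning")
        else:
            keep_cols.append(c)
    sub = table[keep_cols]
    if sub.shape[1] == 0:
        return []
    rho = sub.corr(method="spearman").to_numpy()
    g = nx.Graph()
    g.add_nodes_from(keep_cols)
    for i in range(len(keep_cols)):
        for j in range(i + 1, len(keep_cols)):
            if abs(rho[i, j]) > threshold:
                g.add_edge(keep_cols[i], keep_cols[j])
    pvals = (
        _mwu_pvalues(sub, np.asarray(labels))
        if labels is not None
        else pd.Series(0.0, index=keep_cols)
    )
    retained = []
    for comp in nx.connected_components(g):
        retained.append(min(comp, key=lambda c: (pvals[c], c)))
    return sorted(retained, key=list(table.columns).index)


def iterative_redundancy_reduction(
    table: pd.DataFrame,
    retained: list[str] | None = None,
    threshold: float = 0.8,
) -> list[str]:
    """Greedy redundancy reduction after correlation pruning.

    While any pair among the remaining features has |Spearman rho| above
    ``threshold``, drop the feature with the highest mean absolute
    correlation to the rest (ties broken lexicographically). Idempotent and
    deterministic.
    """
    cols = list(retained) if retained is not None else list(table.columns)
    while len(cols) > 1:
        rho = np.abs(table[cols].corr(method="spearman").to_numpy())
        np.fill_diagonal(rho, 0.0)
        if rho.max() <= threshold:
            break
        mean_rho = rho.mean(axis=1)
        worst = max(
            range(len(cols)), key=lambda i: (mean_rho[i], cols[i])
        )
        cols.pop(worst)
    return cols


@dataclass
class RadiomicSignature:
    """LASSO-selected features with standardized-scale coefficients."""

    features: list[str]
    coefficients: dict[str, float]
    intercept: float
    lam: float
    #: per-feature standardization parameters frozen at selection time
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    lam: float | None = None,
) -> RadiomicSignature:
    """L1-penalized logistic regression with lambda by CV minimum deviance.

    Features are standardized internally (zero mean, unit SD). The penalty
    is chosen on a log-spaced path to minimize the mean cross-validated
    deviance (the minimum-criteria rule, not the 1-SE rule). ``lam`` forces
    a fixed penalty instead of cross-validating.
    """
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    if table.shape[0] < folds and lam is None:
        raise ValueError(f"need >= {folds} subjects for {folds}-fold CV")
    means = table.mean()
    sds = table.std(ddof=0).replace(0.0, 1.0)
    x = ((table - means) / sds).to_numpy()
    n = x.shape[0]

    if lam is not None:
        # sklearn's C is the inverse of the total penalty strength
        clf = LogisticRegression(
            penalty="l1", C=1.0 / (lam * n), solver="liblinear",
            max_iter=2000, random_state=seed,
        ).fit(x, y)
        best_lam = lam
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        clf = LogisticRegressionCV(
            penalty="l1",
            solver="liblinear",
            Cs=np.logspace(-3, 2, 30),
            cv=cv,
            scoring="neg_log_loss",
            max_iter=2000,
            refit=True,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(x, y)
        best_lam = 1.0 / (float(clf.C_[0]) * n)

    coefs = clf.coef_[0]
    nonzero = [c for c, w in zip(table.columns, coefs) if w != 0.0]
    return RadiomicSignature(
        features=nonzero,
        coefficients={c: float(w) for c, w in zip(table.columns, coefs) if w != 0.0},
        intercept=float(clf.intercept_[0]),
        lam=float(best_lam),
        means={c: float(means[c]) for c in nonzero},
        sds={c: float(sds[c]) for c in nonzero},
    )


def radiomic_score(
    features: pd.Series | pd.DataFrame, signature: RadiomicSignature
) -> float | np.ndarray:
    """intercept + sum of coefficient x standardized feature value."""
    names = features.columns if isinstance(features, pd.DataFrame) else features.index
    missing = [f for f in signature.features if f not in names]
    if missing:
        raise ValueError(f"missing signature features: {missing}")
    score = signature.intercept
    if isinstance(features, pd.DataFrame):
        score = np.full(len(features), signature.intercept, dtype=float)
    for f in signature.features:
        z = (features[f] - signature.means[f]) / signature.sds[f]
        score = score + signature.coefficients[f] * (
            z.to_numpy() if hasattr(z, "to_numpy") else z
        )
    return score


def select_clinical(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    categorical: tuple[str, ...] = ("sex", "grade"),
) -> pd.DataFrame:
    """Association screen of clinical candidates against epileptic status.

    Continuous candidates use the Mann-Whitney test, categorical ones the
    chi-square test of independence. Returns every candidate with its
    p-value and a ``retained`` flag (p < alpha).
    """
    y = np.asarray(labels)
    rows = []
    for col in table.columns:
        v = table[col]
        if col in categorical or v.dtype == object:
            ct = pd.crosstab(v, y)
            if ct.shape[0] < 2:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
        else:
            arr = v.to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                p = 1.0
            else:
                p = float(
                    stats.mannwhitneyu(arr[y == 1], arr[y == 0], alternative="two-sided").pvalue
                )
        rows.append({"variable": col, "p": p, "retained": p < alpha})
    return pd.DataFrame(rows)


def run_selection_chain(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    rho_threshold: float = 0.9,
    redundancy_threshold: float = 0.8,
    folds: int = 10,
    seed: int = 0,
) -> tuple[RadiomicSignature, dict]:
    """The full radiomic selection chain; returns the signature and a trace."""
    kept = mwu_filter(table, labels, alpha=alpha)
    trace = {"after_mwu": list(kept)}
    kept = correlation_prune(table[kept], labels, threshold=rho_threshold) if kept else []
    trace["after_correlation_prune"] = list(kept)
    kept = iterative_redundancy_reduction(table, kept, threshold=redundancy_threshold)
    trace["after_redundancy_reduction"] = list(kept)
    if not kept:
        sig = RadiomicSignature([], {}, 0.0, np.inf)
    else:
        sig = lasso_select(table[kept], labels, folds=folds, seed=seed)
    trace["signature"] = list(sig.features)
    return sig, trace
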