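"""Bias-corrected brain age and the Brain Age Index (BAI).

Raw brain-age predictions regress toward the mean of the training
distribution (younger subjects over-, older subjects under-estimated). The
correction removes this linear trend, fitted on a designated healthy
cohort, and adds that cohort's mean absolute error as a fixed offset:

    corrected = predicted + [Omega - (alpha * Omega + beta)] + MAE

where Omega is chronological age and (alpha, beta) are the slope and
intercept of the ordinary-least-squares fit of predicted on chronological
age. The BAI then normalizes the corrected deviation by scale:

    BAI = (corrected - Omega) / (corrected + Omega)

confining the index to (-1, 1) and making brain-age deviations comparable
across subjects of different ages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BiasCorrection",
    "fit_bias_correction",
    "corrected_age",
    "brain_age_index",
    "predictions_table",
    "mann_whitney_u",
    "spearman_rho",
    "compare_groups",
]


@dataclass
class BiasCorrection:
    """Linear bias-correction fit: slope, intercept, MAE and its provenance."""

    alpha: float
    beta: float
    mae_term: float
    fit_cohort_id: str = "healthy-train"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        if self.mae_term < 0:
            raise ValueError("mae_term must be >= 0")


def fit_bias_correction(
    predicted: np.ndarray,
    chronological: np.ndarray,
    fit_cohort_id: str = "healthy-train",
) -> BiasCorrection:
    """OLS of predicted on chronological age; MAE frozen from the fit cohort."""
    p = np.asarray(predicted, dtype=float)
    omega = np.asarray(chronological, dtype=float)
    if p.size < 3 or p.shape != omega.shape:
        raise ValueError("need >= 3 paired predictions")
    if np.ptp(omega) == 0:
        raise ValueError("chronological ages are constant; slope is undefined")
    alpha, beta = np.polyfit(omega, p, deg=1)
    mae = float(np.mean(np.abs(p - omega)))
    return BiasCorrection(float(alpha), float(beta), mae, fit_cohort_id)


def corrected_age(
    predicted: float | np.ndarray,
    omega: float | np.ndarray,
    correction: BiasCorrection,
    include_mae_term: bool = True,
) -> float | np.ndarray:
    """corrected = predicted + [Omega - (alpha*Omega + beta)] + MAE.

    ``include_mae_term=False`` drops the constant MAE offset (the plain
    regression-to-the-mean correction); the default follows the formula as
    printed, with the MAE offset preserving sensitivity to organic lesions.
    """
    omega_arr = np.asarray(omega, dtype=float)
    if np.any(omega_arr <= 0):
        raise ValueError("chronological age must be positive")
    mae = correction.mae_term if include_mae_term else 0.0
    out = (
        np.asarray(predicted, dtype=float)
        + (omega_arr - (correction.alpha * omega_arr + correction.beta))
        + mae
    )
    return float(out) if np.isscalar(predicted) else out


def brain_age_index(
    corrected: float | np.ndarray, omega: float | np.ndarray
) -> float | np.ndarray:
    """BAI = (corrected - Omega)/(corrected + Omega), in (-1, 1)."""
    c = np.asarray(corrected, dtype=float)
    o = np.asarray(omega, dtype=float)
    denom = c + o
    if np.any(denom <= 0):
        raise ValueError("degenerate corrected age: corrected + Omega must be > 0")
    out = (c - o) / denom
    return float(out) if np.isscalar(corrected) else out


def predictions_table(
    ids: list[str],
    predicted: np.ndarray,
    omega: np.ndarray,
    correction: BiasCorrection,
    include_mae_term: bool = True,
) -> pd.DataFrame:
    """Per-subject table: id, chronological age, predicted, corrected, BAI."""
    corr = corrected_age(predicted, omega, correction, include_mae_term)
    return pd.DataFrame(
        {
            "id": ids,
            "age": np.asarray(omega, dtype=float),
            "predicted": np.asarray(predicted, dtype=float),
            "corrected": corr,
            "bai": brain_age_index(corr, omega),
        }
    )


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (U = #{x_i > y_j} + half-ties) and its p-value.

    The p-value is exact (full enumeration of label assignments) when
    n_x + n_y <= 12 and the pooled sample is tie-free; otherwise the normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _mwu_exact_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force two-sided exact p: enumerate all label assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    mu = nx * y.size / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n), nx):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


GROUP_LABELS = ("control", "GRE", "non-GRE")


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    correction: str = "bonferroni",
    group_order: tuple[str, ...] = GROUP_LABELS,
) -> dict:
    """Descriptives, normality tests and pairwise Mann-Whitney comparisons.

    Returns a report with per-group n / mean / SD, Kolmogorov-Smirnov and
    Shapiro-Wilk normality p-values, and all pairwise Mann-Whitney tests
    with raw and multiplicity-adjusted p-values (Bonferroni or
    Benjamini-Hochberg).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    present = [g for g in group_order if (labels == g).sum() > 0]
    unknown = set(np.unique(labels)) - set(group_order)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    if len(present) < 2 or any((labels == g).sum() < 2 for g in present):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")

    groups = {}
    for g in present:
        v = values[labels == g]
        z = (v - v.mean()) / v.std(ddof=1) if v.std(ddof=1) > 0 else v - v.mean()
        groups[g] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "ks_p": float(stats.kstest(z, "norm").pvalue),
            "shapiro_p": float(stats.shapiro(v).pvalue) if v.size >= 3 else np.nan,
        }

    pairs = list(itertools.combinations(present, 2))
    raw_p, stats_u = [], []
    for a, b in pairs:
        u, p = mann_whitney_u(values[labels == a], values[labels == b])
        raw_p.append(p)
        stats_u.append(u)
    method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
    adj = multipletests(raw_p, method=method)[1] if pairs else np.array([])
    comparisons = [
        {"groups": f"{a} vs {b}", "U": u, "p_raw": p, "p_adjusted": float(q)}
        for (a, b), u, p, q in zip(pairs, stats_u, raw_p, adj)
    ]
    return {"groups": groups, "comparisons": comparisons, "correction": correction}
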