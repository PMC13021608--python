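"""Radiomic extraction and the feature-selection chain."""

import numpy as np
import pandas as pd
import pytest

from lesionbai.features import (
    FEATURE_NAMES,
    correlation_prune,
    extract_features,
    iterative_redundancy_reduction,
    lasso_select,
    mwu_filter,
    radiomic_score,
    run_selection_chain,
    select_clinical,
)
from lesionbai.imaging import LesionMask, Volume
from lesionbai.phantom import generate_feature_table


def _lesion_volume(intensity=None, side=4, spacing=2.0, seed=0):
    data = np.zeros((12, 12, 12))
    mask = np.zeros((12, 12, 12))
    sl = slice(4, 4 + side)
    mask[sl, sl, sl] = 1
    if intensity is None:
        rng = np.random.default_rng(seed)
        data[sl, sl, sl] = rng.normal(1.0, 0.3, size=(side, side, side))
    else:
        data[sl, sl, sl] = intensity
    sp = (spacing,) * 3
    return Volume(data, spacing=sp), LesionMask(mask, spacing=sp)


class TestExtractFeatures:
    def test_names_and_completeness(self):
        v, m = _lesion_volume()
        feats = extract_features(v, m)
        assert list(feats.index) == FEATURE_NAMES
        assert feats.notna().all()

    def test_constant_lesion_degenerate_texture(self):
        v, m = _lesion_volume(intensity=2.5)
        feats = extract_features(v, m)
        assert feats["fo_sd"] == 0.0
        assert feats["fo_entropy"] == 0.0
        assert feats["tx_glcm_energy"] == pytest.approx(1.0)
        assert feats["tx_glcm_contrast"] == 0.0

    def test_single_voxel_volume_is_eight_mm3(self):
        data = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8))
        mask[4, 4, 4] = 1
        data[4, 4, 4] = 1.0
        feats = extract_features(
            Volume(data, spacing=(2, 2, 2)), LesionMask(mask, spacing=(2, 2, 2))
        )
        assert feats["sh_volume_mm3"] == pytest.approx(8.0)

    def test_intensity_shift_invariance(self):
        v, m = _lesion_volume(seed=3)
        f1 = extract_features(v, m)
        shifted = Volume(
            np.where(m.data > 0, v.data + 5.0, v.data), spacing=v.spacing
        )
        f2 = extract_features(shifted, m)
        assert f2["fo_mean"] == pytest.approx(f1["fo_mean"] + 5.0)
        for name in ["fo_sd", "fo_entropy", "tx_glcm_contrast",
                     "tx_glcm_energy", "tx_glcm_homogeneity", "fo_iqr"]:
            assert f2[name] == pytest.approx(f1[name], abs=1e-9)

    def test_empty_mask_rejected(self):
        v, _ = _lesion_volume()
        with pytest.raises(ValueError, match="empty"):
            extract_features(v, LesionMask(np.zeros(v.shape), spacing=v.spacing))


class TestMwuFilter:
    def test_large_shift_retained_and_alpha_zero_empty(self):
        table, y = generate_feature_table(100, 1, 5, 0, effect_size=2.0, seed=1)
        assert "inf1" in mwu_filter(table, y)
        assert mwu_filter(table, y, alpha=0.0) == []

    def test_single_class_rejected(self):
        table, _ = generate_feature_table(10, 1, 1, 0, seed=0)
        with pytest.raises(ValueError):
            mwu_filter(table, np.zeros(10, dtype=int))


class TestCorrelationPrune:
    def test_exact_duplicate_collapsed(self):
        rng = np.random.default_rng(0)
        f1 = rng.normal(size=50)
        table = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": rng.normal(size=50)})
        assert len(correlation_prune(table)) == 2

    def test_rho_exactly_at_threshold_keeps_both(self):
        # Spearman rho of one adjacent rank swap at n=5 is exactly
        # 1 - 6*2/(5*24) = 0.9: the strict inequality must keep both
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 4.0, 5.0])
        from scipy.stats import spearmanr

        assert spearmanr(x, y).statistic == pytest.approx(0.9)
        table = pd.DataFrame({"a": x, "b": y})
        assert correlation_prune(table, threshold=0.9) == ["a", "b"]

    def test_clique_of_near_duplicates_keeps_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        table = pd.DataFrame(
            {f"g{i}": base + rng.normal(0, 0.05, 200) for i in range(4)}
        )
        assert len(correlation_prune(table)) == 1

    def test_representative_has_smallest_filter_p(self):
        table, y = generate_feature_table(200, 1, 0, 1, effect_size=1.0, seed=5)
        kept = correlation_prune(table, y)
        assert len(kept) == 1  # inf1 and its duplicate collapse to one


class TestRedundancyReduction:
    def test_fixed_point_below_threshold(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        assert iterative_redundancy_reduction(table) == list("abcd")

    def test_drops_hub_of_a_correlation_chain(self):
        # f2 correlates ~0.85 with both f1 and f3, which share only ~0.5:
        # f2 has the highest mean |rho| and must be dropped, then the
        # remaining pair is below the threshold and survives
        rng = np.random.default_rng(3)
        n = 2000
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        f1 = z1
        f3 = 0.5 * z1 + np.sqrt(1 - 0.25) * z2
        f2 = (f1 + f3) / np.linalg.norm([1, 1])
        table = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
        rho = table.corr(method="spearman")
        assert rho.loc["f1", "f2"] > 0.8 and rho.loc["f2", "f3"] > 0.8
        assert rho.loc["f1", "f3"] < 0.8
        assert iterative_redundancy_reduction(table) == ["f1", "f3"]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=300)
        table = pd.DataFrame(
            {
                "a": base,
                "b": base + rng.normal(0, 0.3, 300),
                "c": rng.normal(size=300),
            }
        )
        once = iterative_redundancy_reduction(table)
        twice = iterative_redundancy_reduction(table, once)
        assert once == twice


class TestLasso:
    def test_forced_large_lambda_empty_signature(self):
        table, y = generate_feature_table(100, 3, 10, 0, effect_size=1.0, seed=0)
        sig = lasso_select(table, y, lam=1e6)
        assert sig.features == []

    def test_deterministic_under_seed(self):
        table, y = generate_feature_table(120, 2, 10, 0, effect_size=1.0, seed=1)
        s1 = lasso_select(table, y, seed=5)
        s2 = lasso_select(table, y, seed=5)
        assert s1.features == s2.features
        assert s1.coefficients == s2.coefficients

    def test_single_class_rejected(self):
        table, _ = generate_feature_table(20, 1, 1, 0, seed=0)
        with pytest.raises(ValueError):
            lasso_select(table, np.ones(20, dtype=int))


class TestRadiomicScore:
    def test_worked_example(self):
        from lesionbai.features import RadiomicSignature

        sig = RadiomicSignature(
            features=["a", "b"],
            coefficients={"a": 0.5, "b": -0.2},
            intercept=0.0,
            lam=0.1,
            means={"a": 0.0, "b": 0.0},
            sds={"a": 1.0, "b": 1.0},
        )
        vec = pd.Series({"a": 2.0, "b": 5.0})
        assert radiomic_score(vec, sig) == pytest.approx(0.0)

    def test_empty_signature_is_intercept(self):
        from lesionbai.features import RadiomicSignature

        sig = RadiomicSignature([], {}, intercept=1.5, lam=1.0)
        assert radiomic_score(pd.Series({"x": 3.0}), sig) == 1.5

    def test_missing_feature_named(self):
        from lesionbai.features import RadiomicSignature

        sig = RadiomicSignature(["zeta"], {"zeta": 1.0}, 0.0, 0.1,
                                means={"zeta": 0}, sds={"zeta": 1})
        with pytest.raises(ValueError, match="zeta"):
            radiomic_score(pd.Series({"x": 1.0}), sig)


class TestSelectClinical:
    def test_balanced_categorical_not_retained(self):
        y = np.array([0, 1] * 20)
        # grade split identically across both classes: no association
        table = pd.DataFrame({"grade": ["high", "high", "low", "low"] * 10})
        rep = select_clinical(table, y)
        assert not rep.loc[rep["variable"] == "grade", "retained"].item()

    def test_shifted_continuous_retained_and_alpha_one_keeps_all(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 40 + [1] * 40)
        table = pd.DataFrame(
            {"bai": np.concatenate([rng.normal(0, 0.02, 40), rng.normal(0.1, 0.02, 40)]),
             "noise": rng.normal(size=80)}
        )
        rep = select_clinical(table, y)
        assert rep.loc[rep["variable"] == "bai", "retained"].item()
        rep_all = select_clinical(table, y, alpha=1.0)
        assert rep_all["retained"].all()


class TestChainProperties:
    def test_row_permutation_invariance(self):
        table, y = generate_feature_table(120, 2, 10, 1, effect_size=1.0, seed=2)
        sig1, tr1 = run_selection_chain(table, y, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        sig2, tr2 = run_selection_chain(table.iloc[perm], y[perm], seed=0)
        assert tr1["after_redundancy_reduction"] == tr2["after_redundancy_reduction"]
        assert set(sig1.features) == set(sig2.features)
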