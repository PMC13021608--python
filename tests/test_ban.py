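"""Brain Age Network components: splitting, weighting, pooling, training."""

import numpy as np
import pandas as pd
import pytest

from lesionbai import _nn
from lesionbai.ban import (
    BanConfig,
    apply_lesion_exclusion,
    build_network,
    compute_bin_weights,
    evaluate_mae,
    predict_age,
    roi_align_pool,
    split_dataset,
    train,
)
from lesionbai.imaging import GeometryError, LesionMask, Volume


def _subjects(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"id": range(n), "age_bin": (rng.uniform(30, 80, n) // 10).astype(int).astype(str)}
    )


class TestSplitDataset:
    def test_exact_global_sizes_n1000(self):
        tr, va, te = split_dataset(_subjects(1000), stratify_on=["age_bin"], seed=0)
        assert (len(tr), len(va), len(te)) == (700, 100, 200)

    def test_largest_remainder_n10(self):
        tr, va, te = split_dataset(_subjects(10), seed=0)
        assert (len(tr), len(va), len(te)) == (7, 1, 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_disjoint_and_exhaustive(self, seed):
        subj = _subjects(137, seed=seed)
        tr, va, te = split_dataset(subj, stratify_on=["age_bin"], seed=seed)
        union = np.concatenate([tr, va, te])
        assert len(np.unique(union)) == len(union) == 137

    def test_per_stratum_proportions_within_one(self):
        subj = _subjects(400, seed=5)
        tr, va, te = split_dataset(subj, stratify_on=["age_bin"], seed=5)
        for key, grp in subj.groupby("age_bin"):
            idx = set(grp.index)
            for split, frac in zip((tr, va, te), (0.7, 0.1, 0.2)):
                got = len(idx & set(split.tolist()))
                assert abs(got - frac * len(idx)) <= 1.0

    def test_deterministic(self):
        a = split_dataset(_subjects(50), seed=9)
        b = split_dataset(_subjects(50), seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestBinWeights:
    def test_inverse_frequency_worked_example(self):
        ages = np.array([5.0] * 10 + [15.0] * 40)
        w = compute_bin_weights(ages, (0, 10, 20))
        np.testing.assert_allclose(w[:10], 2.5)
        np.testing.assert_allclose(w[10:], 0.625)

    def test_uniform_bins_give_unit_weights(self):
        ages = np.array([5.0, 15.0, 25.0, 6.0, 16.0, 26.0])
        np.testing.assert_allclose(compute_bin_weights(ages, (0, 10, 20, 30)), 1.0)

    def test_per_bin_total_weight_equal(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 90, 200)
        edges = (20, 40, 60, 90)
        w = compute_bin_weights(ages, edges)
        which = np.searchsorted(np.array(edges), ages, side="right") - 1
        totals = [w[which == b].sum() for b in np.unique(which)]
        np.testing.assert_allclose(totals, totals[0])

    def test_age_outside_bins_rejected(self):
        with pytest.raises(ValueError):
            compute_bin_weights(np.array([150.0]), (0, 100))


class TestLesionExclusion:
    def test_contract(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(8, 8, 8))
        v = Volume(data)
        empty = LesionMask(np.zeros((8, 8, 8)))
        np.testing.assert_array_equal(apply_lesion_exclusion(v, empty).data, data)

        mask = LesionMask(rng.random((8, 8, 8)) > 0.7)
        v2 = Volume(data + mask.data * 99.0)  # differ only inside the mask
        out1 = apply_lesion_exclusion(v, mask)
        out2 = apply_lesion_exclusion(v2, mask)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert np.all(out1.data[mask.data == 1] == 0)

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryError):
            apply_lesion_exclusion(
                Volume(np.zeros((4, 4, 4))), LesionMask(np.zeros((4, 4, 5)))
            )


class TestRoiAlign:
    def test_constant_map_pools_to_constant(self):
        fmap = np.full((3, 8, 8, 8), 5.0)
        out = roi_align_pool(fmap, ((0.3, 7.1), (1.0, 6.0), (2.2, 7.9)), (2, 2, 2))
        np.testing.assert_allclose(out, 5.0)
        assert out.shape == (3, 2, 2, 2)

    def test_identity_on_integer_subgrid(self):
        rng = np.random.default_rng(1)
        fmap = rng.normal(size=(1, 6, 6, 6))
        # box spanning voxel centres [1.5, 4.5) -> 3 cells of size 1, sample
        # at each cell centre (=voxel centre) with 1 sample per cell
        out = roi_align_pool(
            fmap, ((1.5, 4.5), (1.5, 4.5), (1.5, 4.5)), (3, 3, 3), samples_per_axis=1
        )
        np.testing.assert_allclose(out[0], fmap[0, 2:5, 2:5, 2:5], atol=1e-12)

    def test_linear_ramp_matches_cell_centres(self):
        d = 10
        ramp = np.broadcast_to(
            np.arange(d, dtype=float)[:, None, None], (d, d, d)
        ).copy()[None]
        box = ((1.2, 7.8), (2.0, 8.0), (2.0, 8.0))
        grid = (4, 2, 2)
        out = roi_align_pool(ramp, box, grid)
        h = (7.8 - 1.2) / 4
        centres = 1.2 + (np.arange(4) + 0.5) * h
        for c, val in zip(centres, out[0, :, 0, 0]):
            assert val == pytest.approx(c, abs=1e-5)

    def test_output_shape_independent_of_box(self):
        fmap = np.random.default_rng(0).normal(size=(2, 16, 16, 16))
        for span in [(0.0, 16.0), (3.0, 4.0), (7.7, 8.0)]:
            out = roi_align_pool(fmap, (span, span, span), (2, 2, 2))
            assert out.shape == (2, 2, 2, 2)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roi_align_pool(np.zeros((1, 4, 4, 4)), ((2.0, 2.0), (0, 4), (0, 4)), (2, 2, 2))


class TestNetwork:
    def test_forward_returns_finite_scalar_per_sample(self):
        cfg = BanConfig(conv_channels=(2, 4), blocks_per_stage=(1, 1), seed=0)
        model = build_network(cfg)
        x = np.random.default_rng(0).normal(size=(3, 1, 16, 16, 16))
        boxes = [((0.0, 16.0),) * 3] * 3
        pred = model.forward(x, boxes)
        assert pred.shape == (3,) and np.all(np.isfinite(pred))

    def test_parameter_count_is_function_of_config(self):
        cfg = BanConfig(conv_channels=(4, 8), blocks_per_stage=(1, 2), seed=0)
        assert build_network(cfg).parameter_count() == build_network(cfg).parameter_count()

    def test_zeroed_residual_branch_reduces_to_shortcut(self):
        unit = _nn.ResidualUnit(3, 3, stride=1, rng=np.random.default_rng(0))
        for p in unit.conv2.parameters():
            p.value[...] = 0.0
        x = np.abs(np.random.default_rng(1).normal(size=(1, 3, 6, 6, 6)))
        np.testing.assert_allclose(unit.forward(x), x, atol=1e-12)

    def test_too_small_input_rejected_with_minimum(self):
        cfg = BanConfig(conv_channels=(2, 2, 2, 2), blocks_per_stage=(1,) * 4, seed=0)
        model = build_network(cfg)
        with pytest.raises(ValueError, match=">= 8"):
            model.forward(np.zeros((1, 1, 4, 4, 4)), [((0, 4),) * 3])


class TestTraining:
    def test_early_stop_at_patience_bound(self, small_cohort):
        # zero learning rate freezes the weights, so the validation MAE
        # never improves after the first epoch and training must stop after
        # exactly early_stop_patience further epochs
        co = small_cohort
        controls = np.flatnonzero((co.subjects["grade"] == "none").to_numpy())
        cfg = BanConfig(
            conv_channels=(2,), blocks_per_stage=(1,), learning_rate=0.0,
            early_stop_patience=4, plateau_patience=2, max_epochs=50,
            batch_size=8, seed=0,
        )
        model = build_network(cfg)
        trained = train(
            model, co.volumes, co.masks, co.subjects["age"].to_numpy(),
            (controls[:6], controls[6:8]), cfg,
        )
        assert len(trained.history) == 1 + cfg.early_stop_patience

    def test_plateau_scheduler_two_triggers(self):
        from lesionbai.ban import PlateauScheduler

        sched = PlateauScheduler(0.001, factor=0.5, patience=5)
        sched.step(1.0)  # first epoch sets the best
        lrs = [sched.step(1.0) for _ in range(10)]  # flat loss forever
        assert lrs[4] == pytest.approx(0.0005)  # first trigger after 5 stale
        assert lrs[9] == pytest.approx(0.00025)  # second trigger after 5 more
        # an improving loss never triggers
        sched2 = PlateauScheduler(0.001, patience=5)
        for loss in np.linspace(1.0, 0.1, 20):
            assert sched2.step(loss) == 0.001

    def test_prediction_determinism_and_lesion_invariance(
        self, small_cohort, tiny_trained_ban
    ):
        co = small_cohort
        gli = next(
            i for i, m in enumerate(co.masks) if not m.is_empty()
        )
        v, m = co.volumes[gli], co.masks[gli]
        p1 = predict_age(tiny_trained_ban, v, m)
        p2 = predict_age(tiny_trained_ban, v, m)
        assert p1 == p2
        rng = np.random.default_rng(0)
        perturbed = v.data.copy()
        perturbed[m.data == 1] = rng.normal(size=int(m.data.sum())) * 50
        v2 = Volume(perturbed, spacing=v.spacing)
        assert predict_age(tiny_trained_ban, v2, m) == p1

    def test_geometry_mismatch_rejected(self, tiny_trained_ban):
        v = Volume(np.random.default_rng(0).normal(size=(16, 16, 16)))
        with pytest.raises(GeometryError):
            predict_age(tiny_trained_ban, v, None)

    def test_fully_masked_volume_raises_empty_roi(self, small_cohort, tiny_trained_ban):
        co = small_cohort
        v = co.volumes[0]
        full = LesionMask(np.ones(v.shape), spacing=v.spacing)
        with pytest.raises(ValueError, match="empty ROI|constant"):
            predict_age(tiny_trained_ban, v, full)


class TestEvaluateMae:
    def test_worked_cases(self):
        assert evaluate_mae([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)
        mae, _ = evaluate_mae([1.0, -3.0], [0.0, 0.0])
        assert mae == pytest.approx(2.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=1000), rng.normal(size=1000)
        mae, sd = evaluate_mae(p, t)
        err = np.abs(p - t)
        assert mae == pytest.approx(err.mean(), abs=1e-12)
        assert sd == pytest.approx(err.std(), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_mae([], [])
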