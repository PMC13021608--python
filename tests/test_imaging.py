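"""NIfTI round-trips, normalization, resampling, and mask-QC statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionbai.imaging import (
    GeometryError,
    LesionMask,
    Volume,
    VolumeFormatError,
    dice_coefficient,
    icc_2_1,
    normalize_intensity,
    read_volume,
    resample_isotropic,
    write_volume,
)


@pytest.fixture()
def volume():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(10, 12, 14)).astype(np.float32)
    data[0] = 0  # background slab
    return Volume(data, spacing=(2.0, 2.0, 2.0))


class TestNiftiIO:
    def test_roundtrip_bit_exact(self, volume, tmp_path):
        path = tmp_path / "v.nii.gz"
        write_volume(volume, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, volume.data)
        assert back.spacing == pytest.approx((2.0, 2.0, 2.0))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_malformed_file(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"this is not a nifti header")
        with pytest.raises(VolumeFormatError):
            read_volume(bad)

    def test_4d_input_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3), dtype=np.float32), np.eye(4))
        nib.save(img, str(tmp_path / "f4.nii.gz"))
        with pytest.raises(VolumeFormatError, match="expected 3D volume"):
            read_volume(tmp_path / "f4.nii.gz")


class TestNormalize:
    def test_zero_mean_unit_sd_outside_exclusion(self, volume):
        mask = LesionMask(np.zeros(volume.shape), spacing=volume.spacing)
        mask.data[5:7, 5:7, 5:7] = 1
        out = normalize_intensity(volume, mask)
        include = (volume.data != 0) & (mask.data == 0)
        assert out.data[include].mean() == pytest.approx(0.0, abs=1e-6)
        assert out.data[include].std() == pytest.approx(1.0, abs=1e-6)
        assert np.all(out.data[mask.data == 1] == 0)
        assert np.all(out.data[volume.data == 0] == 0)

    def test_affine_invariance(self, volume):
        out1 = normalize_intensity(volume)
        shifted = Volume(
            np.where(volume.data != 0, 3.0 * volume.data + 7.0, 0.0),
            spacing=volume.spacing,
        )
        out2 = normalize_intensity(shifted)
        # float32 input limits the achievable agreement
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-5)

    def test_constant_region_rejected(self):
        v = Volume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="constant|variance"):
            normalize_intensity(v)


class TestResample:
    def test_constant_stays_constant(self):
        v = Volume(np.full((6, 6, 6), 7.0), spacing=(2, 2, 2))
        out = resample_isotropic(v, 1.0)
        np.testing.assert_allclose(out.data, 7.0)

    def test_identity_at_same_spacing(self):
        rng = np.random.default_rng(1)
        v = Volume(rng.normal(size=(5, 6, 7)), spacing=(2, 2, 2))
        out = resample_isotropic(v, 2.0)
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_linear_ramp_matches_analytic_interpolant(self):
        # f(x) = x along axis 0, sampled at half the spacing: the trilinear
        # interpolant of a linear function is the function itself
        shape = (9, 4, 4)
        ramp = np.broadcast_to(
            np.arange(shape[0], dtype=float)[:, None, None], shape
        ).copy()
        v = Volume(ramp, spacing=(2, 2, 2))
        out = resample_isotropic(v, 1.0)
        expect = np.arange(out.shape[0]) * 0.5  # voxel i at physical i*1mm = index i/2
        np.testing.assert_allclose(out.data[:, 0, 0], expect, atol=1e-5)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(Volume(np.zeros((3, 3, 3))), 0.0)


class TestDice:
    def _mask(self, arr):
        return LesionMask(np.asarray(arr))

    def test_worked_values(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[:2, :2, :2] = 1  # 8 voxels
        b[1:3, :2, :2] = 1  # 8 voxels, overlap 4
        assert dice_coefficient(self._mask(a), self._mask(b)) == pytest.approx(0.5)
        assert dice_coefficient(self._mask(a), self._mask(a)) == 1.0
        disjoint = np.zeros((4, 4, 4))
        disjoint[3, 3, 3] = 1
        assert dice_coefficient(self._mask(a), self._mask(disjoint)) == 0.0
        empty = np.zeros((4, 4, 4))
        assert dice_coefficient(self._mask(empty), self._mask(empty)) == 1.0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            dice_coefficient(
                LesionMask(np.zeros((4, 4, 4))), LesionMask(np.zeros((5, 4, 4)))
            )

    @given(st.integers(0, 2**15 - 1), st.integers(0, 2**15 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = self._mask(np.array([bits_a >> i & 1 for i in range(15)]).reshape(1, 3, 5))
        b = self._mask(np.array([bits_b >> i & 1 for i in range(15)]).reshape(1, 3, 5))
        d = dice_coefficient(a, b)
        assert d == dice_coefficient(b, a)
        assert 0.0 <= d <= 1.0


def _icc_anova_oracle(x):
    """Independent mean-squares computation of ICC(2,1) (Shrout & Fleiss)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_2_1(x).icc == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(200, 2))
        assert abs(icc_2_1(x).icc) < 0.15

    def test_worked_matrix_matches_anova_oracle(self):
        x = np.array([[9.0, 2.0], [8.0, 4.0], [7.0, 6.0], [10.0, 7.0]])
        res = icc_2_1(x)
        assert res.icc == pytest.approx(_icc_anova_oracle(x), abs=1e-12)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        subj = rng.normal(size=30)
        x = np.column_stack([subj + rng.normal(0, 0.5, 30) for _ in range(3)])
        df = pd.DataFrame(x, columns=["r1", "r2", "r3"]).reset_index(names="subject")
        long = df.melt(id_vars="subject", var_name="rater", value_name="score")
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref_row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]  # absolute agreement, single
        res = icc_2_1(x)
        assert res.icc == pytest.approx(ref_row["ICC"], abs=1e-6)
        ci = list(ref_row[ref.columns[-1]])  # rounded to 2 decimals by pingouin
        assert res.ci_low == pytest.approx(ci[0], abs=0.01)
        assert res.ci_high == pytest.approx(ci[1], abs=0.01)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((2, 2)))
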