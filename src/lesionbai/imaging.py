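"""Volume containers, NIfTI-1 I/O, preprocessing and mask-QC statistics.

The package operates on T1-weighted volumes that are assumed to be already
co-registered to a common template space; this module supplies the light
plumbing around that assumption: reading/writing NIfTI-1, grayscale
(z-score) normalization outside the lesion, isotropic resampling, and the
two inter-rater agreement statistics used for lesion-mask quality control
(Dice similarity coefficient and ICC(2,1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Volume",
    "LesionMask",
    "GeometryError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_intensity",
    "resample_isotropic",
    "dice_coefficient",
    "icc_2_1",
]


class VolumeFormatError(ValueError):
    """Raised for files that are not a readable 3D NIfTI-1 volume."""


class GeometryError(ValueError):
    """Raised when two images that must share a grid do not."""


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and world origin (mm).

    Orientation is carried through the affine; voxel indices are 0-based and
    world coordinates follow the NIfTI convention (affine maps voxel index to
    mm).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {self.data.ndim}D array"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_geometry(self, other: "Volume | LesionMask", atol: float = 1e-5) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LesionMask:
    """Binary mask (tumor core + peritumoral edema) aligned to a Volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected 3D mask, got {arr.ndim}D array")
        # anything not strictly binary is thresholded at 0.5
        self.data = (arr.astype(np.float64) > 0.5).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    same_geometry = Volume.same_geometry


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header/format errors
        raise VolumeFormatError(f"not a readable NIfTI file: {path} ({exc})") from exc
    arr = np.squeeze(arr) if arr.ndim == 4 and arr.shape[-1] == 1 else arr
    if arr.ndim != 3:
        raise VolumeFormatError(
            f"expected 3D volume, got {arr.ndim}D data in {path}"
        )
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return arr, tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 volume (.nii or .nii.gz)."""
    arr, spacing, origin = _load_nifti(path)
    return Volume(arr, spacing=spacing, origin=origin)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1; data is stored as float32."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> LesionMask:
    """Read a binary lesion mask; values are thresholded at 0.5."""
    arr, spacing, origin = _load_nifti(path)
    return LesionMask(arr, spacing=spacing, origin=origin)


def write_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask_affine(mask))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def mask_affine(mask: LesionMask) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(mask.spacing)
    aff[:3, 3] = mask.origin
    return aff


def normalize_intensity(
    volume: Volume, mask_exclude: LesionMask | None = None
) -> Volume:
    """Z-score the volume over included voxels; excluded voxels become 0.

    Included voxels are the non-background (non-zero) voxels outside
    ``mask_exclude``. The z-score is affine invariant, so the result does not
    depend on the scanner's arbitrary intensity scale.
    """
    data = volume.data.astype(np.float64)
    include = data != 0
    if mask_exclude is not None:
        if not volume.same_geometry(mask_exclude):
            raise GeometryError("mask geometry does not match volume")
        include &= mask_exclude.data == 0
    vals = data[include]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("cannot normalize: included region is constant")
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot normalize: zero variance in included region")
    out = np.zeros_like(data)
    out[include] = (vals - vals.mean()) / sd
    return Volume(out, spacing=volume.spacing, origin=volume.origin)


def resample_isotropic(volume: Volume, target_spacing: float) -> Volume:
    """Trilinearly resample onto an isotropic grid of ``target_spacing`` mm.

    The output grid covers the physical extent of the input; samples beyond
    the last input voxel centre are clamped to the edge value.
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    sp = np.array(volume.spacing)
    shape = np.array(volume.shape)
    extent = (shape - 1) * sp  # physical span between first/last voxel centres
    out_shape = np.maximum(np.ceil(extent / target_spacing).astype(int) + 1, 1)
    grids = np.meshgrid(
        *[np.arange(n) * target_spacing / s for n, s in zip(out_shape, sp)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        volume.data.astype(np.float64), np.stack(grids), order=1, mode="nearest"
    )
    return Volume(
        out.reshape(tuple(out_shape)),
        spacing=(target_spacing,) * 3,
        origin=volume.origin,
    )


def dice_coefficient(a: LesionMask, b: LesionMask) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1.0)."""
    if not a.same_geometry(b):
        raise GeometryError("masks do not share a grid")
    sa, sb = int(a.data.sum()), int(b.data.sum())
    if sa + sb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (sa + sb)


@dataclass
class IccResult:
    """ICC(2,1) estimate with its 95% confidence interval and mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    ms: dict = field(default_factory=dict)


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> IccResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    ``ratings`` is a subjects x raters matrix of scalars (for mask QC:
    per-subject lesion volumes from each rater). The estimate follows the
    standard two-way ANOVA mean-squares decomposition; the confidence
    interval uses the F-distribution bounds of McGraw & Wong.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 3 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing values")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # McGraw & Wong (1996) CI for ICC(2,1), Satterthwaite df for the
    # compound mean square in the denominator.
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_star1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_star1 * mse) / (
            f_star1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_star2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star2 * msr
        )
    else:  # degenerate: perfect agreement
        lower = upper = icc
    return IccResult(
        icc=float(icc),
        ci_low=float(lower),
        ci_high=float(upper),
        ms={"msr": float(msr), "msc": float(msc), "mse": float(mse)},
    )
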