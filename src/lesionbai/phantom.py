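"""Synthetic cohorts for the lesion-aware brain-age framework.

Real cohorts for this problem (multicenter glioma T1 scans plus healthy
controls) cannot be redistributed, so this module generates 3D phantoms that
carry the statistical structure the framework assumes:

* each volume encodes an *effective age* through two deterministic,
  linearly age-dependent structural signals — the radius of a central
  ventricle-like dark region and a cortical-band intensity decline — plus
  additive Gaussian voxel noise;
* glioma phantoms receive an ellipsoidal lesion core with a surrounding
  edema shell, written both into the image intensities and into a binary
  mask;
* glioma phantoms additionally carry a group-level "accelerated aging"
  perturbation outside the lesion (their effective age exceeds their
  chronological age), larger on average in non-epileptic than epileptic
  subjects — mirroring the observed direction in which epilepsy attenuates
  apparent brain-age acceleration;
* epilepsy labels are drawn from a known logistic model in tumor grade and
  the subject's aging perturbation, so label-feature associations are known
  exactly for recovery tests.

The generative parameters per subject (true aging shift, lesion volume,
ventricle radius) are recorded in a truth table that is meant for tests
only — model-fitting code never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import LesionMask, Volume, write_mask, write_volume

__all__ = [
    "PhantomConfig",
    "PhantomCohort",
    "generate_cohort",
    "generate_feature_table",
    "save_cohort",
]


@dataclass
class PhantomConfig:
    """Generative settings for a synthetic cohort.

    Defaults emulate the study conditions: ages spanning adulthood, a glioma
    fraction near one third, an aging perturbation of ~15 effective years in
    non-epileptic and ~8 in epileptic glioma subjects, and an epilepsy
    prevalence among glioma subjects of roughly 30%.
    """

    n_subjects: int = 100
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: float = 2.0
    age_range: tuple[float, float] = (30.0, 85.0)
    #: ventricle-radius growth in voxels per effective year
    age_signal_strength: float = 0.05
    noise_sd: float = 0.05
    glioma_fraction: float = 0.35
    lesion_radius_range: tuple[float, float] = (2.5, 5.0)
    edema_voxels: int = 2
    aging_shift_nonepileptic: float = 15.0
    aging_shift_epileptic: float = 8.0
    shift_jitter_sd: float = 3.0
    grade_high_fraction: float = 0.7
    #: logistic coefficients (intercept, high-grade, aging shift) of the label model
    epilepsy_logit_coefs: tuple[float, float, float] = (1.0, -0.5, -0.12)
    #: lesions may cover at most this fraction of the ventricle-like region
    max_ventricle_overlap: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be positive, got {self.volume_shape}")
        if not 0.0 <= self.glioma_fraction <= 1.0:
            raise ValueError("glioma_fraction must be in [0, 1]")
        if self.aging_shift_epileptic > self.aging_shift_nonepileptic:
            raise ValueError(
                "epileptic aging shift must not exceed the non-epileptic shift"
            )
        if self.noise_sd < 0 or self.age_signal_strength < 0:
            raise ValueError("noise_sd and age_signal_strength must be >= 0")


@dataclass
class PhantomCohort:
    """A generated cohort: volumes, masks, subject table, and the truth table."""

    volumes: list[Volume]
    masks: list[LesionMask]
    subjects: pd.DataFrame
    truth: pd.DataFrame
    config: PhantomConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.volumes)


def _ventricle_radius(effective_age: float, cfg: PhantomConfig) -> float:
    return 1.5 + cfg.age_signal_strength * effective_age


def _render_volume(
    effective_age: float, cfg: PhantomConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render one brain phantom; returns (image, brain support, ventricle radius)."""
    shape = np.array(cfg.volume_shape)
    center = (shape - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    r_brain = 0.45 * shape.min()
    brain = np.clip(r_brain - d, 0.0, 1.0)  # anti-aliased outer boundary

    img = brain.copy()
    # ventricle-like central dark region, radius linear in effective age
    r_v = _ventricle_radius(effective_age, cfg)
    ventricle = np.clip(r_v - d, 0.0, 1.0)
    img *= 1.0 - 0.85 * ventricle
    # cortical band: outer 3-voxel shell dims linearly with effective age
    band = (d > r_brain - 3.0) & (d <= r_brain)
    img[band] *= max(0.0, 1.0 - 0.003 * effective_age)
    return img, brain > 0, r_v


def _place_lesion(
    img: np.ndarray,
    brain: np.ndarray,
    d_center: np.ndarray,
    r_v: float,
    cfg: PhantomConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Write an ellipsoidal core + edema shell into img; return the binary mask."""
    shape = np.array(img.shape)
    center = (shape - 1) / 2.0
    r_brain = 0.45 * shape.min()
    ventricle_region = d_center <= r_v
    n_vent = max(int(ventricle_region.sum()), 1)

    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    for _ in range(100):
        radii = rng.uniform(*cfg.lesion_radius_range, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(0.5, 0.7) * r_brain
        c = center + direction * dist
        core = (
            ((zz - c[0]) / radii[0]) ** 2
            + ((yy - c[1]) / radii[1]) ** 2
            + ((xx - c[2]) / radii[2]) ** 2
        ) <= 1.0
        core &= brain
        if not core.any():
            continue
        shell = ndimage.binary_dilation(core, iterations=cfg.edema_voxels) & brain
        mask = shell
        overlap = (mask & ventricle_region).sum() / n_vent
        if overlap <= cfg.max_ventricle_overlap:
            break
    else:
        raise RuntimeError("could not place a lesion satisfying the overlap bound")

    edema = shell & ~core
    img[core] = 1.8
    img[edema] = 1.4
    return mask.astype(np.uint8)


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate a deterministic cohort from ``config`` (bit-identical per seed)."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    ages = rng.uniform(*cfg.age_range, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    sites = np.array([("A", "B", "C")[i % 3] for i in range(n)])

    n_glioma = int(round(cfg.glioma_fraction * n))
    glioma = np.zeros(n, dtype=bool)
    glioma[rng.permutation(n)[:n_glioma]] = True

    grades = np.where(
        glioma, np.where(rng.random(n) < cfg.grade_high_fraction, "high", "low"), "none"
    )

    # Aging perturbation and epilepsy label. The pre-attenuation shift is drawn
    # around the non-epileptic mean; the label follows the configured logistic
    # model in (grade, shift); epileptic subjects' realized shift is then
    # attenuated by the configured group difference, so the two config fields
    # are the generative group means and the planted ordering
    # control < epileptic < non-epileptic holds by construction.
    c0, c_grade, c_shift = cfg.epilepsy_logit_coefs
    shifts = np.zeros(n)
    epilepsy = np.full(n, "n/a", dtype=object)
    raw = np.maximum(
        rng.normal(cfg.aging_shift_nonepileptic, cfg.shift_jitter_sd, size=n), 0.0
    )
    u = rng.random(n)
    for i in range(n):
        if not glioma[i]:
            continue
        logit = c0 + c_grade * (grades[i] == "high") + c_shift * raw[i]
        is_epi = u[i] < 1.0 / (1.0 + np.exp(-logit))
        epilepsy[i] = "yes" if is_epi else "no"
        shifts[i] = raw[i]
        if is_epi:
            shifts[i] = max(
                raw[i] - (cfg.aging_shift_nonepileptic - cfg.aging_shift_epileptic),
                0.0,
            )

    volumes: list[Volume] = []
    masks: list[LesionMask] = []
    truth_rows = []
    sp = (cfg.spacing_mm,) * 3
    shape = np.array(cfg.volume_shape)
    center = (shape - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d_center = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )

    for i in range(n):
        eff_age = ages[i] + shifts[i]
        img, brain, r_v = _render_volume(eff_age, cfg, rng)
        if glioma[i]:
            mask_arr = _place_lesion(img, brain, d_center, r_v, cfg, rng)
        else:
            mask_arr = np.zeros(cfg.volume_shape, dtype=np.uint8)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape) * brain
        volumes.append(Volume(img.astype(np.float32), spacing=sp))
        masks.append(LesionMask(mask_arr, spacing=sp))
        truth_rows.append(
            {
                "id": f"sub-{i:04d}",
                "true_aging_shift": shifts[i],
                "lesion_voxels": int(mask_arr.sum()),
                "ventricle_radius": r_v,
            }
        )

    subjects = pd.DataFrame(
        {
            "id": [f"sub-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "site": sites,
            "grade": grades,
            "epilepsy": epilepsy,
        }
    )
    return PhantomCohort(
        volumes=volumes,
        masks=masks,
        subjects=subjects,
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


def generate_feature_table(
    n_subjects: int,
    n_informative: int,
    n_noise: int,
    n_duplicates: int,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table with planted class structure for the selection chain.

    Informative features are standard normal shifted by ``effect_size``
    between classes; duplicates are near-copies (|rho| > 0.95) of informative
    parents (cycling over them); noise features are independent of the
    labels. Classes are balanced (floor(n/2) positives), label order
    shuffled by the seed.
    """
    if n_subjects < 4:
        raise ValueError(f"need at least 4 subjects, got {n_subjects}")
    if min(n_informative, n_noise, n_duplicates) < 0 or effect_size < 0:
        raise ValueError("counts and effect_size must be >= 0")
    if n_duplicates > 0 and n_informative == 0:
        raise ValueError("duplicates need at least one informative parent")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_subjects, dtype=int)
    y[: n_subjects // 2] = 1
    rng.shuffle(y)

    cols: dict[str, np.ndarray] = {}
    for j in range(n_informative):
        cols[f"inf{j + 1}"] = rng.normal(size=n_subjects) + effect_size * y
    for j in range(n_noise):
        cols[f"noise{j + 1}"] = rng.normal(size=n_subjects)
    for j in range(n_duplicates):
        parent = f"inf{(j % n_informative) + 1}"
        cols[f"dup{j + 1}_{parent}"] = cols[parent] + rng.normal(
            scale=0.15, size=n_subjects
        )
    table = pd.DataFrame(cols, index=[f"sub-{i:04d}" for i in range(n_subjects)])
    table.attrs["provenance"] = {c: "radiomic" for c in table.columns}
    return table, y


def save_cohort(cohort: PhantomCohort, out_dir: str | Path) -> None:
    """Write a cohort as NIfTI volumes/masks plus subjects.csv and truth.csv."""
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for sid, vol, mask in zip(cohort.subjects["id"], cohort.volumes, cohort.masks):
        write_volume(vol, out / "volumes" / f"{sid}.nii.gz")
        write_mask(mask, out / "masks" / f"{sid}.nii.gz")
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    if cohort.config is not None:
        cfg = asdict(cohort.config)
        pd.Series(
            {k: str(v) for k, v in cfg.items()}, name="value"
        ).to_csv(out / "config.csv")
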