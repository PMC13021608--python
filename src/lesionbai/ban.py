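"""The Brain Age Network (BAN): lesion-aware 3D brain-age regression.

The network is a compact VGG-style 3D convolutional regressor enhanced with
residual units (short-circuit connections); all spatial downsampling uses
stride-2 convolutions rather than pooling. Tumor and peritumoral edema are
excluded from the input with binary masks before feature extraction, and
the irregular non-lesion region is pooled with ROI-Align (trilinear
interpolation at sub-voxel sample points) so the regression head always
sees a fixed-size input regardless of lesion size.

Training follows the protocol: Adam (lr 1e-3, weight decay 1e-6, beta1
0.9, beta2 0.999), bin-weighted L1 loss with weights inversely
proportional to age-bin frequency, learning-rate halving after five
plateau epochs of the training loss, and early stopping after 20 epochs
without validation-MAE improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .imaging import GeometryError, LesionMask, Volume, normalize_intensity

__all__ = [
    "BanConfig",
    "TrainedBan",
    "split_dataset",
    "compute_bin_weights",
    "apply_lesion_exclusion",
    "roi_align_pool",
    "build_network",
    "train",
    "predict_age",
    "evaluate_mae",
    "cross_validate",
]

roi_align_pool = _nn.roi_align_pool


@dataclass
class BanConfig:
    """Architecture and optimization settings for the Brain Age Network."""

    conv_channels: tuple[int, ...] = (16, 32, 64)
    blocks_per_stage: tuple[int, ...] = (1, 1, 1)
    roi_output_grid: tuple[int, int, int] = (2, 2, 2)
    samples_per_cell_axis: int = 2
    age_bin_edges: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    early_stop_patience: int = 20
    max_epochs: int = 100
    batch_size: int = 16
    seed: int = 0

    def validate(self) -> None:
        if len(self.conv_channels) != len(self.blocks_per_stage):
            raise ValueError("conv_channels and blocks_per_stage must align")
        if min(self.roi_output_grid) < 1:
            raise ValueError("roi_output_grid must be strictly positive")
        if not all(np.diff(self.age_bin_edges) > 0):
            raise ValueError("age bin edges must be strictly increasing")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be positive")


class BanModel:
    """Residual 3D conv regressor with ROI-Align pooling and a linear head."""

    def __init__(self, config: BanConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.conv_channels
        self.stem = _nn.Conv3d(1, chans[0], 3, stride=1, rng=rng)
        self.stem_relu = _nn.ReLU()
        self.stages: list[_nn.ResidualUnit] = []
        c_prev = chans[0]
        for s, (c, n_blocks) in enumerate(zip(chans, config.blocks_per_stage)):
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                self.stages.append(_nn.ResidualUnit(c_prev, c, stride=stride, rng=rng))
                c_prev = c
        self.roi = _nn.RoiAlign(config.roi_output_grid, config.samples_per_cell_axis)
        n_pooled = c_prev * int(np.prod(config.roi_output_grid))
        self.head = _nn.Linear(n_pooled, 1, rng=rng)
        self.total_stride = 2 ** (len(chans) - 1)

    def parameters(self) -> list[_nn.Parameter]:
        ps = self.stem.parameters() + self.head.parameters()
        for st in self.stages:
            ps += st.parameters()
        return ps

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def min_input_dim(self) -> int:
        return self.total_stride

    def check_input(self, shape: tuple[int, int, int]) -> None:
        if min(shape) < self.min_input_dim():
            raise ValueError(
                f"input shape {shape} too small; every axis must be >= "
                f"{self.min_input_dim()} for {len(self.config.conv_channels)} stages"
            )

    def _boxes_to_feature_space(self, boxes: list) -> list:
        s = self.total_stride
        return [tuple((lo / s, hi / s) for lo, hi in box) for box in boxes]

    def forward(self, x: np.ndarray, boxes: list) -> np.ndarray:
        """x: (N, 1, D, H, W); boxes: per-sample ROI in input voxel coords."""
        self.check_input(x.shape[2:])
        h = self.stem_relu.forward(self.stem.forward(x))
        for st in self.stages:
            h = st.forward(h)
        pooled = self.roi.forward(h, self._boxes_to_feature_space(boxes))
        self._pooled_shape = pooled.shape
        flat = pooled.reshape(pooled.shape[0], -1)
        return self.head.forward(flat)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dflat = self.head.backward(dpred[:, None])
        dpooled = dflat.reshape(self._pooled_shape)
        dh = self.roi.backward(dpooled)
        for st in reversed(self.stages):
            dh = st.backward(dh)
        self.stem.backward(self.stem_relu.backward(dh))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.value[...] = s


def build_network(config: BanConfig) -> BanModel:
    """Construct an untrained Brain Age Network from its config."""
    return BanModel(config)


@dataclass
class TrainedBan:
    """A trained network plus everything needed to reproduce its predictions."""

    model: BanModel
    config: BanConfig
    input_shape: tuple[int, int, int]
    history: pd.DataFrame
    #: affine target transform (center, scale): the network regresses
    #: (age - center)/scale; predictions are mapped back to years
    target_center: float = 0.0
    target_scale: float = 1.0
    bias_fit_inputs: pd.DataFrame | None = None
    split_indices: dict = field(default_factory=dict)


class PlateauScheduler:
    """Halve the learning rate when the tracked loss stops improving.

    After ``patience`` consecutive epochs without improvement the rate is
    multiplied by ``factor`` and the counter resets.
    """

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 5, eps: float = 1e-8):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.eps = eps
        self._best = np.inf
        self._count = 0

    def step(self, loss: float) -> float:
        if loss < self._best - self.eps:
            self._best = loss
            self._count = 0
        else:
            self._count += 1
            if self._count >= self.patience:
                self.lr *= self.factor
                self._count = 0
        return self.lr


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    quotas = fractions * total
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for _ in range(total - counts.sum()):
        j = int(np.argmax(rem))
        counts[j] += 1
        rem[j] = -1
    return counts


def split_dataset(
    subjects: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    stratify_on: list[str] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test partition with exact global sizes.

    Global split sizes follow largest-remainder rounding of the fractions;
    within each stratum the allocation also follows largest-remainder, with
    leftover units steered toward the globally most under-filled split so
    per-stratum proportions stay within one subject of target while the
    global sizes come out exact. Strata smaller than 3 are collapsed into
    the preceding stratum with a warning. Returns positional indices.
    """
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(subjects)
    if n == 0:
        raise ValueError("empty subject table")
    if stratify_on:
        strata_keys = subjects[stratify_on].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        strata_keys = np.array(["all"] * n)

    order = sorted(pd.unique(strata_keys))
    groups = {k: np.flatnonzero(strata_keys == k) for k in order}
    merged: list[np.ndarray] = []
    for k in order:
        idx = groups[k]
        if len(idx) < 3 and merged:
            warnings.warn(f"stratum '{k}' has <3 subjects; merged into neighbor")
            merged[-1] = np.concatenate([merged[-1], idx])
        elif len(idx) < 3 and not merged:
            warnings.warn(f"stratum '{k}' has <3 subjects; merged into neighbor")
            merged.append(idx)  # nothing before it yet; absorb the next one
        else:
            if merged and len(merged[-1]) < 3:
                merged[-1] = np.concatenate([merged[-1], idx])
            else:
                merged.append(idx)
    rng = np.random.default_rng(seed)
    targets = _largest_remainder(n, fractions)

    # phase 1: largest-remainder within each stratum (within-1 of quota)
    quotas = [fractions * len(idx) for idx in merged]
    counts = [np.floor(q).astype(int) for q in quotas]
    for q, c, idx in zip(quotas, counts, merged):
        rem = q - c
        for _ in range(len(idx) - c.sum()):
            j = int(np.argmax(rem))
            c[j] += 1
            rem[j] = -1.0

    # phase 2: shift single subjects between splits, only where the move
    # keeps every stratum within one subject of its quota, until the global
    # totals equal the largest-remainder targets exactly
    assigned = np.sum(counts, axis=0)
    guard = 0
    while np.any(assigned > targets) and guard < 10 * n:
        guard += 1
        j = int(np.argmax(assigned - targets))  # overfull split
        k = int(np.argmin(assigned - targets))  # underfull split
        moved = False
        for q, c in zip(quotas, counts):
            if c[j] > np.floor(q[j]) and c[k] < np.ceil(q[k]):
                c[j] -= 1
                c[k] += 1
                assigned[j] -= 1
                assigned[k] += 1
                moved = True
                break
        if not moved:  # relax the within-1 constraint for this one move
            for q, c in zip(quotas, counts):
                if c[j] > 0:
                    c[j] -= 1
                    c[k] += 1
                    assigned[j] -= 1
                    assigned[k] += 1
                    break

    splits: list[list[int]] = [[], [], []]
    for idx, c in zip(merged, counts):
        idx = rng.permutation(idx)
        pos = 0
        for j in range(3):
            splits[j].extend(idx[pos : pos + c[j]].tolist())
            pos += c[j]
    return tuple(np.array(sorted(s), dtype=int) for s in splits)


def compute_bin_weights(
    ages: np.ndarray, bin_edges: tuple[float, ...]
) -> np.ndarray:
    """Loss weights inversely proportional to age-bin frequency, mean 1.

    Every subject in the same bin gets the same weight 1/count(bin),
    rescaled so the mean weight over subjects is exactly 1 — hence the
    total weight contributed by each occupied bin is equal.
    """
    ages = np.asarray(ages, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if ages.min() < edges[0] or ages.max() > edges[-1]:
        raise ValueError("every age must fall inside the bin range")
    which = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(which, minlength=len(edges) - 1)
    w = 1.0 / counts[which]
    return w / w.mean()


def apply_lesion_exclusion(volume: Volume, mask: LesionMask) -> Volume:
    """Zero-fill voxels under the lesion mask; everything else unchanged."""
    if not volume.same_geometry(mask):
        raise GeometryError("lesion mask geometry does not match volume")
    out = volume.data.copy()
    out[mask.data > 0] = 0
    return Volume(out, spacing=volume.spacing, origin=volume.origin)


def _foreground_box(data: np.ndarray) -> tuple:
    """Tight continuous bounding box of the non-zero region, in voxel coords."""
    nz = np.nonzero(data)
    if nz[0].size == 0:
        raise ValueError("empty ROI: no foreground voxels outside the lesion mask")
    return tuple((float(ax.min()), float(ax.max()) + 1.0) for ax in nz)


def prepare_input(volume: Volume, mask: LesionMask | None) -> tuple[np.ndarray, tuple]:
    """Normalize, exclude the lesion, and compute the non-lesion ROI box.

    This is the single preprocessing path used identically at training and
    inference time, which is what makes predictions exactly invariant to
    intensity changes inside the exclusion mask.
    """
    normed = normalize_intensity(volume, mask_exclude=mask)
    if mask is not None:
        normed = apply_lesion_exclusion(normed, mask)
    box = _foreground_box(normed.data)
    return normed.data.astype(np.float64)[None], box


def train(
    model: BanModel,
    volumes: list[Volume],
    masks: list[LesionMask | None],
    ages: np.ndarray,
    splits: tuple[np.ndarray, np.ndarray],
    config: BanConfig | None = None,
    weight_ages: np.ndarray | None = None,
) -> TrainedBan:
    """Fit the network with the bin-weighted L1 protocol.

    ``splits`` is (train_indices, val_indices). ``weight_ages`` optionally
    designates the cohort whose age distribution defines the bin weights
    (e.g. the glioma training subset); by default the training subset's own
    ages are used.
    """
    cfg = config or model.config
    train_idx, val_idx = (np.asarray(s, dtype=int) for s in splits)
    if train_idx.size == 0:
        raise ValueError("training split is empty")
    ages = np.asarray(ages, dtype=float)

    inputs: dict[int, tuple[np.ndarray, tuple]] = {}
    for i in np.concatenate([train_idx, val_idx]):
        inputs[int(i)] = prepare_input(volumes[i], masks[i])

    w_source = np.asarray(weight_ages, dtype=float) if weight_ages is not None else ages[train_idx]
    bin_w_lookup_ages = ages[train_idx]
    # weights per *training subject*, from the designated cohort's bin frequencies
    edges = np.asarray(cfg.age_bin_edges, dtype=float)
    which = np.clip(
        np.searchsorted(edges, bin_w_lookup_ages, side="right") - 1, 0, len(edges) - 2
    )
    src_which = np.clip(
        np.searchsorted(edges, w_source, side="right") - 1, 0, len(edges) - 2
    )
    counts = np.bincount(src_which, minlength=len(edges) - 1).astype(float)
    counts[counts == 0] = np.inf  # unoccupied bins carry no weight
    w_train = 1.0 / counts[which]
    if not np.all(np.isfinite(w_train)) or w_train.sum() == 0:
        w_train = np.ones_like(w_train)
    w_train = w_train / w_train.mean()
    weight_of = dict(zip(train_idx.tolist(), w_train))

    # regress the standardized age so the head works at unit scale
    t_center = float(ages[train_idx].mean())
    t_scale = float(ages[train_idx].std()) or 1.0
    targets_std = (ages - t_center) / t_scale

    opt = _nn.Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    best_val = np.inf
    best_state = model.get_state()
    scheduler = PlateauScheduler(
        opt.lr, factor=cfg.plateau_factor, patience=cfg.plateau_patience
    )
    stale_val = 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, perm.size, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            x = np.stack([inputs[int(i)][0] for i in batch])
            boxes = [inputs[int(i)][1] for i in batch]
            target = targets_std[batch]
            wts = np.array([weight_of[int(i)] for i in batch])
            opt.zero_grad()
            pred = model.forward(x, boxes)
            loss, dpred = _nn.weighted_l1_loss(pred, target, wts)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}, "
                    f"lr={opt.lr}, batch={batch.tolist()}"
                )
            model.backward(dpred)
            opt.step()
            epoch_loss += loss * t_scale  # report the loss in years
            n_batches += 1
        epoch_loss /= max(n_batches, 1)

        if val_idx.size:
            val_pred = _predict_prepared(model, inputs, val_idx) * t_scale + t_center
            val_mae = float(np.mean(np.abs(val_pred - ages[val_idx])))
        else:
            val_mae = np.nan
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_mae": val_mae, "lr": opt.lr}
        )

        # plateau scheduler on the training loss
        opt.lr = scheduler.step(epoch_loss)

        # early stopping on the validation MAE
        if val_idx.size:
            if val_mae < best_val - 1e-8:
                best_val = val_mae
                best_state = model.get_state()
                stale_val = 0
            else:
                stale_val += 1
                if stale_val >= cfg.early_stop_patience:
                    break
        else:
            best_state = model.get_state()

    model.set_state(best_state)
    return TrainedBan(
        model=model,
        config=cfg,
        input_shape=tuple(volumes[0].shape),
        history=pd.DataFrame(history),
        target_center=t_center,
        target_scale=t_scale,
        split_indices={"train": train_idx.tolist(), "val": val_idx.tolist()},
    )


def _predict_prepared(model: BanModel, inputs: dict, idx: np.ndarray) -> np.ndarray:
    preds = np.empty(idx.size)
    for j, i in enumerate(idx):
        x, box = inputs[int(i)]
        preds[j] = model.forward(x[None], [box])[0]
    return preds


def predict_age(
    trained: TrainedBan, volume: Volume, mask: LesionMask | None = None
) -> float:
    """Predict age for one subject; deterministic given the trained weights."""
    if tuple(volume.shape) != trained.input_shape:
        raise GeometryError(
            f"volume shape {volume.shape} differs from training shape "
            f"{trained.input_shape}"
        )
    x, box = prepare_input(volume, mask)
    raw = float(trained.model.forward(x[None], [box])[0])
    return raw * trained.target_scale + trained.target_center


def evaluate_mae(
    predictions: np.ndarray, truths: np.ndarray
) -> tuple[float, float]:
    """Mean and SD of absolute prediction errors, in years."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    err = np.abs(predictions - truths)
    return float(err.mean()), float(err.std())


def cross_validate(
    config: BanConfig,
    volumes: list[Volume],
    masks: list[LesionMask | None],
    ages: np.ndarray,
    train_idx: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """K-fold CV on the training subset (for hyperparameter selection)."""
    train_idx = np.asarray(train_idx, dtype=int)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train_idx)
    folds = np.array_split(perm, n_folds)
    rows = []
    for f, held in enumerate(folds):
        fit = np.concatenate([folds[j] for j in range(n_folds) if j != f])
        model = build_network(config)
        trained = train(model, volumes, masks, ages, (fit, held), config)
        preds = np.array([predict_age(trained, volumes[i], masks[i]) for i in held])
        mae, sd = evaluate_mae(preds, ages[held])
        rows.append({"fold": f, "val_mae": mae, "val_mae_sd": sd, "n_val": held.size})
    return pd.DataFrame(rows)
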