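"""End-to-end orchestration: simulate -> brain age -> BAI -> features -> fusion.

Each stage writes its artifacts into the run directory and appends an
entry (stage seed, input checksums, outputs, elapsed time) to a JSON run
manifest, so a completed run is reproducible from its manifest alone. All
stage seeds are derived deterministically from the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bai as bai_mod
from . import ban as ban_mod
from . import features as feat_mod
from . import fusion as fusion_mod
from .imaging import read_mask, read_volume
from .phantom import PhantomConfig, generate_cohort, save_cohort

log = logging.getLogger("lesionbai")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

ALL_STAGES = ("simulate", "ban", "bai", "features", "fusion")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; round-trips through YAML."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(n_subjects=120))
    ban: ban_mod.BanConfig = field(
        default_factory=lambda: ban_mod.BanConfig(
            conv_channels=(4, 8), blocks_per_stage=(1, 1), max_epochs=25
        )
    )
    n_search_draws: int = 8
    cv_folds: int = 5
    lasso_folds: int = 10
    test_fraction: float = 0.3
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, ALL_STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("phantom", {}).items()
        })
        ban_cfg = ban_mod.BanConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("ban", {}).items()
        })
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(phantom=phantom, ban=ban_cfg, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, default_flow_style=None))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in paths if p.is_file()}


def validate_inputs(cohort_dir: str | Path) -> pd.DataFrame:
    """Completeness and geometry checks on a cohort directory.

    Flags subjects with missing volume/mask files, volume-mask geometry
    mismatches, or incomplete records (glioma rows must carry age, grade
    and epilepsy status). Returns a table of flags; an empty table means
    the cohort passed.
    """
    root = Path(cohort_dir)
    if not root.exists():
        raise FileNotFoundError(f"cohort directory not found: {root}")
    subjects = pd.read_csv(root / "subjects.csv")
    flags = []
    for _, row in subjects.iterrows():
        sid = row["id"]
        vol_path = root / "volumes" / f"{sid}.nii.gz"
        mask_path = root / "masks" / f"{sid}.nii.gz"
        if not vol_path.exists():
            flags.append({"id": sid, "flag": "missing_volume", "detail": str(vol_path)})
            continue
        is_glioma = str(row.get("grade", "none")) != "none"
        if pd.isna(row.get("age")):
            flags.append({"id": sid, "flag": "missing_age", "detail": ""})
        if is_glioma:
            if pd.isna(row.get("epilepsy")) or str(row.get("epilepsy")) == "n/a":
                flags.append({"id": sid, "flag": "missing_epilepsy_status", "detail": ""})
            if not mask_path.exists():
                flags.append({"id": sid, "flag": "missing_mask", "detail": str(mask_path)})
                continue
        if mask_path.exists():
            vol = read_volume(vol_path)
            mask = read_mask(mask_path)
            if not vol.same_geometry(mask):
                flags.append(
                    {
                        "id": sid,
                        "flag": "geometry_mismatch",
                        "detail": f"{vol_path.name} vs {mask_path.name}",
                    }
                )
        if pd.isna(row.get("grade")):
            flags.append({"id": sid, "flag": "missing_grade", "detail": ""})
    return pd.DataFrame(flags, columns=["id", "flag", "detail"])


def _group_label(row: pd.Series) -> str:
    if row["grade"] == "none":
        return "control"
    return "GRE" if row["epilepsy"] == "yes" else "non-GRE"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    manifest["config"] = {
        "seed": config.seed,
        "stages": list(config.stages),
        "phantom": asdict(config.phantom),
        "ban": asdict(config.ban),
    }

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        seed = config.stage_seed(stage)
        log.info("stage=%s seed=%d starting", stage, seed)
        try:
            outputs = _STAGE_FNS[stage](config, out, seed, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 2),
            "outputs": _checksums([out / o for o in outputs]),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)
    return manifest


def _load_cohort_state(config: RunConfig, out: Path, state: dict) -> None:
    """Resume support: rebuild the in-memory cohort from stage outputs."""
    if "cohort" in state:
        return
    subjects = pd.read_csv(out / "subjects.csv")
    volumes = [read_volume(out / "volumes" / f"{s}.nii.gz") for s in subjects["id"]]
    masks = [read_mask(out / "masks" / f"{s}.nii.gz") for s in subjects["id"]]
    state["cohort"] = {"subjects": subjects, "volumes": volumes, "masks": masks}


def _stage_simulate(config: RunConfig, out: Path, seed: int, state: dict) -> list[str]:
    cfg = replace(config.phantom, seed=seed)
    cohort = generate_cohort(cfg)
    save_cohort(cohort, out)
    flags = validate_inputs(out)
    if not flags.empty:
        missing = flags[flags["flag"].str.startswith("missing")]
        if not missing.empty:
            raise ValueError(f"incomplete cohort: {missing.to_dict('records')}")
    state["cohort"] = {
        "subjects": cohort.subjects,
        "volumes": cohort.volumes,
        "masks": cohort.masks,
    }
    return ["subjects.csv", "truth.csv"]


def _stage_ban(config: RunConfig, out: Path, seed: int, state: dict) -> list[str]:
    _load_cohort_state(config, out, state)
    co = state["cohort"]
    subjects, volumes, masks = co["subjects"], co["volumes"], co["masks"]
    ages = subjects["age"].to_numpy()
    is_control = (subjects["grade"] == "none").to_numpy()
    controls = np.flatnonzero(is_control)

    # train on healthy subjects only (brain age = chronological age there),
    # stratifying the split on age decade
    ctrl = subjects.loc[controls].copy()
    ctrl["age_bin"] = (ctrl["age"] // 10).astype(int).astype(str)
    tr, va, te = ban_mod.split_dataset(ctrl, stratify_on=["age_bin"], seed=seed)
    train_idx, val_idx, test_idx = controls[tr], controls[va], controls[te]

    cfg = replace(config.ban, seed=seed)
    model = ban_mod.build_network(cfg)
    trained = ban_mod.train(
        model, volumes, masks, ages, (train_idx, val_idx), cfg
    )
    preds = np.array(
        [ban_mod.predict_age(trained, v, m) for v, m in zip(volumes, masks)]
    )
    pred_df = subjects[["id", "age"]].copy()
    pred_df["predicted"] = preds
    pred_df["cohort"] = np.where(is_control, "control", "glioma")
    pred_df["split"] = "apply"
    pred_df.loc[train_idx, "split"] = "train"
    pred_df.loc[val_idx, "split"] = "val"
    pred_df.loc[test_idx, "split"] = "test"
    pred_df.to_csv(out / "predictions.csv", index=False)
    trained.history.to_csv(out / "ban_history.csv", index=False)
    state["predictions"] = pred_df
    state["trained_ban"] = trained
    return ["predictions.csv", "ban_history.csv"]


def _stage_bai(config: RunConfig, out: Path, seed: int, state: dict) -> list[str]:
    if "predictions" not in state:
        state["predictions"] = pd.read_csv(out / "predictions.csv")
    _load_cohort_state(config, out, state)
    pred_df = state["predictions"]
    subjects = state["cohort"]["subjects"]

    fit = pred_df[pred_df["split"] == "train"]
    correction = bai_mod.fit_bias_correction(
        fit["predicted"].to_numpy(), fit["age"].to_numpy()
    )
    table = bai_mod.predictions_table(
        pred_df["id"].tolist(),
        pred_df["predicted"].to_numpy(),
        pred_df["age"].to_numpy(),
        correction,
    )
    labels = subjects.apply(_group_label, axis=1).to_numpy()
    table["group"] = labels
    table.to_csv(out / "bai.csv", index=False)
    report = bai_mod.compare_groups(table["bai"].to_numpy(), labels)
    report["bias_correction"] = {
        "alpha": correction.alpha,
        "beta": correction.beta,
        "mae_term": correction.mae_term,
    }
    (out / "bai_stats.json").write_text(json.dumps(report, indent=2))
    state["bai"] = table
    return ["bai.csv", "bai_stats.json"]


def _stage_features(config: RunConfig, out: Path, seed: int, state: dict) -> list[str]:
    _load_cohort_state(config, out, state)
    co = state["cohort"]
    subjects = co["subjects"]
    glioma = subjects[subjects["grade"] != "none"]
    idx = glioma.index.to_numpy()
    table = feat_mod.extract_feature_table(
        [co["volumes"][i] for i in idx],
        [co["masks"][i] for i in idx],
        glioma["id"].tolist(),
    )
    y = (glioma["epilepsy"] == "yes").to_numpy().astype(int)
    sig, trace = feat_mod.run_selection_chain(
        table, y, folds=min(config.lasso_folds, max(2, y.size // 4)), seed=seed
    )
    table.to_csv(out / "features.csv")
    (out / "signature.json").write_text(
        json.dumps(
            {
                "features": sig.features,
                "coefficients": sig.coefficients,
                "intercept": sig.intercept,
                "lambda": sig.lam,
                "trace": trace,
            },
            indent=2,
        )
    )
    state["features"] = table
    state["signature"] = sig
    state["selection_trace"] = trace
    return ["features.csv", "signature.json"]


def _stage_fusion(config: RunConfig, out: Path, seed: int, state: dict) -> list[str]:
    _load_cohort_state(config, out, state)
    if "features" not in state:
        state["features"] = pd.read_csv(out / "features.csv", index_col=0)
    if "bai" not in state:
        state["bai"] = pd.read_csv(out / "bai.csv")
    subjects = state["cohort"]["subjects"]
    glioma = subjects[subjects["grade"] != "none"].reset_index(drop=True)
    y = (glioma["epilepsy"] == "yes").to_numpy().astype(int)

    feats = state["features"].loc[glioma["id"]]
    trace = state.get("selection_trace", {})
    kept = trace.get("after_redundancy_reduction") or list(feats.columns)
    X_rad = feats[kept].to_numpy(dtype=float)

    bai_table = state["bai"].set_index("id").loc[glioma["id"]]
    X_cli = np.column_stack(
        [
            glioma["age"].to_numpy(dtype=float),
            (glioma["grade"] == "high").to_numpy(dtype=float),
            bai_table["bai"].to_numpy(dtype=float),
            (glioma["sex"] == "M").to_numpy(dtype=float),
        ]
    )

    rng = np.random.default_rng(seed)
    n = len(y)
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    if len(pos) < 4 or len(neg) < 4:
        raise ValueError(
            f"too few subjects per epilepsy class for fusion "
            f"(yes={len(pos)}, no={len(neg)}; need >= 4 each)"
        )
    n_test_pos = max(1, int(round(len(pos) * config.test_fraction)))
    n_test_neg = max(1, int(round(len(neg) * config.test_fraction)))
    test_idx = np.sort(np.concatenate([pos[:n_test_pos], neg[:n_test_neg]]))
    train_idx = np.sort(np.setdiff1d(np.arange(n), test_idx))

    space = fusion_mod.SearchSpace(n_draws=config.n_search_draws, seed=seed)
    folds = min(config.cv_folds, int(np.bincount(y[train_idx]).min()))
    folds = max(folds, 2)
    best_rad, _ = fusion_mod.random_search(X_rad[train_idx], y[train_idx], space, folds=folds, seed=seed)
    best_cli, _ = fusion_mod.random_search(X_cli[train_idx], y[train_idx], space, folds=folds, seed=seed)
    p_rad, fold_map = fusion_mod.oof_probabilities(best_rad, X_rad[train_idx], y[train_idx], folds=folds, seed=seed)
    p_cli, _ = fusion_mod.oof_probabilities(best_cli, X_cli[train_idx], y[train_idx], folds=folds, seed=seed, fold_map=fold_map)
    model = fusion_mod.fit_fusion(
        p_rad, p_cli, y[train_idx],
        radiomic_params=best_rad, clinical_params=best_cli,
        X_radiomic=X_rad[train_idx], X_clinical=X_cli[train_idx],
        fold_map=fold_map, seed=seed,
    )
    oof_fused = fusion_mod.stacked_probabilities(model, p_rad, p_cli)
    threshold = fusion_mod.youden_threshold(oof_fused, y[train_idx])
    p_test = model.predict_proba(X_rad[test_idx], X_cli[test_idx])
    metrics = {
        "train_oof": fusion_mod.evaluate_classifier(oof_fused, y[train_idx], threshold=threshold, seed=seed),
        "test": fusion_mod.evaluate_classifier(p_test, y[test_idx], threshold=threshold, seed=seed),
        "threshold_policy": "youden-on-train-oof",
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
    }
    (out / "fusion_metrics.json").write_text(json.dumps(metrics, indent=2))
    state["fusion_metrics"] = metrics
    return ["fusion_metrics.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "ban": _stage_ban,
    "bai": _stage_bai,
    "features": _stage_features,
    "fusion": _stage_fusion,
}
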