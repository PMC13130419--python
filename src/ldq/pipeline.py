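"""End-to-end orchestration: phantom cohort -> homogenise -> split ->
augment -> segment (U-Net and/or multi-atlas) -> fat fraction -> metrics
and statistics, with one global seed fanned out per stage.

Stage seeds derive from the run seed through a stable stage-name hash, so
each stage is independently reproducible. All emitted artifacts are plain
text (CSV/JSON); volumes are written only on request.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .eval_stats import bland_altman, mc_cv_plan, reference_table, segmentation_metrics
from .fat_fraction import measure_cohort
from .geometry import Geometry
from .multiatlas import MultiAtlasSegmenter
from .phantom import CohortSpec, PhantomSpec, generate_cohort
from .preprocess import homogenise
from .unet import UNetSegmenter
from .volumes import write_dixon, write_label_map

__all__ = ["RunConfig", "validate_config", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one via a stable hash."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run. JSON round-trippable."""

    out_dir: str = "ldq_run"
    seed: int = 0
    engine: str = "both"  # "unet" | "multiatlas" | "both"
    n_subjects: int = 24
    n_val: int = 8
    multiatlas_n: int = 10  # leave-one-out benchmark size
    grid: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    noise_sd: float = 0.02
    deformation_mm: float = 3.0
    downsample_factor: int = 1  # >1: generate finer in-plane, then homogenise
    augment: str = "none"  # "none" | "linear" | "full"
    unet: dict = field(default_factory=dict)  # UNetSegmenter overrides
    multiatlas: dict = field(default_factory=dict)  # MultiAtlasSegmenter overrides
    write_volumes: bool = False

    @classmethod
    def demo(cls, out_dir: str = "ldq_demo", seed: int = 0) -> "RunConfig":
        return cls(out_dir=out_dir, seed=seed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"config parse error at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("grid", "spacing_mm"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "pyramid" in payload.get("multiatlas", {}):
            payload["multiatlas"]["pyramid"] = tuple(payload["multiatlas"]["pyramid"])
        return cls(**payload)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems (empty iff the config is usable)."""
    problems: list[str] = []
    if config.engine not in ("unet", "multiatlas", "both"):
        problems.append(f"engine: must be unet|multiatlas|both, got {config.engine!r}")
    if config.n_subjects < 2:
        problems.append(f"n_subjects: must be >= 2, got {config.n_subjects}")
    if not 1 <= config.n_val < config.n_subjects:
        problems.append(f"n_val: must satisfy 1 <= n_val < n_subjects, got n_val={config.n_val}, n_subjects={config.n_subjects}")
    if config.multiatlas_n > config.n_subjects:
        problems.append(f"multiatlas_n: must be <= n_subjects, got {config.multiatlas_n}")
    if any(s <= 0 for s in config.spacing_mm):
        problems.append(f"spacing_mm: all components must be > 0, got {config.spacing_mm}")
    if any(g < 8 for g in config.grid):
        problems.append(f"grid: all components must be >= 8, got {config.grid}")
    if config.downsample_factor < 1:
        problems.append(f"downsample_factor: must be >= 1, got {config.downsample_factor}")
    if config.augment not in ("none", "linear", "full"):
        problems.append(f"augment: must be none|linear|full, got {config.augment!r}")
    if config.noise_sd < 0:
        problems.append(f"noise_sd: must be >= 0, got {config.noise_sd}")
    lr = config.unet.get("learning_rate")
    if lr is not None and lr <= 0:
        problems.append(f"unet.learning_rate: must be > 0, got {lr}")
    k = config.multiatlas.get("k")
    if k is not None and k < 1:
        problems.append(f"multiatlas.k: must be >= 1, got {k}")
    return problems


def _log_stage(report: dict, stage: str, t0: float) -> None:
    report.setdefault("stage_seconds", {})[stage] = round(time.time() - t0, 2)
    log.info(json.dumps({"stage": stage, "seconds": report["stage_seconds"][stage]}))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured pipeline; returns the run directory.

    Deterministic directory contents for a fixed config and seed
    (timestamps aside). Any stage failure raises with the stage name and,
    where applicable, the subject id.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    report: dict = {"engine": config.engine, "seed": config.seed}

    # --- cohort -----------------------------------------------------------
    t0 = time.time()
    f = config.downsample_factor
    gen_geom = Geometry(
        (config.grid[0] * f, config.grid[1] * f, config.grid[2]),
        (config.spacing_mm[0] / f, config.spacing_mm[1] / f, config.spacing_mm[2]),
    )
    cohort_spec = CohortSpec(
        n_subjects=config.n_subjects,
        phantom=PhantomSpec(geometry=gen_geom, noise_sd=config.noise_sd, deformation_mm=config.deformation_mm),
        seed=stage_seed(config.seed, "cohort"),
    )
    pairs, table = generate_cohort(cohort_spec)
    table.to_csv(out / "cohort.csv", index=False)
    _log_stage(report, "cohort", t0)

    # --- homogenise -------------------------------------------------------
    t0 = time.time()
    if f > 1:
        vols, labels, _ = homogenise(
            [v for v, _ in pairs], [m for _, m in pairs], factor=f, register=False
        )
        pairs = list(zip(vols, labels))
    _log_stage(report, "homogenise", t0)
    if config.write_volumes:
        for vol, lmap in pairs:
            write_dixon(vol, out / "volumes")
            write_label_map(lmap, out / "volumes" / f"{vol.subject_id}_labels.nii.gz")

    # --- split ------------------------------------------------------------
    ids = [v.subject_id for v, _ in pairs]
    rng = np.random.default_rng(stage_seed(config.seed, "split"))
    val_idx = sorted(rng.choice(len(pairs), size=config.n_val, replace=False).tolist())
    train_idx = [i for i in range(len(pairs)) if i not in val_idx]
    (out / "split.json").write_text(
        json.dumps({"train": [ids[i] for i in train_idx], "val": [ids[i] for i in val_idx]}, indent=1)
    )

    metrics_rows: list[dict] = []
    predictions: dict[str, list] = {}

    # --- U-Net ------------------------------------------------------------
    if config.engine in ("unet", "both"):
        t0 = time.time()
        from .augment import apply_linear, full_plan, linear_plan, synthesize_deformed

        train_pairs = [pairs[i] for i in train_idx]
        val_pairs = [pairs[i] for i in val_idx]
        train_ids = [ids[i] for i in train_idx]
        if config.augment != "none":
            plan = linear_plan(train_ids) if config.augment == "linear" else full_plan(train_ids)
            plan.assert_no_leakage([ids[i] for i in val_idx])
            (out / "augment_plan.json").write_text(json.dumps(plan.to_records(), indent=1))
            by_id = {ids[i]: pairs[i] for i in train_idx}
            for rec in plan.records:
                vol, lmap = by_id[rec.source]
                if rec.kind == "linear":
                    train_pairs.append(apply_linear(vol, lmap, rec.flip, rec.angle_deg))
                else:
                    train_pairs.append(synthesize_deformed((vol, lmap), by_id[rec.partner][0]))
        seg = UNetSegmenter(seed=stage_seed(config.seed, "unet"), **config.unet)
        try:
            seg.fit(
                [v for v, _ in train_pairs], [m for _, m in train_pairs],
                validation_data=([v for v, _ in val_pairs], [m for _, m in val_pairs]),
            )
        except Exception as exc:
            raise RuntimeError(f"stage unet failed: {exc}") from exc
        pd.DataFrame(seg.history_.as_dict()["train_loss"], columns=["train_loss"]).assign(
            val_loss=seg.history_.val_loss
        ).to_csv(out / "unet_history.csv", index_label="epoch")
        preds = seg.predict([v for v, _ in val_pairs])
        predictions["unet"] = list(zip(val_pairs, preds))
        for (vol, truth), pred in zip(val_pairs, preds):
            for m in segmentation_metrics(pred, truth, subject=vol.subject_id, method="unet"):
                metrics_rows.append(dataclasses.asdict(m))
        report["unet_best_epoch"] = seg.history_.best_epoch
        report["unet_n_params"] = int(seg.n_params_)
        _log_stage(report, "unet", t0)

    # --- multi-atlas ------------------------------------------------------
    if config.engine in ("multiatlas", "both"):
        t0 = time.time()
        sub = pairs[: config.multiatlas_n]
        seg = MultiAtlasSegmenter(**config.multiatlas)
        seg.fit([v for v, _ in sub], [m for _, m in sub])
        ma_preds = []
        for vol, truth in sub:  # leave-one-out via matching subject ids
            try:
                pred = seg.predict(vol)
            except Exception as exc:
                raise RuntimeError(f"stage multiatlas failed for subject {vol.subject_id!r}: {exc}") from exc
            ma_preds.append(((vol, truth), pred))
            for m in segmentation_metrics(pred, truth, subject=vol.subject_id, method="multiatlas"):
                metrics_rows.append(dataclasses.asdict(m))
        predictions["multiatlas"] = ma_preds
        _log_stage(report, "multiatlas", t0)

    # --- metrics + fat fraction ------------------------------------------
    t0 = time.time()
    metrics = pd.DataFrame(metrics_rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    if not metrics.empty:
        report["mean_dice"] = {
            method: round(float(g["dice"].mean()), 4) for method, g in metrics.groupby("method")
        }

    ff_truth = measure_cohort(pairs, covariates=table)
    ff_truth.to_csv(out / "ff_truth.csv", index=False)
    for method, items in predictions.items():
        pred_pairs = [(vol, pred) for (vol, _), pred in items]
        ff_pred = measure_cohort(pred_pairs, covariates=table)
        ff_pred.to_csv(out / f"ff_{method}.csv", index=False)
        if ff_pred.empty:
            continue
        merged = ff_pred.merge(
            ff_truth, on=["subject", "muscle", "side"], suffixes=("_pred", "_truth")
        )
        both = merged[merged["side"] == "LR"]
        if len(both) >= 3:
            agreement = bland_altman(both["mean_ff_pct_truth"], both["mean_ff_pct_pred"])
            report[f"ff_agreement_{method}"] = {
                "bias_pct": round(agreement.bias, 3),
                "loa_low_pct": round(agreement.loa_low, 3),
                "loa_high_pct": round(agreement.loa_high, 3),
                "r_squared": round(agreement.r_squared, 4),
            }
    ref = reference_table(ff_truth, strata="active" if "active" in ff_truth.columns else "none")
    ref.to_csv(out / "reference_table.csv", index=False)
    _log_stage(report, "evaluate", t0)

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return out
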