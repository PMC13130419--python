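"""Reproducible desk-scale benchmarks of the segmentation engines.

One function generates a phantom cohort under the default study
conditions and scores both engines on it: the U-Net on a held-out
validation split and the multi-atlas baseline in a leave-one-out scheme
on a subset of the same cohort. Returns plain numbers so callers (tests,
the acceptance script, notebooks) can assert or report them.
"""

from __future__ import annotations

import numpy as np

from .eval_stats import dice
from .multiatlas import AtlasLibrary, FusionConfig, segment_multiatlas
from .phantom import CohortSpec, PhantomSpec, generate_cohort
from .unet import UNetConfig, build_model, predict, train

__all__ = ["make_benchmark_cohort", "unet_benchmark", "multiatlas_benchmark", "segmentation_benchmark"]


def make_benchmark_cohort(n_subjects: int = 24, seed: int = 0):
    """Phantom cohort at the default 64 x 64 x 32 grid and study conditions."""
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    pairs, table = generate_cohort(spec, render_images=True)
    return pairs, table


def unet_benchmark(
    pairs,
    n_val: int = 8,
    seed: int = 0,
    config: UNetConfig | None = None,
) -> dict:
    """Train the desk U-Net on a random split and score validation Dice."""
    config = config or UNetConfig.desk()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pairs))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    train_pairs = [pairs[i] for i in train_idx]
    val_pairs = [pairs[i] for i in val_idx]
    model, n_params = build_model(config)
    model, history = train(model, train_pairs, val_pairs, config)
    per_subject = []
    for vol, truth in val_pairs:
        pred = predict(model, vol)
        per_subject.append([dice(pred, truth, c) for c in truth.codes])
    scores = np.asarray(per_subject)
    return {
        "mean_dice": float(scores.mean()),
        "per_structure_dice": scores.mean(axis=0).tolist(),
        "n_params": int(n_params),
        "epochs_run": len(history.train_loss),
        "best_epoch": history.best_epoch,
        "n_train": len(train_pairs),
        "n_val": len(val_pairs),
    }


def multiatlas_benchmark(pairs, n_subjects: int = 10, config: FusionConfig | None = None) -> dict:
    """Leave-one-out multi-atlas segmentation over a phantom subset."""
    config = config or FusionConfig()
    sub = pairs[:n_subjects]
    library = AtlasLibrary([v for v, _ in sub], [m for _, m in sub])
    per_subject = []
    for vol, truth in sub:
        pred = segment_multiatlas(vol, library, config)  # LOO via matching id
        per_subject.append([dice(pred, truth, c) for c in truth.codes])
    scores = np.asarray(per_subject)
    return {
        "mean_dice": float(scores.mean()),
        "per_structure_dice": scores.mean(axis=0).tolist(),
        "n_subjects": len(sub),
        "k": config.k,
    }


def segmentation_benchmark(
    seed: int = 0,
    n_subjects: int = 24,
    n_val: int = 8,
    multiatlas_n: int = 10,
    unet_config: UNetConfig | None = None,
    fusion_config: FusionConfig | None = None,
) -> dict:
    """Shared-cohort benchmark of both engines (the U-Net's validation
    split and the multi-atlas leave-one-out subset are drawn from one
    generated cohort)."""
    pairs, _ = make_benchmark_cohort(n_subjects, seed)
    unet = unet_benchmark(pairs, n_val=n_val, seed=seed, config=unet_config)
    matlas = multiatlas_benchmark(pairs, n_subjects=multiatlas_n, config=fusion_config)
    return {"unet": unet, "multiatlas": matlas}
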