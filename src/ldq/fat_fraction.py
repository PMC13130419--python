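"""Fat-fraction maps and per-muscle mean fat fraction.

The voxel-wise fat fraction is FF = F / (W + F), the ratio of the fat
image to the sum of the water and fat images. Voxels with negligible total
signal (air) are flagged invalid rather than silently set to 0/0. Muscle
means are arithmetic means of the valid voxels inside the structure's 3D
mask, reported in percent; masks can be cropped to an inclusive axial
slice range, and left/right values combine by an unweighted bilateral
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Geometry
from .volumes import MUSCLE_CODES, MUSCLES, DixonVolume, LabelMap

__all__ = ["FFMap", "FFRecord", "ff_map", "mean_ff", "bilateral_mean", "measure_subject", "measure_cohort"]


class EmptyStructureError(ValueError):
    """A structure has no voxels inside the (cropped) mask."""


@dataclass
class FFMap:
    """Voxel-wise fat-fraction grid with a validity mask."""

    ff: np.ndarray
    geometry: Geometry
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.ff = np.asarray(self.ff, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ff.shape != self.geometry.shape or self.valid.shape != self.geometry.shape:
            raise ValueError("ff/valid shape does not match geometry")


@dataclass
class FFRecord:
    """Per-subject, per-muscle mean fat fraction with context."""

    subject: str
    muscle: str
    side: str  # "L", "R" or "LR" for the bilateral mean
    mean_ff_pct: float
    n_voxels: int
    n_invalid: int = 0
    crop: tuple[int, int] | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_ff_pct <= 100.0:
            raise ValueError(f"mean FF must be in [0, 100] %, got {self.mean_ff_pct}")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


def ff_map(dixon: DixonVolume, epsilon: float | None = None) -> FFMap:
    """Compute FF = F / (W + F) with an explicit validity mask.

    ``epsilon`` defaults to 1e-6 times the maximum of W + F; voxels whose
    total signal is at or below it are flagged invalid.
    """
    total = dixon.water.astype(np.float64) + dixon.fat.astype(np.float64)
    if epsilon is None:
        epsilon = 1e-6 * float(total.max()) if total.max() > 0 else 1e-12
    valid = total > epsilon
    ff = np.zeros_like(total)
    np.divide(dixon.fat, total, out=ff, where=valid)
    ff = np.clip(ff, 0.0, 1.0)
    return FFMap(ff, dixon.geometry, valid)


def mean_ff(
    ffmap: FFMap,
    label_map: LabelMap,
    code: int,
    crop: tuple[int, int] | None = None,
) -> tuple[float, int, int]:
    """Mean FF (percent) over a structure's valid voxels.

    ``crop`` is an inclusive (z0, z1) axial slice range. Returns
    ``(mean_ff_pct, n_voxels_used, n_invalid_excluded)``; raises
    :class:`EmptyStructureError` if the cropped mask has no valid voxels.
    """
    ffmap.geometry.require_match(label_map.geometry, what="ff map vs label map")
    mask = label_map.labels == code
    if crop is not None:
        z0, z1 = crop
        zmask = np.zeros(mask.shape[2], dtype=bool)
        zmask[z0 : z1 + 1] = True
        mask = mask & zmask[None, None, :]
    n_total = int(mask.sum())
    usable = mask & ffmap.valid
    n_valid = int(usable.sum())
    if n_valid == 0:
        raise EmptyStructureError(
            f"structure code {code} has no valid voxels"
            + (f" in axial crop [{crop[0]}, {crop[1]}]" if crop else "")
        )
    return float(ffmap.ff[usable].mean() * 100.0), n_valid, n_total - n_valid


def bilateral_mean(left: FFRecord, right: FFRecord) -> FFRecord:
    """Unweighted mean of the left and right side means (not voxel-weighted)."""
    if left.subject != right.subject or left.muscle != right.muscle:
        raise ValueError("bilateral mean needs the same subject and muscle on both sides")
    if {left.side, right.side} != {"L", "R"}:
        raise ValueError(f"need one 'L' and one 'R' record, got {left.side!r}/{right.side!r}")
    return FFRecord(
        subject=left.subject,
        muscle=left.muscle,
        side="LR",
        mean_ff_pct=(left.mean_ff_pct + right.mean_ff_pct) / 2.0,
        n_voxels=left.n_voxels + right.n_voxels,
        n_invalid=left.n_invalid + right.n_invalid,
        crop=left.crop,
        covariates=dict(left.covariates),
    )


def measure_subject(
    dixon: DixonVolume,
    label_map: LabelMap,
    crop: tuple[int, int] | None = None,
    covariates: dict | None = None,
    allow_missing: bool = False,
) -> list[FFRecord]:
    """Per-side and bilateral FF records for every muscle of one subject.

    With ``allow_missing=True`` (useful for predicted masks, which may
    miss a structure entirely) absent structures are skipped instead of
    raising; the bilateral record needs both sides present.
    """
    fmap = ff_map(dixon)
    records: list[FFRecord] = []
    code_by_name = {name: code for code, name in MUSCLE_CODES.items()}
    for muscle in MUSCLES:
        sides = {}
        for side in ("L", "R"):
            try:
                value, n_vox, n_inv = mean_ff(fmap, label_map, code_by_name[f"{muscle}_{side}"], crop)
            except EmptyStructureError:
                if allow_missing:
                    continue
                raise
            rec = FFRecord(
                subject=dixon.subject_id, muscle=muscle, side=side,
                mean_ff_pct=value, n_voxels=n_vox, n_invalid=n_inv,
                crop=crop, covariates=dict(covariates or {}),
            )
            sides[side] = rec
            records.append(rec)
        if {"L", "R"} <= set(sides):
            records.append(bilateral_mean(sides["L"], sides["R"]))
    return records


def records_to_frame(records: list[FFRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject": r.subject, "muscle": r.muscle, "side": r.side,
            "mean_ff_pct": r.mean_ff_pct, "n_voxels": r.n_voxels, "n_invalid": r.n_invalid,
            "crop": f"{r.crop[0]}:{r.crop[1]}" if r.crop else "",
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def measure_cohort(
    pairs: list[tuple[DixonVolume, LabelMap]],
    covariates: pd.DataFrame | None = None,
    crop: tuple[int, int] | None = None,
    allow_missing: bool = True,
) -> pd.DataFrame:
    """FF records for a cohort, joined with per-subject covariates.

    Missing structures (possible in predicted masks) are skipped by
    default rather than aborting the whole cohort.
    """
    cov_by_subject = {}
    if covariates is not None:
        cov_cols = [c for c in ("age", "male", "bmi", "active") if c in covariates.columns]
        cov_by_subject = {
            row["subject"]: {c: row[c] for c in cov_cols} for _, row in covariates.iterrows()
        }
    records: list[FFRecord] = []
    for vol, lmap in pairs:
        records.extend(
            measure_subject(
                vol, lmap, crop=crop,
                covariates=cov_by_subject.get(vol.subject_id),
                allow_missing=allow_missing,
            )
        )
    return records_to_frame(records)
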