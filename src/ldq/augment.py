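"""Training-set augmentation: linear (flip + small rotations) and
nonlinear (pairwise early-stopped B-spline registration).

Linear augmentation enumerates {unflipped, flipped} x rotation angles per
training subject (10 variants with the default angle set {0, +-5, +-10}
degrees); flips mirror across the medial-lateral axis and swap left/right
label codes. Nonlinear augmentation registers every ordered pair of
training subjects with a deliberately small iteration budget, so the
optimisation stops early and the warped moving image is an intermediate
"virtual anatomy" between the two — n(n-1) synthetic subjects from n real
ones. Plans never reference validation subjects, which keeps augmentation
leakage-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .registration import (
    RegistrationParams,
    apply_transform_labels,
    apply_transform_volume,
    ncc,
    register_bspline,
)
from .volumes import FLIP_CODE_MAP, DixonVolume, LabelMap

__all__ = [
    "LinearAugmentSpec",
    "AugmentRecord",
    "AugmentPlan",
    "linear_plan",
    "nonlinear_plan",
    "full_plan",
    "apply_linear",
    "synthesize_deformed",
]

#: Early-stopped B-spline settings for virtual-anatomy synthesis.
NONLINEAR_PARAMS = RegistrationParams(iterations=500, samples=2048, pyramid=(4, 2, 1))


@dataclass(frozen=True)
class LinearAugmentSpec:
    """Flip + rotation grid for linear augmentation.

    ``angles_deg`` always includes 0 (the unrotated copy counts among the
    variants — this is what makes 18 subjects yield exactly 180 linear
    records); rotations are in the axial plane, about the slice axis.
    """

    flip_axis: int = 0  # medial-lateral
    angles_deg: tuple[float, ...] = (0.0, 5.0, -5.0, 10.0, -10.0)
    rotation_plane: tuple[int, int] = (0, 1)  # rotate within the axial plane

    def __post_init__(self) -> None:
        angles = tuple(dict.fromkeys(float(a) for a in self.angles_deg)) or (0.0,)
        if 0.0 not in angles:
            angles = (0.0,) + angles
        object.__setattr__(self, "angles_deg", angles)


@dataclass(frozen=True)
class AugmentRecord:
    """One augmentation output: a linear variant or a synthesized pair."""

    source: str
    kind: str  # "linear" | "nonlinear"
    flip: bool = False
    angle_deg: float = 0.0
    partner: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "nonlinear"):
            raise ValueError(f"unknown augmentation kind {self.kind!r}")
        if self.kind == "nonlinear" and (self.partner is None or self.partner == self.source):
            raise ValueError("nonlinear records need a distinct partner subject")


@dataclass
class AugmentPlan:
    """Ordered list of augmentation records for one training subset."""

    train_ids: tuple[str, ...]
    records: list[AugmentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def referenced_ids(self) -> set[str]:
        ids = {r.source for r in self.records}
        ids |= {r.partner for r in self.records if r.partner is not None}
        return ids

    def assert_no_leakage(self, validation_ids) -> None:
        """Hard guard: no record may touch a validation subject."""
        leaked = self.referenced_ids() & set(validation_ids)
        if leaked:
            raise ValueError(f"augmentation plan references validation subjects: {sorted(leaked)}")

    def to_records(self) -> list[dict]:
        return [asdict(r) for r in self.records]


def linear_plan(train_ids, spec: LinearAugmentSpec | None = None) -> AugmentPlan:
    """Enumerate flip x angle variants: |angles| * 2 records per subject."""
    train_ids = tuple(train_ids)
    if not train_ids:
        raise ValueError("linear_plan needs at least one training id")
    spec = spec or LinearAugmentSpec()
    records = [
        AugmentRecord(source=sid, kind="linear", flip=flip, angle_deg=angle)
        for sid in train_ids
        for flip in (False, True)
        for angle in spec.angles_deg
    ]
    return AugmentPlan(train_ids, records)


def nonlinear_plan(train_ids) -> AugmentPlan:
    """One record per ordered pair of distinct training ids: n(n-1) records."""
    train_ids = tuple(train_ids)
    if len(train_ids) < 2:
        raise ValueError("nonlinear_plan needs at least two training ids")
    records = [
        AugmentRecord(source=a, kind="nonlinear", partner=b)
        for a in train_ids
        for b in train_ids
        if a != b
    ]
    return AugmentPlan(train_ids, records)


def full_plan(train_ids, spec: LinearAugmentSpec | None = None) -> AugmentPlan:
    """Linear + nonlinear plan: 10n + n(n-1) records (486 for n=18)."""
    lin = linear_plan(train_ids, spec)
    non = nonlinear_plan(train_ids)
    return AugmentPlan(lin.train_ids, lin.records + non.records)


# ---------------------------------------------------------------------------
# Applying augmentations


def _flip_labels(labels: np.ndarray, axis: int) -> np.ndarray:
    flipped = np.flip(labels, axis=axis)
    out = flipped.copy()
    for src, dst in FLIP_CODE_MAP.items():
        out[flipped == src] = dst
    return out


def apply_linear(
    volume: DixonVolume,
    label_map: LabelMap | None,
    flip: bool,
    angle_deg: float,
    spec: LinearAugmentSpec | None = None,
) -> tuple[DixonVolume, LabelMap | None]:
    """Apply one linear augmentation record.

    Flips mirror across the medial-lateral axis and swap paired left/right
    label codes; rotations are about the image center in the axial plane
    (linear interpolation for images, nearest neighbour for labels).
    """
    spec = spec or LinearAugmentSpec()
    if float(angle_deg) not in spec.angles_deg:
        raise ValueError(f"angle {angle_deg} not in spec angles {spec.angles_deg}")
    chans = {k: v.copy() for k, v in volume.channels.items()}
    labels = label_map.labels.copy() if label_map is not None else None

    if flip:
        chans = {k: np.flip(v, axis=spec.flip_axis).copy() for k, v in chans.items()}
        if labels is not None:
            labels = _flip_labels(labels, spec.flip_axis)
    if angle_deg != 0.0:
        chans = {
            k: np.clip(
                ndimage.rotate(v, angle_deg, axes=spec.rotation_plane, reshape=False, order=1, mode="constant"),
                0.0, None,
            )
            for k, v in chans.items()
        }
        if labels is not None:
            labels = ndimage.rotate(labels, angle_deg, axes=spec.rotation_plane, reshape=False, order=0, mode="constant")

    out_vol = DixonVolume(chans["in_phase"], chans["water"], chans["fat"], volume.geometry, volume.subject_id)
    out_map = LabelMap(labels, label_map.geometry, label_map.code_table) if label_map is not None else None
    return out_vol, out_map


def synthesize_deformed(
    moving: tuple[DixonVolume, LabelMap | None],
    fixed_volume: DixonVolume,
    params: RegistrationParams | None = None,
) -> tuple[DixonVolume, LabelMap | None]:
    """Warp ``moving`` part-way toward ``fixed_volume`` (virtual anatomy).

    Runs an early-stopped B-spline registration of the moving in-phase
    image to the fixed one and applies the resulting transform to all
    channels and (nearest neighbour) to the labels. Deterministic for a
    fixed sampling seed in ``params``.
    """
    params = params or NONLINEAR_PARAMS
    mov_vol, mov_labels = moving
    mov_vol.geometry.require_match(fixed_volume.geometry, what="moving vs fixed (homogenise first)")
    try:
        transform = register_bspline(
            mov_vol.in_phase, mov_vol.geometry, fixed_volume.in_phase, fixed_volume.geometry, params
        )
    except Exception as exc:
        raise RuntimeError(
            f"virtual-anatomy synthesis failed for pair ({mov_vol.subject_id!r}, {fixed_volume.subject_id!r}): {exc}"
        ) from exc
    out_vol = apply_transform_volume(mov_vol, transform, fixed_volume.geometry)
    out_labels = (
        apply_transform_labels(mov_labels, transform, fixed_volume.geometry) if mov_labels is not None else None
    )
    return out_vol, out_labels
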