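"""Dixon volume and multi-label mask containers with NIfTI-1 I/O.

A Dixon acquisition yields three co-registered channels per subject: the
water image W, the fat image F, and the in-phase image IP = W + F. Muscle
masks are integer-coded label maps sharing the image geometry; the fixed
code table covers the four bilateral lumbar muscles (psoas, iliacus,
quadratus lumborum, erector spinae + multifidus), left side before right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import Geometry, GeometryMismatchError

__all__ = [
    "MUSCLE_CODES",
    "MUSCLES",
    "FLIP_CODE_MAP",
    "DixonVolume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_dixon",
    "write_dixon",
    "read_label_map",
    "write_label_map",
    "onehot_encode",
    "onehot_decode",
]

#: Fixed label codes: left side before right for each muscle.
MUSCLE_CODES: dict[int, str] = {
    1: "P_L",
    2: "P_R",
    3: "I_L",
    4: "I_R",
    5: "QL_L",
    6: "QL_R",
    7: "ESM_L",
    8: "ESM_R",
}

#: Muscle names without side, in code order.
MUSCLES: tuple[str, ...] = ("P", "I", "QL", "ESM")

#: Left/right code swap used when mirroring a volume across the medial-lateral axis.
FLIP_CODE_MAP: dict[int, int] = {0: 0, 1: 2, 2: 1, 3: 4, 4: 3, 5: 6, 6: 5, 7: 8, 8: 7}


@dataclass
class DixonVolume:
    """Co-registered in-phase / water / fat channels on one voxel grid."""

    in_phase: np.ndarray
    water: np.ndarray
    fat: np.ndarray
    geometry: Geometry
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("in_phase", "water", "fat"):
            arr = np.asarray(getattr(self, name), dtype=np.float32)
            if arr.shape != self.geometry.shape:
                raise GeometryMismatchError(
                    f"{name} shape {arr.shape} does not match geometry {self.geometry.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")
            setattr(self, name, arr)

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"in_phase": self.in_phase, "water": self.water, "fat": self.fat}

    def with_channels(self, in_phase, water, fat) -> "DixonVolume":
        return DixonVolume(in_phase, water, fat, self.geometry, self.subject_id)


@dataclass
class LabelMap:
    """Integer-coded multi-structure segmentation sharing a volume's geometry."""

    labels: np.ndarray
    geometry: Geometry
    code_table: dict[int, str] = field(default_factory=lambda: dict(MUSCLE_CODES))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("labels must be integer-valued")
            arr = np.round(arr).astype(np.int16)
        self.labels = arr.astype(np.int16, copy=False)
        if self.labels.shape != self.geometry.shape:
            raise GeometryMismatchError(
                f"labels shape {self.labels.shape} does not match geometry {self.geometry.shape}"
            )
        self.code_table = {int(k): str(v) for k, v in self.code_table.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.code_table)
        if unknown:
            raise ValueError(f"label codes {sorted(unknown)} not in code_table")

    @property
    def codes(self) -> list[int]:
        """All codes in the code table, sorted (0/background excluded)."""
        return sorted(self.code_table)

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def volume_mm3(self, code: int) -> float:
        return float(np.count_nonzero(self.labels == code)) * float(np.prod(self.geometry.spacing))


# ---------------------------------------------------------------------------
# One-hot encoding


def onehot_encode(label_map: LabelMap) -> np.ndarray:
    """Encode a LabelMap as a stack of binary channels.

    Returns an array of shape ``(n_codes + 1,) + grid_shape`` where channel 0
    is background and channel i corresponds to the i-th sorted code. Each
    voxel is hot in exactly one channel.
    """
    codes = label_map.codes
    out = np.zeros((len(codes) + 1,) + label_map.labels.shape, dtype=np.uint8)
    out[0] = label_map.labels == 0
    for i, code in enumerate(codes, start=1):
        out[i] = label_map.labels == code
    return out


def onehot_decode(stack: np.ndarray, geometry: Geometry, code_table: dict[int, str] | None = None) -> LabelMap:
    """Inverse of :func:`onehot_encode`: channel argmax back to integer codes."""
    if code_table is None:
        code_table = dict(MUSCLE_CODES)
    codes = [0] + sorted(code_table)
    idx = np.argmax(stack, axis=0)
    labels = np.asarray(codes, dtype=np.int16)[idx]
    return LabelMap(labels, geometry, code_table)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O

_GEOM_TOL_MM = 1e-4


def _geometry_from_nifti(img: nib.Nifti1Image) -> Geometry:
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return Geometry(shape=img.shape[:3], spacing=tuple(float(z) for z in zooms), origin=tuple(float(o) for o in origin))


def read_volume(path: str | Path) -> tuple[np.ndarray, Geometry]:
    """Read a scalar 3D NIfTI volume as ``(grid, geometry)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    return grid, _geometry_from_nifti(img)


def write_volume(grid: np.ndarray, geometry: Geometry, path: str | Path) -> Path:
    """Write a 3D grid as a NIfTI-1 file; read-back equals input."""
    path = Path(path)
    grid = np.asarray(grid)
    if grid.shape != geometry.shape:
        raise GeometryMismatchError(f"grid shape {grid.shape} != geometry {geometry.shape}")
    img = nib.Nifti1Image(grid, geometry.affine())
    img.header.set_zooms(geometry.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_dixon(
    in_phase_path: str | Path,
    water_path: str | Path,
    fat_path: str | Path,
    subject_id: str = "",
) -> DixonVolume:
    """Read a Dixon triplet, enforcing a shared geometry across channels.

    The three files must have identical shape and spacing/origin within
    0.0001 mm; a mismatch raises :class:`GeometryMismatchError` naming the
    offending axis.
    """
    ip, geom = read_volume(in_phase_path)
    w, gw = read_volume(water_path)
    f, gf = read_volume(fat_path)
    geom.require_match(gw, _GEOM_TOL_MM, what="in-phase vs water")
    geom.require_match(gf, _GEOM_TOL_MM, what="in-phase vs fat")
    return DixonVolume(ip, w, f, geom, subject_id)


def write_dixon(volume: DixonVolume, directory: str | Path, stem: str | None = None) -> dict[str, Path]:
    """Write the three Dixon channels as ``<stem>_{ip,water,fat}.nii.gz``."""
    directory = Path(directory)
    stem = stem or volume.subject_id or "dixon"
    paths = {}
    for tag, grid in (("ip", volume.in_phase), ("water", volume.water), ("fat", volume.fat)):
        paths[tag] = write_volume(grid, volume.geometry, directory / f"{stem}_{tag}.nii.gz")
    return paths


def read_label_map(path: str | Path, code_table_path: str | Path | None = None) -> LabelMap:
    """Read an integer label map; code table from a JSON sidecar if present."""
    grid, geom = read_volume(path)
    code_table = dict(MUSCLE_CODES)
    sidecar = Path(code_table_path) if code_table_path else Path(str(path).split(".nii")[0] + ".codes.json")
    if sidecar.exists():
        code_table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelMap(np.round(grid).astype(np.int16), geom, code_table)


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    """Write a label map plus its code table as a JSON sidecar."""
    out = write_volume(label_map.labels.astype(np.int16), label_map.geometry, path)
    sidecar = Path(str(path).split(".nii")[0] + ".codes.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in label_map.code_table.items()}, indent=1))
    return out
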