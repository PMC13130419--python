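"""Shared voxel-grid geometry for all volumetric data.

Axis convention used throughout the package: arrays are indexed ``(x, y, z)``
with ``x`` the left-right (medial-lateral) axis, ``y`` the anterior-posterior
axis and ``z`` the superior-inferior (axial slice) axis. Voxel indices are
0-based; axial crop ranges are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "GeometryMismatchError"]


class GeometryMismatchError(ValueError):
    """Two grids that must share a voxel geometry do not."""


@dataclass(frozen=True)
class Geometry:
    """Voxel grid geometry: matrix size, voxel size and origin.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts along (x, y, z). Each component must be >= 1.
    spacing : tuple of float
        Voxel size in mm along (x, y, z). All components must be > 0.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    axes : str
        Tag naming the axis convention; informational only.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "xyz:LR,AP,SI"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical field of view (mm) along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """Physical center of the grid in mm."""
        return tuple(o + (n - 1) * s / 2.0 for o, n, s in zip(self.origin, self.shape, self.spacing))

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-physical affine (axis-aligned, no shear)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    def matches(self, other: "Geometry", tol_mm: float = 1e-4) -> bool:
        """True if shapes are equal and spacing/origin agree within ``tol_mm``."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    def require_match(self, other: "Geometry", tol_mm: float = 1e-4, what: str = "grids") -> None:
        """Raise :class:`GeometryMismatchError` naming the offending axis."""
        if self.shape != other.shape:
            for ax, (a, b) in enumerate(zip(self.shape, other.shape)):
                if a != b:
                    raise GeometryMismatchError(
                        f"{what}: shape differs on axis {'xyz'[ax]}: {a} vs {b}"
                    )
        for ax, (a, b) in enumerate(zip(self.spacing, other.spacing)):
            if abs(a - b) > tol_mm:
                raise GeometryMismatchError(
                    f"{what}: spacing differs on axis {'xyz'[ax]}: {a} vs {b} mm"
                )
        for ax, (a, b) in enumerate(zip(self.origin, other.origin)):
            if abs(a - b) > tol_mm:
                raise GeometryMismatchError(
                    f"{what}: origin differs on axis {'xyz'[ax]}: {a} vs {b} mm"
                )
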