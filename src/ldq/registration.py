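"""Intensity-based registration backend (rigid, affine, B-spline).

Thin wrapper over SimpleITK's registration framework satisfying the
package's registration contract: normalised cross-correlation similarity,
a gradient-descent family optimiser, multi-resolution pyramid, and a fixed
sampling seed for determinism. The moving image is always the in-phase
channel; recovered transforms are then applied to every channel (linear
interpolation) and to label maps (nearest neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .geometry import Geometry
from .volumes import DixonVolume, LabelMap

__all__ = [
    "RegistrationParams",
    "RigidTransform",
    "RegistrationError",
    "ncc",
    "to_sitk",
    "from_sitk",
    "rigid_register",
    "register_affine",
    "register_bspline",
    "resample_to",
    "apply_transform_volume",
    "apply_transform_labels",
]


class RegistrationError(RuntimeError):
    """Registration could not run (e.g. non-overlapping volumes)."""


@dataclass(frozen=True)
class RegistrationParams:
    """Similarity/optimiser settings shared by all registration stages.

    ``metric`` is a tag naming the (fixed) similarity choice: normalised
    cross-correlation. ``optimizer`` selects the descent family for the
    B-spline stage: ``"gradient_descent"`` (sampled, stochastic) or
    ``"lbfgsb"`` (full sampling, deterministic). ``samples`` is the number
    of metric samples per iteration, converted to a sampling fraction of
    the fixed image; ``pyramid`` lists per-level shrink factors, coarse to
    fine.
    """

    metric: str = "ncc"
    optimizer: str = "gradient_descent"
    iterations: int = 200
    samples: int = 2048
    pyramid: tuple[int, ...] = (4, 2, 1)
    bspline_spacing_mm: float = 40.0
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform: rotation angles (degrees, about x/y/z), translation
    (mm) and rotation center (mm), in physical coordinates."""

    rotation_deg: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float]

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center_mm)
        t.SetRotation(*(np.deg2rad(a) for a in self.rotation_deg))
        t.SetTranslation(self.translation_mm)
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        angles = (t.GetAngleX(), t.GetAngleY(), t.GetAngleZ())
        return cls(
            rotation_deg=tuple(float(np.rad2deg(a)) for a in angles),
            translation_mm=tuple(float(v) for v in t.GetTranslation()),
            center_mm=tuple(float(v) for v in t.GetCenter()),
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_sitk(self.to_sitk().GetInverse())


# ---------------------------------------------------------------------------
# numpy <-> SimpleITK (arrays are (x, y, z); sitk arrays are (z, y, x))


def to_sitk(grid: np.ndarray, geometry: Geometry) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(grid, (2, 1, 0)), dtype=np.float64))
    img.SetSpacing(geometry.spacing)
    img.SetOrigin(geometry.origin)
    return img


def from_sitk(img: sitk.Image) -> tuple[np.ndarray, Geometry]:
    grid = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    geom = Geometry(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
    return grid, geom


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation of two equally shaped grids."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float((a * b).sum() / denom)


def _check_overlap(fixed: Geometry, moving: Geometry) -> None:
    for ax in range(3):
        f0 = fixed.origin[ax]
        f1 = f0 + (fixed.shape[ax] - 1) * fixed.spacing[ax]
        m0 = moving.origin[ax]
        m1 = m0 + (moving.shape[ax] - 1) * moving.spacing[ax]
        if f1 < m0 or m1 < f0:
            raise RegistrationError(
                f"volumes do not overlap in physical space on axis {'xyz'[ax]}"
            )


def _setup_method(fixed: sitk.Image, params: RegistrationParams) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    n_vox = int(np.prod(fixed.GetSize()))
    frac = min(1.0, params.samples / n_vox)
    if frac >= 0.999:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(frac, params.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    shrink = list(params.pyramid)
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, int(s // 2)) for s in shrink])
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-6,
        numberOfIterations=params.iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    return reg


def rigid_register(
    moving: DixonVolume, fixed: DixonVolume, params: RegistrationParams | None = None
) -> RigidTransform:
    """Recover the rigid transform aligning ``moving`` onto ``fixed``.

    Registers the in-phase channels with NCC similarity. The returned
    transform maps fixed-space points into moving space (the resampling
    convention), so resampling ``moving`` through it aligns it with
    ``fixed``.
    """
    params = params or RegistrationParams()
    _check_overlap(fixed.geometry, moving.geometry)
    f = to_sitk(fixed.in_phase, fixed.geometry)
    m = to_sitk(moving.in_phase, moving.geometry)
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = _setup_method(f, params)
    reg.SetInitialTransform(init, inPlace=False)
    try:
        result = reg.Execute(f, m)
    except RuntimeError as exc:  # pragma: no cover - backend failure path
        raise RegistrationError(f"rigid registration failed: {exc}") from exc
    euler = sitk.Euler3DTransform(result.GetNthTransform(0) if hasattr(result, "GetNthTransform") else result)
    return RigidTransform.from_sitk(euler)


def register_affine(
    moving_grid: np.ndarray,
    moving_geom: Geometry,
    fixed_grid: np.ndarray,
    fixed_geom: Geometry,
    params: RegistrationParams | None = None,
) -> sitk.Transform:
    """Affine registration of scalar grids; returns the fitted transform."""
    params = params or RegistrationParams()
    _check_overlap(fixed_geom, moving_geom)
    f = to_sitk(fixed_grid, fixed_geom)
    m = to_sitk(moving_grid, moving_geom)
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = _setup_method(f, params)
    reg.SetInitialTransform(init, inPlace=False)
    try:
        fitted = reg.Execute(f, m)
    except RuntimeError as exc:  # pragma: no cover
        raise RegistrationError(f"affine registration failed: {exc}") from exc
    # Never-worsen guard: keep the initial transform if the optimised one
    # lowered the full-volume NCC (the contract is NCC(after) >= NCC(before)).
    before = sitk.GetArrayFromImage(sitk.Resample(m, f, init, sitk.sitkLinear, 0.0))
    after = sitk.GetArrayFromImage(sitk.Resample(m, f, fitted, sitk.sitkLinear, 0.0))
    fgrid = sitk.GetArrayFromImage(f)
    if ncc(fgrid, after) < ncc(fgrid, before):
        return init
    return fitted


def register_bspline(
    moving_grid: np.ndarray,
    moving_geom: Geometry,
    fixed_grid: np.ndarray,
    fixed_geom: Geometry,
    params: RegistrationParams | None = None,
    initial: sitk.Transform | None = None,
) -> sitk.Transform:
    """B-spline free-form registration; ``initial`` (e.g. affine) optional.

    With a deliberately small iteration budget this stops early, producing
    an intermediate "virtual anatomy" between moving and fixed — the same
    mechanism used for nonlinear training-set augmentation.
    """
    params = params or RegistrationParams()
    f = to_sitk(fixed_grid, fixed_geom)
    m = to_sitk(moving_grid, moving_geom)
    if initial is not None:
        m = sitk.Resample(m, f, initial, sitk.sitkLinear, 0.0)
    mesh = [
        max(1, int(round(ext / params.bspline_spacing_mm)))
        for ext in (np.array(fixed_geom.shape) * np.array(fixed_geom.spacing))
    ]
    bspline = sitk.BSplineTransformInitializer(f, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    n_vox = int(np.prod(f.GetSize()))
    frac = min(1.0, params.samples / n_vox)
    if params.optimizer == "lbfgsb" or frac >= 0.999:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(frac, params.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    shrink = list(params.pyramid)
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, int(s // 2)) for s in shrink])
    if params.optimizer == "lbfgsb":
        reg.SetOptimizerAsLBFGSB(
            gradientConvergenceTolerance=1e-7, numberOfIterations=params.iterations
        )
    else:
        reg.SetOptimizerAsGradientDescent(
            learningRate=1.0,
            numberOfIterations=params.iterations,
            convergenceMinimumValue=1e-8,
            convergenceWindowSize=20,
            estimateLearningRate=reg.EachIteration,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(bspline, inPlace=True)
    try:
        fitted = reg.Execute(f, m)
    except RuntimeError as exc:  # pragma: no cover
        raise RegistrationError(f"B-spline registration failed: {exc}") from exc
    # Never-worsen guard against the pre-B-spline alignment.
    fgrid = sitk.GetArrayFromImage(f)
    before = sitk.GetArrayFromImage(m)
    after = sitk.GetArrayFromImage(sitk.Resample(m, f, fitted, sitk.sitkLinear, 0.0))
    improved = ncc(fgrid, after) >= ncc(fgrid, before)
    if initial is not None:
        composite = sitk.CompositeTransform(3)
        composite.AddTransform(initial)
        if improved:
            composite.AddTransform(fitted)
        return composite
    return fitted if improved else sitk.Transform(3, sitk.sitkIdentity)


def resample_to(
    grid: np.ndarray,
    geom: Geometry,
    reference: Geometry,
    transform: sitk.Transform | RigidTransform | None = None,
    nearest: bool = False,
    default_value: float = 0.0,
) -> np.ndarray:
    """Resample ``grid`` onto ``reference`` through ``transform``."""
    if isinstance(transform, RigidTransform):
        transform = transform.to_sitk()
    if transform is None:
        transform = sitk.Transform()
    img = to_sitk(grid, geom)
    ref = to_sitk(np.zeros(reference.shape, dtype=np.float32), reference)
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(img, ref, transform, interp, default_value)
    arr, _ = from_sitk(out)
    return arr


def apply_transform_volume(
    volume: DixonVolume, transform, reference: Geometry | None = None
) -> DixonVolume:
    """Resample all three Dixon channels through one transform (linear)."""
    ref = reference or volume.geometry
    chans = {
        name: np.clip(resample_to(grid, volume.geometry, ref, transform), 0.0, None)
        for name, grid in volume.channels.items()
    }
    return DixonVolume(chans["in_phase"], chans["water"], chans["fat"], ref, volume.subject_id)


def apply_transform_labels(
    label_map: LabelMap, transform, reference: Geometry | None = None
) -> LabelMap:
    """Resample a label map through one transform (nearest neighbour)."""
    ref = reference or label_map.geometry
    arr = resample_to(label_map.labels.astype(np.float32), label_map.geometry, ref, transform, nearest=True)
    return LabelMap(np.round(arr).astype(np.int16), ref, label_map.code_table)
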