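"""Synthetic Dixon phantoms with ground-truth muscle masks and cohorts.

Each phantom is an axial "abdomen": an elliptical soft-tissue body with a
high-fat subcutaneous ring, and eight muscle tubes (psoas, iliacus,
quadratus lumborum, erector spinae + multifidus; left and right) running
along the slice axis. Tissue follows a two-compartment model with unit
proton density: ``fat = FF * 1.0``, ``water = (1 - FF) * 1.0`` inside each
structure, so the in-phase image IP = W + F holds exactly by construction.
Per-subject anatomical variability is emulated with a smooth random
displacement field applied identically to all channels and (nearest
neighbour) to the labels.

Cohorts link per-muscle fat fraction to age, sex, BMI and physical-activity
group through a linear model, so downstream covariance analysis has known
ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Geometry
from .volumes import MUSCLE_CODES, MUSCLES, DixonVolume, LabelMap

__all__ = [
    "MuscleTube",
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_cohort_table",
]


class PhantomSpecError(ValueError):
    """Invalid phantom specification (e.g. overlapping muscle tubes)."""


@dataclass(frozen=True)
class MuscleTube:
    """Elliptic cylinder along the slice axis modelling one muscle belly.

    Offsets are mm from the body center (x positive toward the subject's
    left, y positive posterior); radii are in-plane semi-axes in mm;
    ``z_extent`` is the fraction of the axial field of view covered,
    centered mid-volume.
    """

    dx_mm: float
    dy_mm: float
    rx_mm: float
    ry_mm: float
    z_extent: tuple[float, float] = (0.10, 0.90)

    def __post_init__(self) -> None:
        if self.rx_mm <= 0 or self.ry_mm <= 0:
            raise PhantomSpecError(f"tube radii must be > 0, got {(self.rx_mm, self.ry_mm)}")


def _default_tubes() -> dict[str, MuscleTube]:
    # In-plane layout (128 mm FOV at the default grid): psoas near the
    # midline, iliacus lateral, quadratus lumborum posterior to psoas,
    # erector spinae + multifidus most posterior and largest.
    return {
        "P": MuscleTube(16.0, -8.0, 10.0, 10.0, (0.10, 0.90)),
        "I": MuscleTube(38.0, -2.0, 9.0, 8.0, (0.20, 0.95)),
        "QL": MuscleTube(18.0, 12.0, 8.0, 6.0, (0.10, 0.80)),
        "ESM": MuscleTube(14.0, 30.0, 12.0, 9.0, (0.05, 0.95)),
    }


def _default_ff() -> dict[str, float]:
    # Generative per-muscle fat fractions in the range reported for healthy
    # adult lumbar muscles (ES+M highest, iliacus lowest).
    return {"P": 0.156, "I": 0.116, "QL": 0.143, "ESM": 0.218}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for a single synthetic Dixon subject."""

    geometry: Geometry = field(default_factory=lambda: Geometry((64, 64, 32), (2.0, 2.0, 3.0)))
    tubes: dict[str, MuscleTube] = field(default_factory=_default_tubes)
    muscle_ff: dict[str, float] = field(default_factory=_default_ff)
    #: optional per-side override, keyed by code name like "P_L"; falls back to muscle_ff
    side_ff: dict[str, float] = field(default_factory=dict)
    subcutaneous_ff: float = 0.90
    subcutaneous_thickness_mm: float = 7.0
    other_tissue_ff: float = 0.25
    epimuscular_shell: bool = False
    epimuscular_thickness_mm: float = 4.0
    #: per-tissue proton signal density: fat-dominated tissue brightest on
    #: in-phase TSE, muscle darkest. FF is a signal ratio, so density
    #: cancels and FF recovery is unaffected.
    muscle_density: float = 0.80
    other_tissue_density: float = 0.90
    fat_density: float = 1.00
    noise_sd: float = 0.02
    deformation_mm: float = 3.0
    deformation_smooth_mm: float = 12.0
    seed: int = 0
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        for name, ff in {**self.muscle_ff, **self.side_ff}.items():
            if not 0.0 <= ff <= 1.0:
                raise PhantomSpecError(f"FF for {name} must be in [0, 1], got {ff}")
        if not 0.0 <= self.subcutaneous_ff <= 1.0:
            raise PhantomSpecError("subcutaneous FF must be in [0, 1]")
        if self.deformation_mm < 0 or self.noise_sd < 0:
            raise PhantomSpecError("noise_sd and deformation_mm must be >= 0")

    def ff_for(self, code: int) -> float:
        name = MUSCLE_CODES[code]
        if name in self.side_ff:
            return float(self.side_ff[name])
        return float(self.muscle_ff[name.rsplit("_", 1)[0]])


def _physical_coords(geometry: Geometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center physical coordinates (mm) relative to the grid center."""
    cx, cy, cz = geometry.center_mm
    xs = geometry.origin[0] + np.arange(geometry.shape[0]) * geometry.spacing[0] - cx
    ys = geometry.origin[1] + np.arange(geometry.shape[1]) * geometry.spacing[1] - cy
    zs = geometry.origin[2] + np.arange(geometry.shape[2]) * geometry.spacing[2] - cz
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _build_anatomy(
    spec: PhantomSpec, displacement_mm: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (labels, ff_grid, density_grid), evaluated analytically.

    All structures are defined by closed-form membership tests in physical
    coordinates. A deformation is applied by warping the *coordinate
    field* before evaluating those tests (the same warp for every channel
    and for the labels), so the deformed phantom has crisp, perfectly
    consistent boundaries and constant FF inside every structure — no
    interpolation error anywhere.
    """
    geom = spec.geometry
    X, Y, Z = _physical_coords(geom)
    if displacement_mm is not None:
        X = X + displacement_mm[0]
        Y = Y + displacement_mm[1]
        Z = Z + displacement_mm[2]
    ext_x, ext_y, ext_z = geom.extent_mm
    # Body ellipse with ~10% air margin.
    ax, ay = 0.45 * ext_x, 0.42 * ext_y
    body = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0
    inner = (X / (ax - spec.subcutaneous_thickness_mm)) ** 2 + (
        Y / (ay - spec.subcutaneous_thickness_mm)
    ) ** 2 <= 1.0
    subcut = body & ~inner

    ff = np.zeros(geom.shape, dtype=np.float32)
    ff[body] = spec.other_tissue_ff
    ff[subcut] = spec.subcutaneous_ff
    density = np.zeros(geom.shape, dtype=np.float32)
    density[body] = spec.other_tissue_density
    density[subcut] = spec.fat_density

    labels = np.zeros(geom.shape, dtype=np.int16)
    zmin = -ext_z / 2.0
    for code, name in MUSCLE_CODES.items():
        muscle, side = name.rsplit("_", 1)
        tube = spec.tubes[muscle]
        sign = -1.0 if side == "L" else 1.0
        z0_mm = zmin + tube.z_extent[0] * ext_z
        z1_mm = zmin + tube.z_extent[1] * ext_z
        in_plane = ((X - sign * tube.dx_mm) / tube.rx_mm) ** 2 + ((Y - tube.dy_mm) / tube.ry_mm) ** 2 <= 1.0
        mask = in_plane & (Z >= z0_mm) & (Z <= z1_mm)
        if np.any(labels[mask] != 0):
            raise PhantomSpecError(f"muscle tube {name} overlaps a previously placed tube")
        labels[mask] = code
        ff[mask] = spec.ff_for(code)
        density[mask] = spec.muscle_density

    if spec.epimuscular_shell:
        # Thin high-fat shell posterior to ES+M, outside the muscle masks,
        # emulating the epimuscular fat excluded from muscle borders.
        t = spec.epimuscular_thickness_mm
        tube = spec.tubes["ESM"]
        for sign in (-1.0, 1.0):
            outer = ((X - sign * tube.dx_mm) / (tube.rx_mm + t)) ** 2 + (
                (Y - tube.dy_mm) / (tube.ry_mm + t)
            ) ** 2 <= 1.0
            shell = outer & (labels == 0) & body & (Y > tube.dy_mm)
            ff[shell] = spec.subcutaneous_ff
            density[shell] = spec.fat_density
    return labels, ff, density


def _smooth_displacement(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    amplitude_mm: float,
    smooth_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random smooth displacement field (3, X, Y, Z) in mm, max norm = amplitude."""
    disp = rng.standard_normal((3,) + shape)
    sigmas = [smooth_mm / s for s in spacing]
    for c in range(3):
        disp[c] = ndimage.gaussian_filter(disp[c], sigma=sigmas)
    norms = np.sqrt((disp**2).sum(axis=0))
    peak = norms.max()
    if peak > 0:
        disp *= amplitude_mm / peak
    return disp


def generate_phantom(spec: PhantomSpec) -> tuple[DixonVolume, LabelMap, pd.DataFrame]:
    """Generate one synthetic Dixon triplet with its ground-truth mask.

    The anatomy is evaluated on a smoothly warped coordinate field (the
    identical warp for all channels and labels), then channel noise is
    added. Returns the Dixon volume, the label map, and a table of
    generative fat fraction per label code. Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    # Validate tube disjointness on the undeformed grid first: a shared
    # coordinate warp cannot create overlaps, so this check is exhaustive.
    _build_anatomy(spec)
    disp = None
    if spec.deformation_mm > 0:
        disp = _smooth_displacement(
            spec.geometry.shape, spec.geometry.spacing, spec.deformation_mm, spec.deformation_smooth_mm, rng
        )
    labels, ff, density = _build_anatomy(spec, disp)

    fat = ff * density
    water = (1.0 - ff) * density

    if spec.noise_sd > 0:
        water = np.clip(water + rng.normal(0.0, spec.noise_sd, water.shape), 0.0, None)
        fat = np.clip(fat + rng.normal(0.0, spec.noise_sd, fat.shape), 0.0, None)
    in_phase = water + fat

    vol = DixonVolume(in_phase, water, fat, spec.geometry, spec.subject_id)
    lmap = LabelMap(labels, spec.geometry)
    truth = pd.DataFrame(
        {
            "code": list(MUSCLE_CODES),
            "structure": [MUSCLE_CODES[c] for c in MUSCLE_CODES],
            "generative_ff": [spec.ff_for(c) for c in MUSCLE_CODES],
        }
    )
    return vol, lmap, truth


# ---------------------------------------------------------------------------
# Cohorts with covariate-linked fat fraction


def _default_effects() -> dict[str, dict[str, float]]:
    """Per-muscle linear model for FF: intercept at the reference subject
    (age 40, female, BMI 25, sedentary) plus slopes per covariate.

    Magnitudes follow the pattern reported for healthy lumbar muscles: age
    and activity dominate (strongest age effect in QL and ES+M, strongest
    activity effect in P and I); sex matters mostly for ES+M; BMI is minor.
    """
    return {
        "P": {"intercept": 0.170, "b_age": 0.0008, "b_sex": -0.002, "b_bmi": 0.0020, "b_active": -0.036},
        "I": {"intercept": 0.130, "b_age": 0.0008, "b_sex": -0.006, "b_bmi": 0.0025, "b_active": -0.035},
        "QL": {"intercept": 0.155, "b_age": 0.0020, "b_sex": -0.010, "b_bmi": 0.0015, "b_active": -0.030},
        "ESM": {"intercept": 0.250, "b_age": 0.0018, "b_sex": -0.066, "b_bmi": 0.0010, "b_active": -0.065},
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort of Dixon subjects."""

    n_subjects: int = 173
    age_range: tuple[float, float] = (20.0, 70.0)
    male_prob: float = 81 / 173
    bmi_mean: float = 25.7
    bmi_sd: float = 5.6
    active_prob: float = 86 / 173
    effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    residual_sd: float = 0.020
    asymmetry_sd: float = 0.005
    ff_clip: tuple[float, float] = (0.01, 0.95)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise PhantomSpecError("n_subjects must be >= 1")


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw covariates and generative per-muscle FF for each subject.

    FF model per muscle:
    ``FF = intercept + b_age*(age-40) + b_sex*male + b_bmi*(BMI-25)
    + b_active*active + eps``, ``eps ~ N(0, residual_sd^2)``, clipped to
    ``ff_clip``. Left and right sides share the muscle FF up to a small
    zero-mean asymmetry term. One row per subject with per-side FF columns.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, size=n)
    male = (rng.random(n) < spec.male_prob).astype(int)
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, size=n)
    active = (rng.random(n) < spec.active_prob).astype(int)

    rows: dict[str, np.ndarray] = {
        "subject": np.array([f"S{i:04d}" for i in range(n)]),
        "age": age,
        "male": male,
        "bmi": bmi,
        "active": active,
    }
    lo, hi = spec.ff_clip
    for muscle in MUSCLES:
        eff = spec.effects[muscle]
        ff = (
            eff["intercept"]
            + eff["b_age"] * (age - 40.0)
            + eff["b_sex"] * male
            + eff["b_bmi"] * (bmi - 25.0)
            + eff["b_active"] * active
            + rng.normal(0.0, spec.residual_sd, size=n)
        )
        asym = rng.normal(0.0, spec.asymmetry_sd, size=n)
        rows[f"ff_{muscle}"] = np.clip(ff, lo, hi)
        rows[f"ff_{muscle}_L"] = np.clip(ff - asym / 2, lo, hi)
        rows[f"ff_{muscle}_R"] = np.clip(ff + asym / 2, lo, hi)
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec, render_images: bool = True
) -> tuple[list[tuple[DixonVolume, LabelMap]], pd.DataFrame]:
    """Generate a cohort: covariate/FF ground-truth table plus, optionally,
    a rendered phantom per subject.

    Each subject's phantom uses its own sub-seed (derived from the cohort
    seed) and its per-side generative FF. With ``render_images=False`` only
    the table is produced, which is sufficient for statistical studies.
    """
    table = generate_cohort_table(spec)
    pairs: list[tuple[DixonVolume, LabelMap]] = []
    if render_images:
        seed_rng = np.random.default_rng(spec.seed + 1)
        sub_seeds = seed_rng.integers(0, 2**31 - 1, size=spec.n_subjects)
        for i, row in table.iterrows():
            side_ff = {
                f"{m}_{s}": float(row[f"ff_{m}_{s}"]) for m in MUSCLES for s in ("L", "R")
            }
            pspec = replace(
                spec.phantom,
                side_ff=side_ff,
                seed=int(sub_seeds[i]),
                subject_id=str(row["subject"]),
            )
            vol, lmap, _ = generate_phantom(pspec)
            pairs.append((vol, lmap))
    return pairs, table
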