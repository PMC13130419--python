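"""Segmentation metrics, CV planning, agreement statistics and ANCOVA.

Covers the full evaluation layer: Dice / relative volume difference /
Hausdorff distance per structure, Monte-Carlo cross-validation split
planning, Bland-Altman agreement with linear regression, Kruskal-Wallis
group tests, Type III ANCOVA with partial eta-squared effect sizes, and
median (IQR) normative reference tables stratified by activity group or
sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .volumes import LabelMap

__all__ = [
    "SegMetrics",
    "CVPlan",
    "AgreementResult",
    "AncovaTable",
    "dice",
    "rvd",
    "hausdorff",
    "segmentation_metrics",
    "mc_cv_plan",
    "bland_altman",
    "kruskal_wallis",
    "partial_eta_squared",
    "ancova_type3",
    "reference_table",
]


# ---------------------------------------------------------------------------
# Segmentation metrics


@dataclass(frozen=True)
class SegMetrics:
    """Dice, signed relative volume difference (%) and Hausdorff distance
    (mm) for one structure of one subject under one method."""

    dice: float
    rvd_pct: float
    hd_mm: float
    structure: str = ""
    subject: str = ""
    method: str = ""


def _masks(a: LabelMap, b: LabelMap, code: int) -> tuple[np.ndarray, np.ndarray]:
    a.geometry.require_match(b.geometry, what="metric inputs")
    return a.labels == code, b.labels == code


def dice(mask_a: LabelMap, mask_b: LabelMap, code: int) -> float:
    """Dice similarity 2|A^B| / (|A|+|B|); both-empty is defined as 1.0
    (perfect agreement on absence)."""
    a, b = _masks(mask_a, mask_b, code)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def rvd(pred: LabelMap, truth: LabelMap, code: int) -> float:
    """Signed relative volume difference (pred - truth) / truth * 100."""
    p, t = _masks(pred, truth, code)
    vt = int(t.sum())
    if vt == 0:
        raise ValueError(f"ground truth empty for code {code}")
    return (int(p.sum()) - vt) / vt * 100.0


def _boundary_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def hausdorff(mask_a: LabelMap, mask_b: LabelMap, code: int, percentile: float | None = None) -> float:
    """Symmetric Hausdorff distance (mm) between structure boundaries.

    Boundary voxel centers in physical units; the maximum of the two
    directed max-min distances. ``percentile`` (e.g. 95) replaces the max
    of each directed distance distribution with that percentile.
    """
    a, b = _masks(mask_a, mask_b, code)
    if not a.any() or not b.any():
        raise ValueError(f"hausdorff undefined: empty mask for code {code}")
    spacing = mask_a.geometry.spacing
    pa = _boundary_points_mm(a, spacing)
    pb = _boundary_points_mm(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def segmentation_metrics(
    pred: LabelMap, truth: LabelMap, subject: str = "", method: str = ""
) -> list[SegMetrics]:
    """All three metrics for every structure present in the ground truth."""
    out = []
    for code in truth.codes:
        if not (truth.labels == code).any():
            continue
        hd = (
            hausdorff(pred, truth, code)
            if (pred.labels == code).any()
            else float("inf")
        )
        out.append(
            SegMetrics(
                dice=dice(pred, truth, code),
                rvd_pct=rvd(pred, truth, code),
                hd_mm=hd,
                structure=truth.code_table[code],
                subject=subject,
                method=method,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation planning


@dataclass(frozen=True)
class CVPlan:
    """Fixed-split Monte-Carlo CV plan: per fold, disjoint train/val index
    sets covering all subjects; every subject in >= 1 validation set."""

    n_subjects: int
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    seed: int

    def validation_coverage(self) -> set[int]:
        cov: set[int] = set()
        for _, val in self.folds:
            cov |= set(val)
        return cov


def mc_cv_plan(n_subjects: int = 26, n_folds: int = 5, n_val: int = 8, seed: int = 0) -> CVPlan:
    """Randomly sample ``n_folds`` train/validation splits of size
    ``(n_subjects - n_val, n_val)``, resampling (bounded retries) until
    every subject appears in at least one validation set. Subjects may
    repeat across validation sets of different folds.
    """
    if n_val >= n_subjects:
        raise ValueError(f"n_val={n_val} must be < n_subjects={n_subjects}")
    if n_folds * n_val < n_subjects:
        raise ValueError(
            f"coverage infeasible: n_folds*n_val={n_folds * n_val} < n_subjects={n_subjects}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        folds = []
        for _ in range(n_folds):
            val = rng.choice(n_subjects, size=n_val, replace=False)
            train = np.setdiff1d(np.arange(n_subjects), val)
            folds.append((tuple(int(i) for i in train), tuple(int(i) for i in sorted(val))))
        plan = CVPlan(n_subjects, tuple(folds), seed)
        if plan.validation_coverage() == set(range(n_subjects)):
            return plan
    raise RuntimeError("could not satisfy validation coverage after bounded retries")


# ---------------------------------------------------------------------------
# Agreement statistics


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias and limits of agreement plus y-on-x regression."""

    bias: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r_squared: float


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of method ``y`` against method ``x``.

    bias = mean(y - x); limits of agreement = bias +- 1.96 * sd(y - x)
    with the sample (n-1) standard deviation; regression of y on x gives
    slope, intercept and R^2.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.allclose(x, x[0]):
        slope, intercept, r2 = 0.0, float(y.mean()), 1.0 if np.allclose(y, y[0]) else 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return AgreementResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, slope, intercept, r2)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on g-1 df."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # scipy raises on all-identical data
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Type III ANCOVA with partial eta squared


@dataclass(frozen=True)
class AncovaTable:
    """Type III ANCOVA results: one row per effect.

    ``table`` has columns effect, ss, df1, F, p, partial_eta_sq; ``df2``
    is the residual degrees of freedom of the full model; ``coef`` holds
    the fitted coefficients with standard errors (for recovery checks).
    """

    table: pd.DataFrame
    df2: int
    coef: pd.DataFrame = field(default_factory=pd.DataFrame, compare=False)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: df1*F / (df1*F + df2)."""
    return float(df1 * F / (df1 * F + df2))


def ancova_type3(
    data: pd.DataFrame,
    response: str,
    covariates: list[str],
    group: str | None = None,
) -> AncovaTable:
    """Type III ANCOVA: each effect's SS adjusted for all others.

    Continuous covariates enter linearly; the categorical ``group`` column
    uses sum-to-zero contrasts (so Type III sums of squares are
    well-defined). Effects are tested against the residual of the full
    model: F = (SS_eff/df1) / (SS_res/df2); partial eta^2 =
    SS_eff / (SS_eff + SS_res).
    """
    cols = list(covariates) + ([group] if group else [])
    missing = [c for c in cols + [response] if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if data[cols + [response]].isna().any().any():
        raise ValueError("missing values in model columns")
    terms = list(covariates)
    if group:
        terms.append(f"C({group}, Sum)")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    if model.df_resid <= 0:
        raise ValueError("model has no residual degrees of freedom")
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design: {model.model.exog.shape[1] - rank} aliased columns among {model.model.exog_names}"
        )
    anova = anova_lm(model, typ=3)
    ss_res = float(anova.loc["Residual", "sum_sq"])
    df2 = int(anova.loc["Residual", "df"])
    rows = []
    for term in terms:
        name = term if term in anova.index else term
        ss = float(anova.loc[name, "sum_sq"])
        df1 = int(anova.loc[name, "df"])
        F = float(anova.loc[name, "F"])
        p = float(anova.loc[name, "PR(>F)"])
        effect = group if term.startswith("C(") else term
        rows.append(
            {
                "effect": effect,
                "ss": ss,
                "df1": df1,
                "F": F,
                "p": p,
                "partial_eta_sq": ss / (ss + ss_res),
            }
        )
    coef = pd.DataFrame({"estimate": model.params, "se": model.bse})
    return AncovaTable(pd.DataFrame(rows), df2, coef)


# ---------------------------------------------------------------------------
# Normative reference tables


def reference_table(
    records: pd.DataFrame,
    strata: str = "none",
    value_col: str = "mean_ff_pct",
    percentiles: tuple[float, ...] = (25.0, 50.0, 75.0),
) -> pd.DataFrame:
    """Median / IQR (or an arbitrary percentile grid) of bilateral-mean FF
    per muscle, optionally stratified.

    ``strata`` is 'none' or a column name such as 'active' or 'male'.
    Percentiles use linear interpolation. Cells without records are
    flagged with NaN and n=0 rather than fabricated.
    """
    recs = records[records["side"] == "LR"] if "side" in records.columns else records
    if recs.empty:
        raise ValueError("no bilateral-mean records to tabulate")
    group_cols = ["muscle"] if strata == "none" else ["muscle", strata]
    if strata != "none" and strata not in recs.columns:
        raise ValueError(f"stratum column {strata!r} not in records")
    rows = []
    keys = recs.groupby(group_cols, sort=True).groups
    for key, idx in keys.items():
        key = key if isinstance(key, tuple) else (key,)
        values = recs.loc[idx, value_col].to_numpy(dtype=float)
        row = dict(zip(group_cols, key))
        row["n"] = len(values)
        if len(values) == 0:
            for p in percentiles:
                row[f"p{p:g}"] = float("nan")
        else:
            for p in percentiles:
                row[f"p{p:g}"] = float(np.percentile(values, p))  # linear interpolation
        if {25.0, 50.0, 75.0} <= set(percentiles):
            row["median"] = row["p50"]
            row["iqr_low"], row["iqr_high"] = row["p25"], row["p75"]
        rows.append(row)
    return pd.DataFrame(rows)
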