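"""Metrics, CV planning, agreement statistics and ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from ldq.eval_stats import (
    AncovaTable,
    ancova_type3,
    bland_altman,
    dice,
    hausdorff,
    kruskal_wallis,
    mc_cv_plan,
    partial_eta_squared,
    reference_table,
    rvd,
)
from ldq.geometry import Geometry
from ldq.volumes import LabelMap


def _lmap(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=np.int16)
    return LabelMap(arr, Geometry(arr.shape, spacing))


def _brute_force_hausdorff(a, b, spacing):
    """All-pairs oracle: boundary = voxels with a 6-neighbour outside."""

    def boundary(mask):
        interior = np.ones_like(mask)
        for ax in range(3):
            for sh in (1, -1):
                shifted = np.roll(mask, sh, axis=ax)
                edge_idx = [slice(None)] * 3
                edge_idx[ax] = 0 if sh == 1 else -1
                shifted[tuple(edge_idx)] = False
                interior &= shifted
        return mask & ~interior

    pa = np.argwhere(boundary(a)) * np.asarray(spacing)
    pb = np.argwhere(boundary(b)) * np.asarray(spacing)
    d = cdist(pa, pb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestDice:
    def test_identical_masks(self):
        m = _lmap(np.random.default_rng(0).integers(0, 3, (6, 6, 6)))
        assert dice(m, m, 1) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        b = np.zeros((4, 4, 4), dtype=np.int16)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dice(_lmap(a), _lmap(b), 1) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        b = np.zeros((4, 4, 4), dtype=np.int16)
        a[:2, :2, :2] = 1  # 8 voxels
        b[1:3, :2, :2] = 1  # 8 voxels, 4 shared
        assert dice(_lmap(a), _lmap(b), 1) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = _lmap(np.zeros((3, 3, 3)))
        assert dice(z, z, 5) == 1.0


class TestRVD:
    @pytest.mark.parametrize("vp, vt, expected", [(100, 100, 0.0), (110, 100, 10.0), (90, 100, -10.0)])
    def test_signed_percent(self, vp, vt, expected):
        p = np.zeros((10, 10, 10), dtype=np.int16)
        t = np.zeros((10, 10, 10), dtype=np.int16)
        p.ravel()[:vp] = 1
        t.ravel()[:vt] = 1
        assert rvd(_lmap(p), _lmap(t), 1) == pytest.approx(expected)

    def test_empty_truth_raises(self):
        p = _lmap(np.ones((2, 2, 2)))
        t = _lmap(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            rvd(p, t, 1)


class TestHausdorff:
    def test_identical_zero(self):
        m = np.zeros((5, 5, 5), dtype=np.int16)
        m[1:4, 1:4, 1:4] = 2
        assert hausdorff(_lmap(m), _lmap(m), 2) == 0.0

    def test_two_single_voxels_axis_distance(self):
        a = np.zeros((6, 1, 1), dtype=np.int16)
        b = np.zeros((6, 1, 1), dtype=np.int16)
        a[1, 0, 0] = 1
        b[4, 0, 0] = 1
        assert hausdorff(_lmap(a), _lmap(b), 1) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        a = np.zeros((6, 1, 1), dtype=np.int16)
        b = np.zeros((6, 1, 1), dtype=np.int16)
        a[1, 0, 0] = 1
        b[4, 0, 0] = 1
        assert hausdorff(_lmap(a, (2.0, 1.0, 1.0)), _lmap(b, (2.0, 1.0, 1.0)), 1) == pytest.approx(6.0)

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            a = rng.random((12, 12, 12)) > 0.6
            b = rng.random((12, 12, 12)) > 0.6
            got = hausdorff(_lmap(a.astype(int)), _lmap(b.astype(int)), 1)
            expected = _brute_force_hausdorff(a, b, (1.0, 1.0, 1.0))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_raises(self):
        a = _lmap(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            hausdorff(a, a, 1)


class TestMCCVPlan:
    def test_study_sizes(self):
        plan = mc_cv_plan(26, 5, 8, seed=0)
        assert sum(len(v) for _, v in plan.folds) == 40
        assert all(len(t) == 18 for t, _ in plan.folds)
        assert plan.validation_coverage() == set(range(26))

    def test_invariants_over_many_seeds(self):
        for seed in range(200):
            plan = mc_cv_plan(26, 5, 8, seed=seed)
            for train, val in plan.folds:
                assert set(train) & set(val) == set()
                assert set(train) | set(val) == set(range(26))
                assert len(val) == 8
            assert plan.validation_coverage() == set(range(26))

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            mc_cv_plan(26, 2, 8, seed=0)  # 16 < 26, coverage impossible
        with pytest.raises(ValueError):
            mc_cv_plan(5, 2, 8, seed=0)  # n_val >= n_subjects


class TestBlandAltman:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        res = bland_altman(x, x)
        assert res.bias == 0.0
        assert res.loa_high - res.loa_low == 0.0
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.arange(10.0)
        res = bland_altman(x, x + 2.5)
        assert res.bias == pytest.approx(2.5)
        assert res.loa_high - res.loa_low == pytest.approx(0.0)

    def test_known_noise_distribution(self):
        rng = np.random.default_rng(1234)
        x = rng.uniform(0, 30, 10_000)
        y = x + 0.5 + rng.normal(0, 1, 10_000)
        res = bland_altman(x, y)
        assert abs(res.bias - 0.5) < 0.03
        assert abs((res.loa_high - res.loa_low) - 2 * 1.96) < 0.12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_rank_statistic(self):
        # ranks {1,2,3} vs {4,5,6}: H = 12/(6*7) * (36/3 + 225/3) - 3*7
        h, _ = kruskal_wallis([[1, 2, 3], [101, 102, 103]])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.random(15)
        b = rng.random(12) + 0.2
        h1, _ = kruskal_wallis([a, b])
        h2, _ = kruskal_wallis([np.exp(a), np.exp(b)])
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestAncova:
    @staticmethod
    def _cohort(n=120, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "age": rng.uniform(20, 70, n),
                "male": rng.integers(0, 2, n),
                "bmi": rng.normal(25, 4, n),
                "group": rng.integers(0, 2, n),
            }
        )
        df["ff"] = (
            15 + 0.1 * (df.age - 40) - 0.5 * df.male + 0.2 * (df.bmi - 25)
            - 3.0 * df.group + rng.normal(0, 1.5, n)
        )
        return df

    def test_eta_identity_from_f_and_dfs(self):
        # identity eta_p^2 = df1*F/(df1*F + df2)
        assert partial_eta_squared(110.47, 1, 166) == pytest.approx(0.400, abs=5e-4)
        assert partial_eta_squared(37.31, 3, 166) == pytest.approx(0.403, abs=5e-4)

    def test_eta_identity_holds_on_fitted_tables(self):
        table = ancova_type3(self._cohort(), "ff", ["age", "male", "bmi"], group="group")
        for _, row in table.table.iterrows():
            ident = partial_eta_squared(row["F"], row["df1"], table.df2)
            assert row["partial_eta_sq"] == pytest.approx(ident, abs=1e-9)

    def test_balanced_orthogonal_design_type3_equals_sequential(self):
        # balanced 2x2 with orthogonal +-1 covariate: Type III SS == Type I SS
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        levels = [(a, g) for a in (-1.0, 1.0) for g in (0, 1)]
        rows = []
        rng = np.random.default_rng(5)
        for a, g in levels:
            for _ in range(10):
                rows.append({"x": a, "group": g, "ff": 10 + 2 * a - 1.5 * g + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        t3 = ancova_type3(df, "ff", ["x"], group="group")
        seq = anova_lm(smf.ols("ff ~ x + C(group, Sum)", df).fit(), typ=1)
        assert t3.effect("x")["ss"] == pytest.approx(seq.loc["x", "sum_sq"], rel=1e-9)
        assert t3.effect("group")["ss"] == pytest.approx(seq.loc["C(group, Sum)", "sum_sq"], rel=1e-9)

    def test_recovers_generative_coefficients(self):
        df = self._cohort(n=400, seed=7)
        table = ancova_type3(df, "ff", ["age", "male", "bmi"], group="group")
        coef = table.coef
        assert coef.loc["age", "estimate"] == pytest.approx(0.1, abs=2 * coef.loc["age", "se"])
        assert coef.loc["bmi", "estimate"] == pytest.approx(0.2, abs=2 * coef.loc["bmi", "se"])

    def test_rank_deficient_design_rejected(self):
        df = self._cohort()
        df["age_copy"] = df["age"]
        with pytest.raises(ValueError, match="rank-deficient|aliased"):
            ancova_type3(df, "ff", ["age", "age_copy"], group="group")

    def test_missing_values_rejected(self):
        df = self._cohort()
        df.loc[0, "bmi"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ancova_type3(df, "ff", ["age", "bmi"], group="group")


class TestReferenceTable:
    def test_median_of_three(self):
        df = pd.DataFrame({"muscle": "P", "side": "LR", "mean_ff_pct": [10.0, 12.0, 14.0]})
        out = reference_table(df)
        assert out.loc[0, "median"] == pytest.approx(12.0)

    def test_all_equal_iqr_zero(self):
        df = pd.DataFrame({"muscle": "P", "side": "LR", "mean_ff_pct": [9.0] * 5})
        out = reference_table(df)
        assert out.loc[0, "iqr_high"] - out.loc[0, "iqr_low"] == 0.0

    def test_stratified_shift_recovered(self):
        rng = np.random.default_rng(3)
        base = rng.normal(20, 0.5, 400)
        df = pd.DataFrame(
            {
                "muscle": "P",
                "side": "LR",
                "mean_ff_pct": np.concatenate([base, base - 4.0]),
                "active": [0] * 400 + [1] * 400,
            }
        )
        out = reference_table(df, strata="active").set_index("active")
        assert out.loc[0, "median"] - out.loc[1, "median"] == pytest.approx(4.0, abs=0.5)
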