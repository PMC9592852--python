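"""Statistical suite: ANOVA decomposition, sphericity, contrasts, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from reachvigor import stats as st

pingouin = pytest.importorskip("pingouin")


def _long(arr, factors):
    """ndarray (subjects × l1 [× l2]) → long-format frame."""
    n = arr.shape[0]
    rows = []
    for s in range(n):
        for idx in np.ndindex(arr.shape[1:]):
            row = {"participant": f"p{s}", "y": arr[(s,) + idx]}
            for f, i in zip(factors, idx):
                row[f] = f"{f}{i}"
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_one_way_matches_pingouin_including_gg(self):
        rng = np.random.default_rng(1)
        # non-spherical data: per-level variance scaling
        arr = rng.normal(size=(12, 4)) * np.array([1.0, 2.0, 4.0, 8.0])
        df = _long(arr, ["cond"])
        mine = st.rm_anova(df, dv="y", subject="participant", within=["cond"])
        ping = pingouin.rm_anova(
            data=df, dv="y", subject="participant", within="cond", correction=True
        )
        row = mine.iloc[0]
        assert row["F"] == pytest.approx(ping["F"].iloc[0], rel=1e-9)
        assert row["p_uncorrected"] == pytest.approx(ping["p_unc"].iloc[0], rel=1e-9)
        assert row["gg_epsilon"] == pytest.approx(ping["eps"].iloc[0], rel=1e-9)
        assert row["p_gg"] == pytest.approx(ping["p_GG_corr"].iloc[0], rel=1e-6)
        assert row["mauchly_W"] == pytest.approx(
            pingouin.sphericity(df, dv="y", subject="participant", within="cond").W,
            rel=1e-6,
        )

    def test_two_way_matches_pingouin(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(10, 3, 2)) + rng.normal(size=(10, 1, 1))
        df = _long(arr, ["position", "cs"])
        mine = st.rm_anova(
            df, dv="y", subject="participant", within=["position", "cs"]
        )
        ping = pingouin.rm_anova(
            data=df, dv="y", subject="participant", within=["position", "cs"]
        )
        for eff_mine, eff_ping in [
            ("position", "position"),
            ("cs", "cs"),
            ("position * cs", "position * cs"),
        ]:
            m = mine[mine.effect == eff_mine].iloc[0]
            p = ping[ping.Source == eff_ping].iloc[0]
            assert m["F"] == pytest.approx(p["F"], rel=1e-9)
            assert m["df1"] == p["ddof1"] and m["df2"] == p["ddof2"]
            assert m["p_uncorrected"] == pytest.approx(p["p_unc"], rel=1e-9)

    def test_three_way_decomposition_against_ols_projection(self):
        # independent oracle: effect SS via explicit cell-mean contrasts
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(8, 2, 3, 2))
        df = _long(arr, ["phase", "position", "cs"])
        mine = st.rm_anova(
            df, dv="y", subject="participant", within=["phase", "position", "cs"]
        )
        assert len(mine) == 7  # 3 mains + 3 two-way + 1 three-way
        # grand decomposition must recover the total sum of squares
        total = ((arr - arr.mean()) ** 2).sum()
        subj_ss = st._effect_ss(arr, (0,))
        parts = mine["ss_effect"].sum() + mine["ss_error"].sum() + subj_ss
        assert parts == pytest.approx(total, rel=1e-9)
        # a hand-computed main effect: phase
        phase_means = arr.mean(axis=(0, 2, 3))
        ss_phase = arr.shape[0] * 6 * ((phase_means - arr.mean()) ** 2).sum()
        assert mine[mine.effect == "phase"]["ss_effect"].iloc[0] == pytest.approx(
            ss_phase, rel=1e-9
        )

    def test_two_level_factor_equals_paired_t(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            df = _long(np.column_stack([x, y]), ["cond"])
            an = st.rm_anova(df, dv="y", subject="participant", within=["cond"]).iloc[0]
            t = st.paired_t(x, y)
            assert an["F"] == pytest.approx(t.t**2, rel=1e-9)
            assert an["p_uncorrected"] == pytest.approx(t.p, rel=1e-9)

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(5)
        df = _long(rng.normal(size=(4, 3)), ["cond"]).drop(index=[2])
        with pytest.raises(st.IncompleteDesignError, match="p0"):
            st.rm_anova(df, dv="y", subject="participant", within=["cond"])

    def test_single_participant_rejected(self):
        df = _long(np.zeros((1, 3)) + [[1.0, 2.0, 3.0]], ["cond"])
        with pytest.raises(st.IncompleteDesignError):
            st.rm_anova(df, dv="y", subject="participant", within=["cond"])

    def test_eta_identity_holds_per_effect(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(size=(10, 3, 2))
        df = _long(arr, ["a", "b"])
        out = st.rm_anova(df, dv="y", subject="participant", within=["a", "b"])
        for _, row in out.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["F"] * row["df1"] / (row["F"] * row["df1"] + row["df2"]),
                rel=1e-12,
            )
            assert row["ss_effect"] / (
                row["ss_effect"] + row["ss_error"]
            ) == pytest.approx(row["partial_eta_sq"], rel=1e-12)


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        cov = 0.5 * np.ones((4, 4)) + 0.5 * np.eye(4)
        assert st.gg_epsilon(cov) == pytest.approx(1.0)

    def test_maximal_asphericity_reaches_lower_bound(self):
        # all variance concentrated on a single contrast of 3 levels
        v = np.array([1.0, -1.0, 0.0])
        cov = np.outer(v, v) + 1e-12 * np.eye(3)
        assert st.gg_epsilon(cov) == pytest.approx(0.5, abs=1e-6)

    def test_bounds_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            k = rng.integers(3, 6)
            A = rng.normal(size=(k + 3, k))
            cov = A.T @ A
            eps = st.gg_epsilon(cov)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_direct_formula_oracle(self):
        # brute-force: orthonormal contrast version of the defining formula
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(6, 3)) @ np.diag([1.0, 2.0, 5.0])
        S = np.cov(Y, rowvar=False, ddof=1)
        C = st._orthonormal_contrasts(3)
        A = C @ S @ C.T
        expected = np.trace(A) ** 2 / (2 * np.sum(A * A))
        assert st.gg_epsilon(S) == pytest.approx(expected, rel=1e-12)

    def test_two_levels_rejected(self):
        with pytest.raises(ValueError):
            st.gg_epsilon(np.eye(2))


class TestHelmertContrasts:
    def test_equal_means_zero_t(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(10, 1))
        table = np.repeat(base, 3, axis=1) + rng.normal(scale=0.0, size=(10, 3))
        for c in st.helmert_contrasts(table):
            assert c.t == pytest.approx(0.0, abs=1e-9)

    def test_pooled_df_is_66_for_34_participants(self):
        rng = np.random.default_rng(10)
        for c in st.helmert_contrasts(rng.normal(size=(34, 3))):
            assert c.df == 66

    def test_hand_computed_example(self):
        # 5 participants, level means (1, 2, 3), additive participant offsets
        offsets = np.array([0.0, 1.0, -1.0, 2.0, 0.5])[:, None]
        table = offsets + np.array([[1.0, 2.0, 3.0]])
        noise = np.array(
            [
                [0.1, -0.1, 0.0],
                [-0.2, 0.1, 0.1],
                [0.0, 0.2, -0.2],
                [0.1, 0.0, -0.1],
                [-0.1, 0.1, 0.0],
            ]
        )
        table = table + noise
        n, k = table.shape
        resid = table - table.mean(0) - table.mean(1, keepdims=True) + table.mean()
        ms_err = (resid**2).sum() / ((k - 1) * (n - 1))
        c1 = table.mean(0) @ np.array([1.0, -0.5, -0.5])
        t1_expected = c1 / np.sqrt(ms_err * 1.5 / n)
        res = st.helmert_contrasts(table)
        assert res[0].t == pytest.approx(t1_expected, rel=1e-12)
        assert res[0].estimate < 0  # level 1 below mean of levels 2,3

    def test_weight_scale_cancels_in_t(self):
        # raw (1, −½, −½) vs doubled (2, −1, −1) weights: t identical
        rng = np.random.default_rng(11)
        table = rng.normal(size=(12, 3))
        res = st.helmert_contrasts(table)
        n, k = table.shape
        resid = table - table.mean(0) - table.mean(1, keepdims=True) + table.mean()
        ms_err = (resid**2).sum() / ((k - 1) * (n - 1))
        c = np.array([2.0, -1.0, -1.0])
        t_scaled = (table.mean(0) @ c) / np.sqrt(ms_err * (c**2).sum() / n)
        assert res[0].t == pytest.approx(t_scaled, rel=1e-12)

    def test_per_contrast_error_option(self):
        rng = np.random.default_rng(12)
        table = rng.normal(size=(15, 3))
        res = st.helmert_contrasts(table, pooled_error=False)
        scores = table @ np.array([1.0, -0.5, -0.5])
        t, p = sst.ttest_1samp(scores, 0.0)
        assert res[0].t == pytest.approx(t, rel=1e-12)
        assert res[0].df == 14

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError):
            st.helmert_contrasts(np.zeros((5, 4)))


class TestPairedT:
    def test_d_is_t_over_sqrt_n(self):
        rng = np.random.default_rng(13)
        for n in (5, 12, 34):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = st.paired_t(x, y)
            assert res.d == pytest.approx(res.t / np.sqrt(n), rel=1e-12)
            assert np.sign(res.d) == np.sign(res.t)
            assert res.df == n - 1

    def test_printed_effect_sizes_from_t(self):
        # d = t/√n for the published paired tests (n = 34)
        assert round(8.53 / np.sqrt(34), 2) == 1.46
        assert round(-14.40 / np.sqrt(34), 2) == -2.47
        lo, hi = st.cohens_d_ci(8.53, 34)
        assert (round(lo, 2), round(hi, 2)) == (0.97, 1.94)
        lo, hi = st.cohens_d_ci(-14.40, 34)
        assert (round(lo, 2), round(hi, 2)) == (-3.15, -1.78)

    def test_zero_variance_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(st.UndefinedStatisticError):
            st.paired_t(x, x)

    def test_symmetry(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a, b = st.paired_t(x, y), st.paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.d == pytest.approx(-b.d)


class TestEtaSquared:
    def test_point_values_from_published_fs(self):
        assert st.partial_eta_squared(0.0, 1, 33) == 0.0
        assert round(st.partial_eta_squared(41.41, 1, 33), 2) == 0.56
        assert round(st.partial_eta_squared(5.22, 1, 33), 2) == 0.14

    def test_ci_reproduces_published_interval(self):
        lo, hi = st.eta_squared_ci(41.41, 1, 33, level=0.90)
        assert (round(lo, 2), round(hi, 2)) == (0.35, 0.67)

    def test_zero_f_truncates_lower_bound(self):
        lo, hi = st.eta_squared_ci(0.0, 1, 33)
        assert lo == 0.0

    def test_bounds_bracket_point_estimate_when_significant(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            df1 = int(rng.integers(1, 4))
            df2 = int(rng.integers(10, 60))
            fcrit = sst.f.ppf(0.95, df1, df2)
            F = fcrit * rng.uniform(1.05, 6.0)
            eta = st.partial_eta_squared(F, df1, df2)
            lo, hi = st.eta_squared_ci(F, df1, df2, level=0.90)
            assert lo <= eta <= hi
            assert lo > 0.0


class TestWithinSubjectCi:
    def test_identical_profiles_collapse_to_zero(self):
        rng = np.random.default_rng(16)
        offsets = rng.normal(scale=10.0, size=(20, 1))
        table = offsets + np.array([[0.0, 1.0, 2.0]])
        half = st.within_subject_ci(table)
        assert np.allclose(half, 0.0, atol=1e-9)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            st.within_subject_ci(np.zeros((5, 1)))

    def test_smaller_than_between_when_offsets_dominate(self):
        rng = np.random.default_rng(17)
        smaller = 0
        for _ in range(100):
            offsets = rng.normal(scale=5.0, size=(12, 1))
            table = offsets + rng.normal(scale=1.0, size=(12, 4))
            corrected = st.within_subject_ci(table)
            n = table.shape[0]
            tcrit = sst.t.ppf(0.975, n - 1)
            uncorrected = tcrit * table.std(axis=0, ddof=1) / np.sqrt(n)
            if np.all(corrected <= uncorrected):
                smaller += 1
        assert smaller >= 95


class TestRobustPearson:
    def test_exact_line_nothing_removed(self):
        x = np.arange(10.0)
        res = st.robust_pearson(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.removed_points == ()

    def test_planted_outlier_removed_and_only_it(self):
        x = np.arange(68.0)
        y = 2 * x
        y[10] += 300.0
        res = st.robust_pearson(x, y)
        assert res.removed_points == (10,)
        assert res.n_used == 67
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_screen_disabled_is_plain_pearson(self):
        rng = np.random.default_rng(18)
        x, y = rng.normal(size=30), rng.normal(size=30)
        y[3] += 50.0
        res = st.robust_pearson(x, y, screen=False)
        r, p = sst.pearsonr(x, y)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p)
        assert res.removed_points == ()

    def test_degenerate_after_removal_rejected(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 50.0])
        # any removal from n=3 leaves too few points
        try:
            res = st.robust_pearson(x, y)
            assert res.n_used >= 3
        except st.UndefinedStatisticError:
            pass


class TestDifferentialScores:
    def _means(self, v_plus, v_minus):
        rows = []
        for phase in ("test_safety", "test_threat"):
            for pos in ("low", "middle", "high"):
                for cs, v in (("CS+", v_plus), ("CS-", v_minus)):
                    rows.append(
                        {
                            "participant": "p00",
                            "phase": phase,
                            "cs_type": cs,
                            "position": pos,
                            "peak_velocity_cm_s": v,
                        }
                    )
        return pd.DataFrame(rows)

    def test_null_differential(self):
        out = st.differential_scores(
            self._means(300.0, 300.0), ["peak_velocity_cm_s"],
            phases=("test_safety", "test_threat"),
        )
        assert out["peak_velocity_cm_s_diff"].iloc[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        out = st.differential_scores(
            self._means(310.0, 300.0), ["peak_velocity_cm_s"],
            phases=("test_safety", "test_threat"),
        )
        assert out["peak_velocity_cm_s_diff"].iloc[0] == pytest.approx(10.0)

    def test_missing_marginal_propagates_nan(self):
        df = self._means(310.0, 300.0)
        df = df[df.cs_type == "CS+"]
        out = st.differential_scores(
            df, ["peak_velocity_cm_s"], phases=("test_safety", "test_threat")
        )
        assert np.isnan(out["peak_velocity_cm_s_diff"].iloc[0])
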