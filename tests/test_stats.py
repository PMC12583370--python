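"""First-principles inference layer vs independent oracles.

The ANOVA decomposition is checked against explicit brute-force group-mean
sums and against statsmodels' OLS ANOVA; the studentized-range CDF against
scipy's independent implementation; Tukey's k=2 case against the pooled
t-test; Pearson r against closed-form sums.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitomorph import stats as st


# hand 2x2 dataset, 2 reps per cell: integers chosen for exact arithmetic
HAND_VALUES = np.array([3.0, 5.0, 6.0, 10.0, 7.0, 9.0, 12.0, 16.0])
HAND_A = np.array(["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"])
HAND_B = np.array(["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"])


def _brute_force_ss(values, fa, fb):
    """Oracle: sums of squares by explicit mean decomposition."""
    grand = values.mean()
    a_levels, b_levels = np.unique(fa), np.unique(fb)
    n = len(values) // (len(a_levels) * len(b_levels))
    ss_a = sum(
        (values[fa == a].mean() - grand) ** 2 * (fa == a).sum() for a in a_levels
    )
    ss_b = sum(
        (values[fb == b].mean() - grand) ** 2 * (fb == b).sum() for b in b_levels
    )
    ss_cells = sum(
        n * (values[(fa == a) & (fb == b)].mean() - grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_e = sum(
        ((values[(fa == a) & (fb == b)] - values[(fa == a) & (fb == b)].mean()) ** 2).sum()
        for a in a_levels
        for b in b_levels
    )
    return ss_a, ss_b, ss_cells - ss_a - ss_b, ss_e


class TestTwoWayAnova:
    def test_constant_data_gives_f_zero_p_one(self):
        vals = np.full(8, 4.2)
        tab = st.two_way_anova(vals, HAND_A, HAND_B)
        for s in ("factor_a", "factor_b", "interaction"):
            assert tab.f[s] == 0.0
            assert tab.p[s] == 1.0

    def test_hand_dataset_matches_brute_force_oracle(self):
        tab = st.two_way_anova(HAND_VALUES, HAND_A, HAND_B)
        ss_a, ss_b, ss_ab, ss_e = _brute_force_ss(HAND_VALUES, HAND_A, HAND_B)
        assert tab.ss["factor_a"] == pytest.approx(ss_a, abs=1e-9)
        assert tab.ss["factor_b"] == pytest.approx(ss_b, abs=1e-9)
        assert tab.ss["interaction"] == pytest.approx(ss_ab, abs=1e-9)
        assert tab.ss["residual"] == pytest.approx(ss_e, abs=1e-9)

    def test_ss_additivity_and_df_bookkeeping(self, rng):
        vals = rng.normal(0, 1, 30)
        fa = np.repeat(["x", "y", "z"], 10)
        fb = np.tile(np.repeat(["u", "v"], 5), 3)
        tab = st.two_way_anova(vals, fa, fb)
        assert sum(tab.ss.values()) == pytest.approx(tab.ss_total, rel=1e-9)
        assert sum(tab.df.values()) == len(vals) - 1

    def test_matches_statsmodels(self, rng):
        from statsmodels.formula.api import ols
        import statsmodels.api as sm

        vals = rng.normal(0, 1, 24)
        fa = np.repeat(["a1", "a2"], 12)
        fb = np.tile(np.repeat(["b1", "b2", "b3"], 4), 2)
        tab = st.two_way_anova(vals, fa, fb)
        df = pd.DataFrame({"y": vals, "A": fa, "B": fb})
        ref = sm.stats.anova_lm(ols("y ~ C(A)*C(B)", df).fit(), typ=2)
        assert tab.ss["factor_a"] == pytest.approx(ref.loc["C(A)", "sum_sq"], rel=1e-9)
        assert tab.ss["interaction"] == pytest.approx(
            ref.loc["C(A):C(B)", "sum_sq"], rel=1e-9
        )
        assert tab.p["factor_b"] == pytest.approx(ref.loc["C(B)", "PR(>F)"], rel=1e-9)

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError, match="nbalanced"):
            st.two_way_anova(
                np.arange(7.0), ["a"] * 4 + ["b"] * 3, ["x", "y"] * 3 + ["x"]
            )

    def test_singleton_cell_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            st.two_way_anova(
                np.arange(4.0), ["a", "a", "b", "b"], ["x", "y", "x", "y"]
            )

    def test_null_calibration(self):
        """Type-I error of each source ~5% under the null."""
        rng = np.random.default_rng(7)
        fa = np.repeat(["a1", "a2", "a3"], 10)
        fb = np.tile(np.repeat(["b1", "b2"], 5), 3)
        rej = {"factor_a": 0, "factor_b": 0, "interaction": 0}
        n = 400
        for _ in range(n):
            tab = st.two_way_anova(rng.normal(0, 1, 30), fa, fb)
            for s in rej:
                rej[s] += tab.p[s] < 0.05
        for s, k in rej.items():
            assert 0.02 < k / n < 0.09, (s, k / n)


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df",
        [(2.0, 2, 8), (3.5, 3, 12), (4.2, 6, 20), (1.0, 4, 5), (5.5, 2, 30), (3.0, 5, 4)],
    )
    def test_cdf_matches_scipy_oracle(self, q, k, df):
        mine = st.studentized_range_cdf(q, k, df)
        ref = sps.studentized_range.cdf(q, k, df)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_cdf_monotone_and_bounded(self):
        qs = np.linspace(0.1, 8, 25)
        vals = [st.studentized_range_cdf(q, 3, 10) for q in qs]
        assert all(0 <= v <= 1 for v in vals)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestTukey:
    def test_k2_equals_pooled_t_test(self, rng):
        for _ in range(5):
            g = {"a": rng.normal(0, 1, 5), "b": rng.normal(0.5, 1, 7)}
            res = st.tukey_hsd(g)
            _, _, p_t = st.students_t(g["a"], g["b"])
            assert res.comparisons[0]["p_adj"] == pytest.approx(p_t, abs=1e-9)

    def test_identical_group_means_give_p_one(self):
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([3.0, 2.0, 1.0]),
             "c": np.array([2.0, 1.0, 3.0])}
        res = st.tukey_hsd(g)
        for c in res.comparisons:
            assert c["p_adj"] == pytest.approx(1.0, abs=1e-12)
            assert not c["significant"]

    def test_matches_scipy_tukey(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0.0, 0.8, 2.0)]
        res = st.tukey_hsd({f"g{i}": g for i, g in enumerate(groups)})
        ref = sps.tukey_hsd(*groups)
        got = {
            frozenset((c["group_1"], c["group_2"])): c["p_adj"]
            for c in res.comparisons
        }
        for i in range(3):
            for j in range(i + 1, 3):
                assert got[frozenset((f"g{i}", f"g{j}"))] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-6
                )

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            st.tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestGatekeeping:
    @staticmethod
    def _data(rng, a_eff=0.0, b_eff=0.0, ab_eff=0.0, n=5):
        rows = []
        for a in ("ctrl", "mod"):
            for b in ("veh", "rot"):
                mu = (
                    a_eff * (a == "mod")
                    + b_eff * (b == "rot")
                    + ab_eff * ((a == "mod") and (b == "rot"))
                )
                for _ in range(n):
                    rows.append(
                        {"factor_a": a, "factor_b": b, "value": rng.normal(mu, 1)}
                    )
        return pd.DataFrame(rows)

    def test_nothing_significant_gives_empty_note(self, rng):
        df = self._data(rng)
        tab = st.two_way_anova(df["value"], df["factor_a"], df["factor_b"])
        if all(tab.p[s] >= 0.05 for s in tab.sources):
            out = st.gatekept_posthoc(tab, df)
            assert len(out) == 1
            assert out[0].family == "none"
            assert out[0].comparisons == []

    def test_strong_main_effect_compares_marginal_means(self, rng):
        df = self._data(rng, a_eff=5.0)
        tab = st.two_way_anova(df["value"], df["factor_a"], df["factor_b"])
        out = st.gatekept_posthoc(tab, df)
        assert any(t.family == "factor_a" for t in out)
        assert all(t.family != "cells" for t in out)
        fam_a = next(t for t in out if t.family == "factor_a")
        # marginal groups pool over the other factor: n = 10 per group
        assert {c["group_1"] for c in fam_a.comparisons} | {
            c["group_2"] for c in fam_a.comparisons
        } == {"ctrl", "mod"}

    def test_interaction_triggers_cell_mean_comparisons(self, rng):
        df = self._data(rng, ab_eff=6.0)
        tab = st.two_way_anova(df["value"], df["factor_a"], df["factor_b"])
        assert tab.p["interaction"] < 0.05
        out = st.gatekept_posthoc(tab, df)
        assert len(out) == 1
        assert out[0].family == "cells"
        groups = {c["group_1"] for c in out[0].comparisons} | {
            c["group_2"] for c in out[0].comparisons
        }
        assert groups == {"ctrl:veh", "ctrl:rot", "mod:veh", "mod:rot"}


class TestStudentsT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = st.students_t(x, x.copy())
        assert t == 0.0 and p == 1.0 and df == 4

    def test_hand_oracle(self):
        # {1,2,3} vs {4,5,6}: pooled s2 = 1, se = sqrt(2/3), t = -3/se
        t, df, p = st.students_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        se = np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(-3.0 / se, abs=1e-12)
        assert df == 4
        assert p == pytest.approx(2 * sps.t.sf(3.0 / se, 4), abs=1e-12)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        t, _, p = st.students_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means(self):
        t, _, p = st.students_t([2.0, 2.0], [1.0, 1.0])
        assert np.isinf(t) and p == 0.0

    def test_null_calibration(self):
        rng = np.random.default_rng(21)
        rej = sum(
            st.students_t(rng.normal(0, 1, 5), rng.normal(0, 1, 5))[2] < 0.05
            for _ in range(400)
        )
        assert 0.02 < rej / 400 < 0.09


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        cm = st.pearson_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1}))
        assert cm.r.loc["x", "y"] == 1.0

    def test_perfect_negative(self):
        x = np.arange(8.0)
        cm = st.pearson_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert cm.r.loc["x", "y"] == -1.0

    def test_hand_sums_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 5.0, 4.0, 9.0])
        cm = st.pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        sx, sy = x - x.mean(), y - y.mean()
        r_oracle = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert cm.r.loc["x", "y"] == pytest.approx(r_oracle, abs=1e-12)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert cm.r.loc["x", "y"] == pytest.approx(r_ref, abs=1e-12)
        assert cm.p.loc["x", "y"] == pytest.approx(p_ref, abs=1e-9)

    def test_symmetry_and_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (12, 4)), columns=list("abcd"))
        cm = st.pearson_matrix(df)
        assert np.allclose(cm.r.values, cm.r.values.T)
        assert np.allclose(np.diag(cm.r.values), 1.0)
        assert np.nanmax(np.abs(cm.r.values)) <= 1.0

    def test_pairwise_complete_handling(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 10), "y": rng.normal(0, 1, 10)})
        df.loc[3, "y"] = np.nan
        cm = st.pearson_matrix(df)
        assert cm.n.loc["x", "y"] == 9

    def test_constant_variable_flagged_nan(self):
        df = pd.DataFrame({"x": np.arange(5.0), "c": np.ones(5)})
        cm = st.pearson_matrix(df)
        assert np.isnan(cm.r.loc["x", "c"])
        assert cm.significant_pairs() == []

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        rej = 0
        for _ in range(400):
            df = pd.DataFrame({"x": rng.normal(0, 1, 10), "y": rng.normal(0, 1, 10)})
            rej += st.pearson_matrix(df).p.loc["x", "y"] < 0.05
        assert 0.02 < rej / 400 < 0.09
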