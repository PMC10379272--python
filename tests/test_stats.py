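"""Tests for the group-statistics layer, with independent oracles:
scipy for the t and Shapiro routes, brute-force label enumeration for the
exact Mann-Whitney p, a hand-computed sum-of-squares table and pingouin for
the split-plot ANOVA, and the covariance formula for Pearson r."""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from operant_stereo.stats import (
    GroupSample,
    behavior_anatomy_correlation,
    bonferroni_adjust,
    format_percent_change,
    mann_whitney_u,
    mixed_design_anova,
    normality_gate,
    percent_change,
    pooled_t_from_summary,
    pooled_t_test,
    two_sample_test,
)


class TestPercentChange:
    @pytest.mark.parametrize("ref, cmp_, text", [
        (11479, 8894, "23% decrease"),
        (0.989, 1.007, "2% increase"),
        (0.682, 0.585, "14% decrease"),
        (17034, 15269, "10% decrease"),
    ])
    def test_footnote_style(self, ref, cmp_, text):
        assert format_percent_change(ref, cmp_) == text

    def test_identity_and_errors(self):
        assert percent_change(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    def test_re_referencing_consistency(self):
        a, b = 0.682, 0.585
        d1 = percent_change(a, b) / 100
        d2 = percent_change(b, a) / 100
        assert (1 + d1) * (1 + d2) == pytest.approx(1.0, rel=1e-12)


class TestPooledT:
    def test_summary_input_reproduces_published_t(self):
        r = pooled_t_from_summary(11479, 1042, 6, 8894, 1060, 8)
        assert r.statistic == pytest.approx(4.548, abs=5e-4)
        assert r.df == 12

    def test_raw_equals_summary(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(10, 2, 7), rng.normal(9, 2, 5)
        r1 = pooled_t_test(GroupSample("x", list(x)), GroupSample("y", list(y)))
        r2 = pooled_t_from_summary(x.mean(), x.std(ddof=1), 7,
                                   y.mean(), y.std(ddof=1), 5)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_against_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1.2, 9)
            mine = pooled_t_test(GroupSample("x", list(x)),
                                 GroupSample("y", list(y)))
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_groups(self):
        r = pooled_t_test(GroupSample("x", [1.0, 2.0, 3.0]),
                          GroupSample("y", [1.0, 2.0, 3.0]))
        assert r.statistic == 0.0
        with pytest.raises(ValueError, match="pooled variance"):
            pooled_t_test(GroupSample("x", [2.0, 2.0]),
                          GroupSample("y", [2.0, 2.0]))


def brute_force_mw_p(x, y, tails="two"):
    """Independent oracle: enumerate every labeling of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u1_of(sel):
        ranks = sps.rankdata(pooled)
        r1 = ranks[list(sel)].sum()
        return r1 - n1 * (n1 + 1) / 2

    obs_sel = tuple(range(n1))
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u2 = n1 * len(y) - u1
    u_min = min(u1, u2)
    null = [ranks[list(c)].sum() - n1 * (n1 + 1) / 2
            for c in combinations(range(len(pooled)), n1)]
    null = np.asarray(null)
    lo = np.mean(null <= u_min)
    hi = np.mean(null >= n1 * len(y) - u_min)
    if tails == "one":
        return lo if u1 <= u_min else hi
    return min(lo + hi, 1.0)


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        r = mann_whitney_u(GroupSample("a", [1, 2]), GroupSample("b", [3, 4]),
                           tails="one")
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1 / 6)

    def test_balanced_ranks_give_central_u(self):
        r = mann_whitney_u(GroupSample("a", [1, 4]), GroupSample("b", [2, 3]))
        assert r.statistic == 2 == 2 * 2 / 2

    def test_exact_p_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for n1, n2 in [(3, 4), (4, 5), (5, 5), (2, 6)]:
            x = list(rng.normal(0, 1, n1))
            y = list(rng.normal(0.8, 1, n2))
            for tails in ("one", "two"):
                mine = mann_whitney_u(GroupSample("x", x),
                                      GroupSample("y", y), tails)
                assert mine.p_value == pytest.approx(
                    brute_force_mw_p(x, y, tails), abs=1e-12)

    def test_exact_p_matches_scipy(self):
        x, y = [3.1, 4.5, 2.2, 5.5], [1.1, 2.0, 0.5]
        mine = mann_whitney_u(GroupSample("x", x), GroupSample("y", y))
        ref = sps.mannwhitneyu(x, y, method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_u_bound_respected(self):
        rng = np.random.default_rng(12)
        x, y = list(rng.normal(0, 1, 7)), list(rng.normal(0, 1, 10))
        r = mann_whitney_u(GroupSample("x", x), GroupSample("y", y))
        assert 0 <= r.statistic <= 7 * 10

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning):
            r = mann_whitney_u(GroupSample("x", [2.0, 2.0]),
                               GroupSample("y", [2.0, 2.0, 2.0]))
        assert r.p_value == 1.0


class TestNormalityGate:
    def test_normal_quantiles_parametric(self):
        q = sps.norm.ppf(np.linspace(0.05, 0.95, 10))
        assert normality_gate(GroupSample("g", list(q))) == "parametric"

    def test_outlier_routes_nonparametric(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98, 25.0]
        assert normality_gate(GroupSample("g", vals)) == "nonparametric"

    def test_constant_sample_warns_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normality_gate(GroupSample("g", [3.0] * 6))
        assert out == "nonparametric"

    def test_gated_dispatch(self):
        q = list(sps.norm.ppf(np.linspace(0.05, 0.95, 8)))
        r = two_sample_test(GroupSample("a", q),
                            GroupSample("b", [v + 1 for v in q]))
        assert r.test_name == "pooled_t"
        skewed = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98, 25.0]
        r = two_sample_test(GroupSample("a", q), GroupSample("b", skewed))
        assert r.test_name == "mann_whitney_u"


class TestMixedAnova:
    @staticmethod
    def toy_frame():
        # 2 groups x 2 animals x 2 timepoints with within-group slope spread
        rows = [
            ("a1", "c", 0, 1.0), ("a1", "c", 1, 2.0),
            ("a2", "c", 0, 2.0), ("a2", "c", 1, 5.0),
            ("b1", "t", 0, 2.0), ("b1", "t", 1, 6.0),
            ("b2", "t", 0, 3.0), ("b2", "t", 1, 9.0),
        ]
        return pd.DataFrame(rows, columns=["animal_id", "group", "time", "value"])

    def test_manual_ss_decomposition_oracle(self):
        # independent oracle: explicit loop-based split-plot SS table
        df = self.toy_frame()
        data = {(r.animal_id, r.time): r.value for r in df.itertuples()}
        subjects = {"a1": "c", "a2": "c", "b1": "t", "b2": "t"}
        times = [0, 1]
        grand = sum(data.values()) / len(data)
        subj_mean = {s: sum(data[(s, t)] for t in times) / 2 for s in subjects}
        grp_mean = {g: np.mean([subj_mean[s] for s in subjects
                                if subjects[s] == g]) for g in ("c", "t")}
        time_mean = {t: np.mean([data[(s, t)] for s in subjects])
                     for t in times}
        cell_mean = {(g, t): np.mean([data[(s, t)] for s in subjects
                                      if subjects[s] == g])
                     for g in ("c", "t") for t in times}
        ss_total = sum((v - grand) ** 2 for v in data.values())
        ss_bs = 2 * sum((subj_mean[s] - grand) ** 2 for s in subjects)
        ss_group = 2 * sum(2 * (grp_mean[g] - grand) ** 2 for g in ("c", "t"))
        ss_time = 4 * sum((time_mean[t] - grand) ** 2 for t in times)
        ss_cells = sum(2 * (cell_mean[(g, t)] - grand) ** 2
                       for g in ("c", "t") for t in times)
        ss_int = ss_cells - ss_group - ss_time
        ss_err = ss_total - ss_bs - ss_time - ss_int

        res = mixed_design_anova(df)
        ss = res["_ss"]
        assert ss["total"] == pytest.approx(ss_total)
        assert ss["between_subjects"] == pytest.approx(ss_bs)
        assert ss["group"] == pytest.approx(ss_group)
        assert ss["time"] == pytest.approx(ss_time)
        assert ss["interaction"] == pytest.approx(ss_int)
        assert ss["error"] == pytest.approx(ss_err)
        f_group = (ss_group / 1) / ((ss_bs - ss_group) / 2)
        f_time = (ss_time / 1) / (ss_err / 2)
        assert res["group"].statistic == pytest.approx(f_group, rel=1e-12)
        assert res["time"].statistic == pytest.approx(f_time, rel=1e-12)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        rows = []
        for g, n in (("c", 5), ("t", 6)):
            for a in range(n):
                base = rng.normal(0, 1)
                for tp in range(4):
                    rows.append((f"{g}{a}", g, tp,
                                 base + (0.5 * tp if g == "t" else 0)
                                 + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["animal_id", "group", "time", "value"])
        res = mixed_design_anova(df)
        aov = pg.mixed_anova(df, dv="value", within="time", between="group",
                             subject="animal_id").set_index("Source")
        assert res["group"].statistic == pytest.approx(
            aov.loc["group", "F"], rel=1e-9)
        assert res["time"].statistic == pytest.approx(
            aov.loc["time", "F"], rel=1e-9)
        assert res["interaction"].statistic == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9)

    def test_ss_conservation(self):
        rng = np.random.default_rng(8)
        rows = [(f"{g}{a}", g, tp, rng.normal())
                for g, n in (("c", 4), ("t", 5))
                for a in range(n) for tp in range(5)]
        df = pd.DataFrame(rows, columns=["animal_id", "group", "time", "value"])
        ss = mixed_design_anova(df)["_ss"]
        assert ss["total"] == pytest.approx(
            ss["between_subjects"] + ss["within_subjects"], rel=1e-9)
        assert ss["within_subjects"] == pytest.approx(
            ss["time"] + ss["interaction"] + ss["error"], rel=1e-9)

    def test_constant_data_is_an_error(self):
        df = self.toy_frame()
        df["value"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            mixed_design_anova(df)

    def test_missing_cell_names_the_animal(self):
        df = self.toy_frame().iloc[:-1]
        with pytest.raises(ValueError, match="b2"):
            mixed_design_anova(df)


class TestMultiplicityAndCorrelation:
    def test_bonferroni(self):
        assert bonferroni_adjust([0.01], m=2)[0] == pytest.approx(0.02)
        assert bonferroni_adjust([0.6], m=4)[0] == 1.0
        p = np.array([0.001, 0.2, 0.9])
        assert np.all(bonferroni_adjust(p) >= p)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)

    def test_collinear_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = behavior_anatomy_correlation(x, [2 * v for v in x], m_comparisons=1)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value < 1e-6

    def test_hand_formula_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r = behavior_anatomy_correlation(x, y, m_comparisons=4)
        hand = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert r.statistic == pytest.approx(hand, rel=1e-12)
        assert r.adjusted_p == pytest.approx(min(r.p_value * 4, 1.0))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            behavior_anatomy_correlation([1, 1, 1], [1, 2, 3])
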