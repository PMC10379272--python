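"""Group statistics: percent change, normality-gated two-sample tests,
split-plot (mixed-design) repeated-measures ANOVA, Bonferroni correction and
behaviour-anatomy Pearson correlation.

Conventions follow the standard bench workflow of this literature: normality
is screened per group with Shapiro-Wilk at alpha = 0.05 and any failure
routes the comparison to the non-parametric test; the Mann-Whitney U is
reported as min(U1, U2) with an exact permutation p-value for small samples;
the ANOVA reports uncorrected (sphericity-assumed) F statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "percent_change",
    "format_percent_change",
    "pooled_t_test",
    "pooled_t_from_summary",
    "mann_whitney_u",
    "normality_gate",
    "two_sample_test",
    "mixed_design_anova",
    "bonferroni_adjust",
    "behavior_anatomy_correlation",
]

EXACT_MW_MAX_N = 12  # combined-n cutoff for exact U enumeration


@dataclass
class GroupSample:
    label: str
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("GroupSample needs >= 1 value")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    tails: str = "two"
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------

def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``."""
    if reference_mean == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def format_percent_change(reference_mean: float, comparison_mean: float) -> str:
    """Rounded footnote-style wording, e.g. ``'23% decrease'``."""
    pct = percent_change(reference_mean, comparison_mean)
    word = "increase" if pct > 0 else "decrease" if pct < 0 else "change"
    return f"{round(abs(pct))}% {word}"


def _one_sided(p_two: float) -> float:
    # one-tailed convention: the alternative is in the observed direction,
    # so the one-tailed p is half the two-tailed p
    return p_two / 2.0


def pooled_t_test(a: GroupSample, b: GroupSample, tails: str = "two") -> TestResult:
    """Classical pooled-variance two-sample Student t-test.

    One-tailed p tests the alternative in the observed direction.
    """
    x, y = np.asarray(a.values, float), np.asarray(b.values, float)
    return pooled_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, tails
    )


def pooled_t_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int,
                          tails: str = "two") -> TestResult:
    """Pooled t-test from summary statistics (mean, SD, n) per group."""
    if n1 + n2 < 3:
        raise ValueError("need n1 + n2 >= 3")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p_two = 2.0 * sps.t.sf(abs(t), df)
    p = p_two if tails == "two" else _one_sided(p_two)
    return TestResult("pooled_t", float(t), df, float(min(p, 1.0)), tails)


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    return u1, x.size * y.size - u1


def mann_whitney_u(a: GroupSample, b: GroupSample, tails: str = "two") -> TestResult:
    """Mann-Whitney U test, reported as min(U1, U2).

    For combined n <= 12, the p-value is exact: every C(n1+n2, n1) relabelling
    of the pooled sample is enumerated and the proportion of labelings with a
    U at least as extreme as observed is returned.  Larger samples use the
    normal approximation with tie correction.  One-tailed p is the single
    tail in the observed direction (half the two-tailed exact tail mass).
    """
    x, y = np.asarray(a.values, float), np.asarray(b.values, float)
    u1, u2 = _u_statistics(x, y)
    u_min = min(u1, u2)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("all values tied across both groups; p = 1")
        return TestResult("mann_whitney_u", u_min, None, 1.0, tails)
    if n1 + n2 <= EXACT_MW_MAX_N:
        # exact permutation distribution of U1 under the null
        idx = range(n1 + n2)
        u1_null = []
        for comb in combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(comb)] = True
            u1_null.append(_u_statistics(pooled[sel], pooled[~sel])[0])
        u1_null = np.asarray(u1_null)
        lo = np.mean(u1_null <= u_min)
        hi = np.mean(u1_null >= n1 * n2 - u_min)
        p = lo if u1 <= u_min else hi
        if tails == "two":
            p = min(lo + hi, 1.0)
        return TestResult("mann_whitney_u", float(u_min), None, float(p), tails)
    # normal approximation with tie correction
    tie_counts = np.unique(pooled, return_counts=True)[1]
    n = n1 + n2
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    mu = n1 * n2 / 2.0
    z = (u1 - mu - np.sign(u1 - mu) * 0.5) / math.sqrt(sigma2)
    p_two = 2.0 * sps.norm.sf(abs(z))
    p = p_two if tails == "two" else _one_sided(p_two)
    return TestResult("mann_whitney_u", float(u_min), None, float(min(p, 1.0)), tails)


def normality_gate(*samples: GroupSample, alpha: float = 0.05) -> str:
    """Shapiro-Wilk screen: all groups must pass for the parametric route."""
    import warnings

    for s in samples:
        if s.n < 3:
            warnings.warn(f"{s.label}: n < 3, defaulting to parametric")
            continue
        vals = np.asarray(s.values, float)
        if np.all(vals == vals[0]):
            warnings.warn(f"{s.label}: constant sample")
            return "nonparametric"
        if sps.shapiro(vals).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def two_sample_test(a: GroupSample, b: GroupSample, tails: str = "two") -> TestResult:
    """Normality-gated comparison: pooled t if both groups pass, else Mann-Whitney."""
    if normality_gate(a, b) == "parametric":
        return pooled_t_test(a, b, tails)
    return mann_whitney_u(a, b, tails)


# ---------------------------------------------------------------------------
# split-plot ANOVA

def mixed_design_anova(data: pd.DataFrame,
                       dv: str = "value",
                       within: str = "time",
                       between: str = "group",
                       subject: str = "animal_id") -> dict[str, TestResult]:
    """Two-factor mixed ANOVA (between-subjects group x within-subjects time).

    Standard split-plot sum-of-squares decomposition with subjects nested in
    groups; F(group) is tested over MS(subjects within groups), F(time) and
    F(interaction) over the within-subjects residual.  No sphericity
    correction is applied (F reported with integer df).
    """
    df = data[[subject, between, within, dv]].copy()
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(f"missing or duplicated cell for {bad}")
    n_time = df[within].nunique()
    per_subj = df.groupby(subject, observed=True)[within].nunique()
    if (per_subj != n_time).any():
        missing = per_subj[per_subj != n_time].index[0]
        raise ValueError(f"incomplete within-subject measurements for {missing!r}")

    grand = df[dv].mean()
    y = df[dv].to_numpy(float)
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero variance")

    subj_mean = df.groupby(subject, observed=True)[dv].mean()
    subj_group = df.groupby(subject, observed=True)[between].first()
    group_mean = df.groupby(between, observed=True)[dv].mean()
    time_mean = df.groupby(within, observed=True)[dv].mean()
    cell_mean = df.groupby([between, within], observed=True)[dv].mean()

    n_subj = len(subj_mean)
    n_groups = df[between].nunique()
    subj_per_group = subj_group.value_counts()

    ss_between_subj = float(n_time * ((subj_mean - grand) ** 2).sum())
    ss_group = float(n_time * sum(
        subj_per_group[g] * (group_mean[g] - grand) ** 2 for g in group_mean.index
    ))
    ss_subj_within = ss_between_subj - ss_group

    ss_time = float(n_subj * ((time_mean - grand) ** 2).sum())
    ss_cells = float(sum(
        subj_per_group[g] * (cell_mean[(g, t)] - grand) ** 2
        for g, t in cell_mean.index
    ))
    ss_interaction = ss_cells - ss_group - ss_time
    ss_within = ss_total - ss_between_subj
    ss_error = ss_within - ss_time - ss_interaction

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_time = n_time - 1
    df_int = df_group * df_time
    df_err = df_subj * df_time

    def fres(name: str, ss: float, dfn: int, ms_err: float, dfe: int) -> TestResult:
        if ms_err <= 0:
            raise ValueError("zero variance in error term")
        f = (ss / dfn) / ms_err
        return TestResult(name, float(f), (dfn, dfe), float(sps.f.sf(f, dfn, dfe)))

    ms_subj = ss_subj_within / df_subj
    ms_err = ss_error / df_err
    out = {
        "group": fres("F_group", ss_group, df_group, ms_subj, df_subj),
        "time": fres("F_time", ss_time, df_time, ms_err, df_err),
        "interaction": fres("F_interaction", ss_interaction, df_int, ms_err, df_err),
    }
    # expose the decomposition for conservation checks
    out["_ss"] = {
        "total": ss_total, "between_subjects": ss_between_subj,
        "within_subjects": ss_within, "group": ss_group,
        "subjects_within_groups": ss_subj_within, "time": ss_time,
        "interaction": ss_interaction, "error": ss_error,
    }  # type: ignore[assignment]
    return out


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni: p * m, clipped at 1.  ``m`` defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    if m < p.size:
        raise ValueError("family size m smaller than number of p-values")
    return np.minimum(p * m, 1.0)


def behavior_anatomy_correlation(x: Sequence[float], y: Sequence[float],
                                 m_comparisons: int = 4,
                                 tails: str = "two") -> TestResult:
    """Pearson correlation with Bonferroni adjustment over a declared family.

    The family size defaults to the number of anatomical regions tested per
    behavioural metric (4).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a correlated variable")
    r, p = sps.pearsonr(x, y)
    if tails == "one":
        p = p / 2.0
    adj = float(min(p * m_comparisons, 1.0))
    return TestResult("pearson_r", float(r), x.size - 2, float(p), tails, adjusted_p=adj)
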