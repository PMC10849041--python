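"""Normality-gated test selection for group comparisons.

The reporting convention reproduced here: every metric is summarized as
mean ± SEM; before any two-group (or one-sample) comparison the data are
screened with the Shapiro–Wilk test, and the comparison then follows a fixed
decision tree —

* both groups normal, unpaired: F-test on variances → Student's t when the
  variances agree, Welch's t otherwise;
* both normal, paired: paired t;  one-sample: one-sample t;
* any group non-normal: Mann–Whitney U (unpaired), Wilcoxon signed-rank
  (paired), or one-sample Wilcoxon.

Levene's test is exposed for comparing variability between cell types (it is
robust to small, unequal samples).  All tests are two-tailed; the gate and
the comparisons share α = 0.05 by default.  The full decision trail
(normality p-values, variance-test p-value) is recorded in every result so a
reported test choice can be audited.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class Design(enum.Enum):
    UNPAIRED = "unpaired"
    PAIRED = "paired"
    ONE_SAMPLE = "one_sample"


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonSpec:
    design: Design
    null_value: float = 0.0  # ONE_SAMPLE only; 1 for ratios, 50 for percent-chance
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SummaryRecord:
    n: int
    mean: float
    sem: float | None  # None flags n == 1


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None
    group_summaries: list[SummaryRecord]
    decision_trail: dict[str, float] = field(default_factory=dict)


def summarize(values) -> SummaryRecord:
    """mean ± SEM with the n−1 (sample) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("summarize needs at least one value")
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else None
    return SummaryRecord(n=int(v.size), mean=float(v.mean()), sem=sem)


def f_test_variances(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test of equal variances (variance ratio test)."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateDataError("both groups have zero variance")
    if va >= vb:
        f, dfn, dfd = va / max(vb, np.finfo(float).tiny), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / max(va, np.finfo(float).tiny), len(b) - 1, len(a) - 1
    p = 2.0 * sps.f.sf(f, dfn, dfd)
    return float(f), float(min(p, 1.0))


def levene_test(a, b) -> tuple[float, float]:
    """Levene's test (median-centred) for between-cell-type variability."""
    stat, p = sps.levene(np.asarray(a, float), np.asarray(b, float), center="median")
    return float(stat), float(p)


def _require_variation(*groups) -> None:
    for g in groups:
        if np.asarray(g).std(ddof=1) == 0:
            raise DegenerateDataError("zero-variance group under a t-test")


def select_and_run(group_a, group_b, spec: ComparisonSpec) -> TestResult:
    """Run the normality-gated comparison for *spec* and record the trail."""
    a = np.asarray(group_a, dtype=float)
    trail: dict[str, float] = {}
    alpha = spec.alpha

    if spec.design is Design.ONE_SAMPLE:
        if group_b is not None:
            raise ValueError("one-sample design takes a single group")
        if a.size < 3:
            raise ValueError("need n >= 3 for normality testing")
        diffs = a - spec.null_value
        if a.std(ddof=1) == 0:
            raise DegenerateDataError("zero-variance sample")
        p_norm = float(sps.shapiro(a).pvalue)
        trail["shapiro_p"] = p_norm
        summaries = [summarize(a)]
        if p_norm >= alpha:
            _require_variation(a)
            res = sps.ttest_1samp(a, spec.null_value)
            return TestResult("one-sample t (two-tailed)", float(res.statistic), float(res.pvalue), float(a.size - 1), summaries, trail)
        if np.all(diffs == 0):
            raise DegenerateDataError("all values equal the null value")
        res = sps.wilcoxon(diffs)
        return TestResult("one-sample Wilcoxon signed-rank", float(res.statistic), float(res.pvalue), None, summaries, trail)

    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group for normality testing")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise DegenerateDataError("zero-variance group")
    pa = float(sps.shapiro(a).pvalue)
    pb = float(sps.shapiro(b).pvalue)
    trail["shapiro_p_a"] = pa
    trail["shapiro_p_b"] = pb
    normal = pa >= alpha and pb >= alpha
    summaries = [summarize(a), summarize(b)]

    if spec.design is Design.UNPAIRED:
        if normal:
            _require_variation(a, b)
            f_stat, f_p = f_test_variances(a, b)
            trail["f_test_p"] = f_p
            equal_var = f_p >= alpha
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            if equal_var:
                name, df = "Student t (two-tailed)", float(a.size + b.size - 2)
            else:
                name = "Welch t (two-tailed)"
                df = float(res.df)
            return TestResult(name, float(res.statistic), float(res.pvalue), df, summaries, trail)
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult("Mann-Whitney U", float(res.statistic), float(res.pvalue), None, summaries, trail)

    # paired
    if a.size != b.size:
        raise ValueError("paired design needs equal group sizes")
    if normal:
        _require_variation(a - b)
        res = sps.ttest_rel(a, b)
        return TestResult("paired t (two-tailed)", float(res.statistic), float(res.pvalue), float(a.size - 1), summaries, trail)
    d = a - b
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    res = sps.wilcoxon(a, b)
    return TestResult("Wilcoxon matched-pairs signed-rank", float(res.statistic), float(res.pvalue), None, summaries, trail)


def two_way_rm_anova(data, dv: str, within: str, subject: str):
    """Two-way repeated-measures ANOVA, delegated to statsmodels AnovaRM.

    Thin pass-through used once (input counts by cortical origin × subject);
    returns the fitted AnovaRM results object.
    """
    from statsmodels.stats.anova import AnovaRM

    return AnovaRM(data, depvar=dv, subject=subject, within=[within]).fit()
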