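"""Statistical layer: Welch tests, Games-Howell post hoc, boxplot summaries.

Group comparisons follow the conventions used throughout the package's
reporting: pairwise two-tailed Welch t-tests (unequal variances) for two
groups; one-way ANOVA followed by the Games-Howell multiple-comparison
test for three or more groups (robust to unequal variances and sample
sizes, p-values from the studentized-range distribution); significance
level p = 0.05 everywhere.  Boxplot summaries use type-7 quartiles,
McGill notches (±1.57 · IQR/√n around the median) and the 1.5×IQR
outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupSummary",
    "welch_ttest",
    "anova_games_howell",
    "box_summary",
]

ALPHA = 0.05


@dataclass
class TestResult:
    """One hypothesis-test outcome."""

    statistic: float
    df: float
    pvalue: float
    label: str = ""
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.pvalue < ALPHA)


@dataclass
class GroupSummary:
    """Notched-boxplot summary of one sample."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    notch: float            # half-width, 1.57 × IQR/√n
    outliers: np.ndarray    # values beyond 1.5×IQR from the box edges


def _welch_parts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return a.mean() - b.mean(), 0.0, float(na + nb - 2), 0.0
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return a.mean() - b.mean(), np.sqrt(se2), float(df), se2


def welch_ttest(a, b, label: str = "") -> TestResult:
    """Two-tailed Welch t-test (unequal variances).

    t = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b) with Welch–Satterthwaite
    degrees of freedom.  Two zero-variance samples with equal means give
    t = 0, p = 1 by convention (p = 0 if their means differ).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    diff, se, df, se2 = _welch_parts(a, b)
    if se == 0:
        if diff == 0:
            return TestResult(statistic=0.0, df=df, pvalue=1.0, label=label)
        return TestResult(statistic=np.sign(diff) * np.inf, df=df, pvalue=0.0, label=label)
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, pvalue=float(p), label=label)


def anova_games_howell(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus Games-Howell pairwise comparisons.

    For each pair (i, j) the Games-Howell statistic is
    q = |m_i − m_j| / √((s_i²/n_i + s_j²/n_j)/2) with a Welch-type
    per-pair df; the p-value comes from the studentized-range
    distribution with k = number of groups.  Pairs where both groups
    have zero variance are handled with limiting df (pooled) and p ∈
    {0, 1} depending on the mean difference.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use welch_ttest for 2)")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    k = len(groups)

    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        anova = TestResult(statistic=0.0, df=float(sum(map(len, groups)) - k), pvalue=1.0,
                           label="anova")
    else:
        f, p = sps.f_oneway(*groups)
        anova = TestResult(statistic=float(f), df=float(sum(map(len, groups)) - k),
                           pvalue=float(p), label="anova")

    results = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            pair = f"{labels[i]} vs {labels[j]}"
            diff, se, df, se2 = _welch_parts(a, b)
            if se2 == 0:
                pv = 1.0 if diff == 0 else 0.0
                q = 0.0 if diff == 0 else np.inf
                results.append(TestResult(statistic=q, df=df, pvalue=pv, label=pair))
                continue
            q = abs(diff) / np.sqrt(se2 / 2.0)
            pv = float(sps.studentized_range.sf(q, k, df))
            results.append(TestResult(statistic=float(q), df=df, pvalue=pv, label=pair))
    return anova, results


def box_summary(values, notch_constant: float = 1.57) -> GroupSummary:
    """Notched-boxplot summary with the 1.5×IQR outlier rule.

    Quartiles use linear interpolation of order statistics (type 7);
    the notch half-width is ``notch_constant × IQR/√n`` (McGill's 95%
    median-comparison convention); outliers are exactly the values more
    than 1.5×IQR beyond the box edges.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        notch=float(notch_constant * iqr / np.sqrt(x.size)),
        outliers=np.sort(x[(x < lo) | (x > hi)]),
    )
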