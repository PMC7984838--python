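"""Statistical tests used across the analyses.

All tests return a :class:`TestResult` and are deterministic given their
inputs (and a seed where resampling is involved).  Standard tests delegate
to scipy/statsmodels; the resampling median-difference test, used to guard
comparisons between groups of very different size, is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "TestResult",
    "welch_t",
    "resample_median_test",
    "two_way_anova",
    "correlation_difference",
    "rank_sum",
]


@dataclass
class TestResult:
    """Uniform container for a test statistic, p-value and effect size."""

    test_name: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    df: float | None = None
    n_per_group: tuple[int, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"invalid p-value {self.p_value}")


def welch_t(x, y) -> TestResult:
    """Welch's t-test (unequal n, unequal variance), two-sided.

    Effect size is ``d' = |mean_x - mean_y| / sqrt((s_x^2 + s_y^2) / 2)``
    with unpooled variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        if np.mean(x) == np.mean(y):
            return TestResult("welch_t", 0.0, 1.0, 0.0, n_per_group=(len(x), len(y)))
        raise ValueError("both samples are constant; Welch t undefined")
    res = sstats.ttest_ind(x, y, equal_var=False)
    d_prime = abs(np.mean(x) - np.mean(y)) / np.sqrt((vx + vy) / 2.0)
    return TestResult(
        "welch_t",
        float(res.statistic),
        float(res.pvalue),
        float(d_prime),
        df=float(res.df),
        n_per_group=(len(x), len(y)),
    )


def resample_median_test(
    x, y, n_iter: int = 1000, seed: int = 0, two_sided: bool = True
) -> TestResult:
    """Resampling test for a difference in medians between unequal-size groups.

    The null distribution is built by drawing ``n_iter`` resamples of size N
    (the smaller group's size) with replacement from the larger group and
    recording each resample median minus the larger group's median.  The
    observed statistic is the difference in medians between the two groups;
    the (default two-sided) p-value is the proportion of null differences at
    least as extreme, with a +1/(n_iter + 1) continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    if len(x) >= len(y):
        larger, smaller = x, y
    else:
        larger, smaller = y, x
    rng = np.random.default_rng(seed)
    draws = rng.choice(larger, size=(n_iter, len(smaller)), replace=True)
    null = np.median(draws, axis=1) - np.median(larger)
    observed = float(np.median(smaller) - np.median(larger))
    if two_sided:
        exceed = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        exceed = int(np.sum(null >= observed))
    p = (exceed + 1) / (n_iter + 1)
    return TestResult(
        "resample_median",
        observed,
        float(p),
        n_per_group=(len(x), len(y)),
        extra={"n_iter": n_iter, "two_sided": two_sided},
    )


def two_way_anova(values, factor_a, factor_b) -> dict[str, TestResult]:
    """Two-way fixed-effects ANOVA with interaction (Type II sums of squares).

    Returns results keyed ``"a"``, ``"b"`` and ``"interaction"``.  Type II SS
    handle the unbalanced group sizes typical of pooled recordings.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    )
    counts = df.groupby(["a", "b"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"empty factor cells: {list(empty.index)}")
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    model = ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    for key, row_name in (("a", "C(a)"), ("b", "C(b)"), ("interaction", "C(a):C(b)")):
        row = table.loc[row_name]
        out[key] = TestResult(
            "two_way_anova",
            float(row["F"]),
            float(row["PR(>F)"]),
            df=float(row["df"]),
        )
    return out


def correlation_difference(
    r1: float, n1: int, r2: float, n2: int, two_sided: bool = True
) -> TestResult:
    """Compare two independent Pearson correlations via Fisher's z.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"n must exceed 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = sstats.norm.sf(abs(z))
    if two_sided:
        p *= 2.0
    return TestResult("correlation_difference", float(z), float(p), n_per_group=(n1, n2))


def rank_sum(x, y) -> TestResult:
    """Wilcoxon rank-sum test (two-sided), via scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sstats.ranksums(x, y)
    return TestResult(
        "rank_sum", float(res.statistic), float(res.pvalue), n_per_group=(len(x), len(y))
    )
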