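"""Statistical layer: relative values, Pearson correlation, one-way ANOVA
with Fisher's LSD post-hoc comparisons.

Conventions: significance level alpha defaults to 0.05, with star labels at
p < 0.05 (*), < 0.01 (**), < 0.001 (***), < 0.0001 (****). Fisher's LSD is
implemented unprotected by default — all pairwise t-tests using the pooled
within-group mean square and residual degrees of freedom are reported
regardless of the omnibus F — with a ``protected=True`` switch that gates
the pairwise tests on omnibus significance. No further multiple-testing
correction is applied (that is what LSD means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CohortSummary",
    "PairwiseComparison",
    "StatResult",
    "relative_values",
    "pearson",
    "anova_lsd",
    "significance_stars",
    "summarize_cohort",
]

DEFAULT_ALPHA = 0.05

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p_value: float) -> str:
    """Star label for a p-value: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for cutoff, stars in _STAR_LEVELS:
        if p_value < cutoff:
            return stars
    return "ns"


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive summary of one group's values."""

    label: str
    n: int
    mean: float
    median: float
    lower_quartile: float
    upper_quartile: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    t_statistic: float
    p_value: float
    stars: str


@dataclass(frozen=True)
class StatResult:
    """Result of a statistical test.

    ``statistic`` is F for ANOVA or r for Pearson; ``pairwise`` lists every
    group pair for ANOVA+LSD. ``extra`` carries test-specific values
    (regression slope/intercept for Pearson; sums of squares for ANOVA).
    """

    test: str
    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA
    pairwise: tuple[PairwiseComparison, ...] = ()
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def summarize_cohort(label: str, values) -> CohortSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError(f"cohort {label!r} has no finite values")
    lq, med, uq = np.percentile(v, [25, 50, 75])
    return CohortSummary(
        label=label,
        n=int(v.size),
        mean=float(v.mean()),
        median=float(med),
        lower_quartile=float(lq),
        upper_quartile=float(uq),
    )


def relative_values(means) -> np.ndarray:
    """Divide each value by the maximum, so the largest maps to 1.0.

    Used to express per-tissue mean fluorescence or DTA relative to the
    brightest tissue in the set.

    Raises
    ------
    ValueError
        If no value is positive (relative scale undefined).
    """
    v = np.asarray(means, dtype=float)
    if v.size == 0 or np.nanmax(v) <= 0:
        raise ValueError("relative values need at least one positive value")
    if np.any(v < 0):
        raise ValueError("relative values are defined for nonnegative inputs")
    return v / np.nanmax(v)


def pearson(x, y, alpha: float = DEFAULT_ALPHA) -> StatResult:
    """Pearson correlation with two-sided p from the t distribution (n-2 df).

    Also fits the least-squares trend line (slope, intercept) for scatter
    export, reported in ``extra``.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, or a constant input.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1D and the same length")
    if xa.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = _sps.pearsonr(xa, ya)
    line = _sps.linregress(xa, ya)
    return StatResult(
        test="pearson",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        extra={"n": int(xa.size), "slope": float(line.slope), "intercept": float(line.intercept)},
    )


def anova_lsd(
    groups: dict[str, "np.ndarray | list"],
    alpha: float = DEFAULT_ALPHA,
    protected: bool = False,
) -> StatResult:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    The omnibus F is computed from the between/within sums-of-squares
    decomposition; each pair (i, j) is then tested with
    ``t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j))`` on the pooled
    residual degrees of freedom. With ``protected=True`` the pairwise tests
    are only reported when the omnibus test is significant at ``alpha``.

    Raises
    ------
    ValueError
        With fewer than 2 groups or any group with fewer than 2 values.
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(data) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g, v in zip(labels, data):
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")

    k = len(data)
    ns = np.array([v.size for v in data])
    n_total = int(ns.sum())
    grand = np.concatenate(data).mean()
    means = np.array([v.mean() for v in data])

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((v - m) ** 2).sum() for v, m in zip(data, means)))
    ss_total = float(((np.concatenate(data) - grand) ** 2).sum())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_within

    if mse == 0.0:
        # all groups internally constant; F is 0 when means agree, else infinite
        f_stat = 0.0 if ss_between == 0 else float("inf")
        p_value = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = ms_between / mse
        p_value = float(_sps.f.sf(f_stat, df_between, df_within))

    pairwise: list[PairwiseComparison] = []
    if not protected or p_value < alpha:
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(means[i] - means[j])
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                if se == 0.0:
                    t_stat = 0.0 if diff == 0 else float("inf") * np.sign(diff)
                    p = 1.0 if diff == 0 else 0.0
                else:
                    t_stat = diff / se
                    p = float(2.0 * _sps.t.sf(abs(t_stat), df_within))
                pairwise.append(
                    PairwiseComparison(
                        group_a=labels[i],
                        group_b=labels[j],
                        mean_difference=diff,
                        t_statistic=float(t_stat),
                        p_value=p,
                        stars=significance_stars(p),
                    )
                )

    return StatResult(
        test="anova_lsd",
        statistic=float(f_stat),
        p_value=p_value,
        alpha=alpha,
        pairwise=tuple(pairwise),
        extra={
            "ss_between": ss_between,
            "ss_within": ss_within,
            "ss_total": ss_total,
            "df_between": df_between,
            "df_within": df_within,
            "mse": mse,
            "group_means": {g: float(m) for g, m in zip(labels, means)},
            "group_ns": {g: int(n) for g, n in zip(labels, ns)},
        },
    )
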