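"""Reliability and descriptive psychometrics: McDonald's omega, Cronbach's
alpha, item-total correlations, skewness, and the group-comparison statistics
used in scale validation (pooled t with Cohen's d, one-way ANOVA with
eta-squared and Scheffe post hoc — from raw data or summary statistics —
Pearson chi-square association, product-moment correlation)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "GroupComparisonResult",
    "DescriptiveResult",
    "omega_from_loadings",
    "cronbach_alpha",
    "item_total_correlations",
    "skewness_with_se",
    "describe",
    "two_group_t",
    "two_group_t_from_stats",
    "oneway_anova",
    "oneway_anova_from_stats",
    "chi_square_association",
    "pearson_r",
]


@dataclass(frozen=True)
class ReliabilityResult:
    omega: Optional[float]
    alpha: Optional[float]
    item_total: Optional[np.ndarray] = None


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    df: tuple
    p: float
    effect_size: Optional[float] = None
    effect_name: Optional[str] = None
    posthoc: Optional[list] = None    # (group_i, group_j, significant) triples


@dataclass(frozen=True)
class DescriptiveResult:
    n: int
    mean: float
    sd: float
    skewness: float
    skewness_se: float
    min: float
    max: float


def omega_from_loadings(loadings: Sequence[float]) -> float:
    """McDonald's omega from standardized loadings:
    omega = (sum lambda)^2 / [(sum lambda)^2 + sum(1 - lambda^2)]."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("loadings vector is empty")
    if np.any(np.abs(lam) >= 1):
        raise ValueError("standardized loadings must satisfy |lambda| < 1")
    s = lam.sum() ** 2
    return float(s / (s + np.sum(1.0 - lam**2)))


def cronbach_alpha(data) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total))."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("data must be respondents x items with >= 2 items")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var))


def item_total_correlations(data) -> dict[str, np.ndarray]:
    """Per-item Pearson correlations with the scale total.

    Returns both variants: ``"total"`` (item vs sum including the item, the
    magnitudes conventionally tabulated) and ``"rest"`` (item vs sum of the
    remaining items, the corrected form).  Zero-variance items yield NaN.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 2 items and >= 3 respondents")
    total = x.sum(axis=1)
    k = x.shape[1]
    r_total = np.full(k, np.nan)
    r_rest = np.full(k, np.nan)
    for j in range(k):
        if x[:, j].std(ddof=1) == 0:
            continue
        r_total[j] = stats.pearsonr(x[:, j], total)[0]
        rest = total - x[:, j]
        if rest.std(ddof=1) > 0:
            r_rest[j] = stats.pearsonr(x[:, j], rest)[0]
    return {"total": r_total, "rest": r_rest}


def skewness_with_se(values) -> tuple[float, float]:
    """Adjusted Fisher-Pearson sample skewness with its exact standard error
    se = sqrt(6n(n-1) / ((n-2)(n+1)(n+3)))."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("skewness requires n >= 3")
    if np.std(x) == 0:
        raise ValueError("skewness undefined for a constant vector")
    s = float(stats.skew(x, bias=False))
    se = float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))
    return s, se


def describe(values) -> DescriptiveResult:
    x = np.asarray(values, dtype=float)
    s, se = skewness_with_se(x)
    return DescriptiveResult(
        n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)),
        skewness=s, skewness_se=se, min=float(x.min()), max=float(x.max()),
    )


def _cohens_d(m1, m2, s1, s2, n1, n2) -> float:
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float(abs(m1 - m2) / sp)


def two_group_t(values, groups) -> GroupComparisonResult:
    """Student t-test (pooled variance, df = n1 + n2 - 2) with Cohen's d."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups are required")
    g1, g2 = (values[groups == lab] for lab in labels)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(g1, g2, equal_var=True)
    d = _cohens_d(g1.mean(), g2.mean(), g1.std(ddof=1), g2.std(ddof=1),
                  g1.size, g2.size)
    return GroupComparisonResult(
        statistic=float(t), df=(g1.size + g2.size - 2,), p=float(p),
        effect_size=d, effect_name="cohens_d",
    )


def two_group_t_from_stats(n1, m1, s1, n2, m2, s2) -> GroupComparisonResult:
    """Pooled t-test reconstructed from per-group (n, mean, sd)."""
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return GroupComparisonResult(
        statistic=float(t), df=(n1 + n2 - 2,), p=float(p),
        effect_size=_cohens_d(m1, m2, s1, s2, n1, n2), effect_name="cohens_d",
    )


def _scheffe(means, ns, mse, dfw, k, alpha=0.05) -> list:
    crit = (k - 1) * stats.f.ppf(1 - alpha, k - 1, dfw)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0:
                out.append((i, j, bool(means[i] != means[j])))
                continue
            f_pair = (means[i] - means[j]) ** 2 / (mse * (1 / ns[i] + 1 / ns[j]))
            out.append((i, j, bool(f_pair > crit)))
    return out


def oneway_anova(values, groups, alpha: float = 0.05) -> GroupComparisonResult:
    """One-way ANOVA on raw data with eta-squared and Scheffe post hoc."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == lab] for lab in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    triples = [(s.size, s.mean(), s.std(ddof=1)) for s in samples]
    return oneway_anova_from_stats(triples, alpha=alpha)


def oneway_anova_from_stats(
    groups: Sequence[tuple[float, float, float]], alpha: float = 0.05
) -> GroupComparisonResult:
    """One-way ANOVA reconstructed exactly from per-group (n, mean, sd).

    SSB = sum n_g (m_g - grand)^2 and SSW = sum (n_g - 1) s_g^2 recover the
    raw-data decomposition identically, so published group summaries suffice.
    """
    groups = list(groups)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb, dfw = k - 1, int(n_total) - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0:   # degenerate: no within-group variation
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = msb / msw
    eta2 = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return GroupComparisonResult(
        statistic=float(f), df=(dfb, dfw), p=float(stats.f.sf(f, dfb, dfw)),
        effect_size=float(eta2), effect_name="eta_squared",
        posthoc=_scheffe(means, ns, msw, dfw, k, alpha),
    )


def chi_square_association(table) -> GroupComparisonResult:
    """Pearson chi-square test of association (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return GroupComparisonResult(statistic=float(chi2), df=(int(df),), p=float(p))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("correlation undefined with a zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
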