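"""Population-genetic and cohort statistics.

Risk-allele frequencies with Wilson score intervals, Pearson chi-square
tests of Hardy-Weinberg equilibrium, two-sample proportion tests for
cross-population allele-frequency comparison, Welch t and chi-square group
comparisons, quintile-of-score logistic trend analysis, and the
normal-approximation sample size for comparing two means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AlleleFrequencyEstimate",
    "HweResult",
    "QuintileTrendResult",
    "PowerSpec",
    "allele_frequency",
    "hwe_test",
    "compare_proportions",
    "welch_t_test",
    "welch_t_test_from_stats",
    "chi2_test",
    "quintile_assign",
    "quintile_trend",
    "sample_size_two_means",
    "round_to_ten",
]


@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    rsid: str
    n_individuals: int
    raf: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class HweResult:
    rsid: str
    n_hom_risk: int
    n_het: int
    n_hom_other: int
    chi2: float
    p: float
    in_hwe: bool


@dataclass(frozen=True)
class QuintileTrendResult:
    """Odds ratios per score quintile versus the bottom quintile."""

    odds_ratios: tuple[float, ...]          # length 5, first is 1 (reference)
    ci95: tuple[tuple[float, float], ...]   # per-quintile 95% CIs
    trend_p: float
    n_per_quintile: tuple[int, ...]


@dataclass(frozen=True)
class PowerSpec:
    delta: float
    sd1: float
    sd2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("delta must be non-zero")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        for name in ("alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def allele_frequency(dosages, rsid: str = "") -> AlleleFrequencyEstimate:
    """Risk-allele frequency with a Wilson score 95% CI on 2n allele trials."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError(f"{rsid or 'site'}: no non-missing dosages")
    n = len(d)
    count = d.sum()
    raf = count / (2 * n)
    lo, hi = proportion_confint(count, 2 * n, alpha=0.05, method="wilson")
    return AlleleFrequencyEstimate(rsid=rsid, n_individuals=n, raf=raf,
                                   ci95=(float(lo), float(hi)))


def hwe_test(n_hom_risk: int, n_het: int, n_hom_other: int,
             rsid: str = "", alpha: float = 0.05) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg genotype proportions.

    Expected counts are ``n p^2, 2 n p q, n q^2`` with ``p`` estimated from
    the observed allele counts.  A monomorphic site is reported as exactly
    in equilibrium (chi2 0, p 1), not as an error.
    """
    obs = np.array([n_hom_risk, n_het, n_hom_other], dtype=float)
    if (obs < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise ValueError(f"{rsid or 'site'}: no genotypes")
    p = (2 * n_hom_risk + n_het) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if p == 0.0 or q == 0.0:
        chi2, pval = 0.0, 1.0
    else:
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(rsid=rsid, n_hom_risk=n_hom_risk, n_het=n_het,
                     n_hom_other=n_hom_other, chi2=chi2, p=pval,
                     in_hwe=pval >= alpha)


def compare_proportions(raf1: float, n_alleles1: int,
                        raf2: float, n_alleles2: int) -> tuple[float, float]:
    """Two-sample pooled-variance z-test of proportions (two-sided).

    ``z**2`` equals the 1-df Pearson chi-square on the corresponding 2x2
    allele table.  Degenerate tables (both proportions 0 or both 1) give
    ``(0, 1)``.
    """
    if n_alleles1 <= 0 or n_alleles2 <= 0:
        raise ValueError("allele counts must be positive")
    x1, x2 = raf1 * n_alleles1, raf2 * n_alleles2
    pooled = (x1 + x2) / (n_alleles1 + n_alleles2)
    var = pooled * (1 - pooled) * (1 / n_alleles1 + 1 / n_alleles2)
    if var == 0.0:
        return 0.0, 1.0
    z = (raf1 - raf2) / math.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def welch_t_test(group1, group2) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_test_from_stats(mean1: float, sd1: float, n1: int,
                            mean2: float, sd2: float, n2: int
                            ) -> tuple[float, float, float]:
    """Welch's t-test from published group summaries (mean, SD, n)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi2_test(table) -> tuple[float, float]:
    """Pearson chi-square on a 2xk contingency table, no continuity
    correction."""
    tab = np.asarray(table, dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def quintile_assign(scores) -> np.ndarray:
    """Quintile index 0..4 from the empirical distribution of ``scores``.

    Boundaries are the 20/40/60/80 percentiles of the pooled analysis
    sample; a score exactly on a boundary stays in the lower quintile.
    """
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores must be complete (no NaN)")
    if len(np.unique(s)) < 5:
        raise ValueError("need at least 5 distinct score values")
    bounds = np.quantile(s, [0.2, 0.4, 0.6, 0.8])
    # strictly-greater comparison sends boundary ties to the lower quintile
    q = (s[:, None] > bounds[None, :]).sum(axis=1)
    for k in range(5):
        if not np.any(q == k):
            raise ValueError(f"quintile {k + 1} is empty after tie handling")
    return q


def quintile_trend(scores, outcome, age, sex=None) -> QuintileTrendResult:
    """Logistic regression of outcome on score quintile, covariate adjusted.

    Per-quintile odds ratios (bottom quintile reference) come from a model
    with quintile indicator terms plus age (and sex when given); the trend
    p-value comes from a second model with quintile entered as a single
    ordinal 0..4 term.
    """
    y = np.asarray(outcome, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    q = quintile_assign(scores)
    covs = [np.asarray(age, dtype=float)]
    if sex is not None:
        sx = np.asarray(sex)
        covs.append((sx == "female").astype(float) if sx.dtype.kind in "OUS"
                    else sx.astype(float))
    cov_mat = np.column_stack(covs)
    indicators = np.column_stack([(q == k).astype(float) for k in range(1, 5)])
    X = sm.add_constant(np.column_stack([indicators, cov_mat]))
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-8)
    ors = [1.0] + [float(np.exp(b)) for b in fit.params[1:5]]
    ci = fit.conf_int()
    cis = [(1.0, 1.0)] + [(float(np.exp(ci[i][0])), float(np.exp(ci[i][1])))
                          for i in range(1, 5)]
    X_tr = sm.add_constant(np.column_stack([q.astype(float), cov_mat]))
    fit_tr = sm.Logit(y, X_tr).fit(disp=0, maxiter=200, tol=1e-8)
    trend_p = float(fit_tr.pvalues[1])
    n_per = tuple(int(np.sum(q == k)) for k in range(5))
    return QuintileTrendResult(odds_ratios=tuple(ors), ci95=tuple(cis),
                               trend_p=trend_p, n_per_quintile=n_per)


def sample_size_two_means(spec: PowerSpec) -> int:
    """Per-group n to detect a mean difference between two normal groups.

    Normal-approximation formula ``n = 2 (z_{1-a/2} + z_power)^2 sigma^2 /
    delta^2`` with ``sigma^2 = (sd1^2 + sd2^2)/2``, rounded up.
    """
    z = stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.power)
    sigma2 = (spec.sd1 ** 2 + spec.sd2 ** 2) / 2
    return int(math.ceil(2 * z * z * sigma2 / spec.delta ** 2))


def round_to_ten(n: int) -> int:
    """Report helper: nearest ten (half away from zero)."""
    return int(math.floor(n / 10 + 0.5) * 10)
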