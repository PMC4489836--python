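"""Clinical utility of adding the gene score to a conventional risk score.

Covers the reclassification analysis: logistic recalibration of the
Framingham risk with the gene score, ordinal risk categories at 10%/20%
cutpoints, the cross-classification table, the categorical net
reclassification improvement (NRI) with its normal-theory confidence
interval, the up-classified-only two-proportion test, and the DeLong
comparison of correlated ROC areas.

NRI conventions
---------------
For events (cases) an upward move is correct; for non-events a downward
move is correct:

    NRI = (up_e - down_e)/n_e  -  (up_ne - down_ne)/n_ne

with the binomial-variance standard error

    se^2 = [ (up_e+down_e)/n_e - ((up_e-down_e)/n_e)^2 ] / n_e
         + [ (up_ne+down_ne)/n_ne - ((up_ne-down_ne)/n_ne)^2 ] / n_ne

a 95% CI of ``nri +/- 1.96 se`` and a two-sided normal p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskThresholds",
    "ReclassificationResult",
    "UpclassifiedResult",
    "DegenerateFitError",
    "combine_risk",
    "classify_risk",
    "reclassification_table",
    "nri",
    "upclassified_analysis",
    "auc",
    "auc_compare",
]

_Z975 = 1.959963984540054


class DegenerateFitError(RuntimeError):
    """Raised when the recalibration logistic fit is not identifiable
    (zero-variance predictor or complete separation)."""


@dataclass(frozen=True)
class RiskThresholds:
    """Strictly increasing probability cutpoints; k cutpoints define k+1
    ordinal categories.  The boundary belongs to the higher category
    (a 10% risk is 'high' under a 10% cut-off)."""

    cutpoints: tuple[float, ...] = (0.10,)

    def __post_init__(self) -> None:
        cps = self.cutpoints
        if not cps:
            raise ValueError("at least one cutpoint required")
        if any(not 0.0 < c < 1.0 for c in cps):
            raise ValueError("cutpoints must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("cutpoints must be strictly increasing")


@dataclass(frozen=True)
class ReclassificationResult:
    """Cross-classification counts per outcome stratum plus NRI statistics."""

    up_event: int
    down_event: int
    unchanged_event: int
    up_nonevent: int
    down_nonevent: int
    unchanged_nonevent: int
    n_event: int
    n_nonevent: int
    nri: float | None = None
    se_nri: float | None = None
    ci95: tuple[float, float] | None = None
    z: float | None = None
    p_two_sided: float | None = None


@dataclass(frozen=True)
class UpclassifiedResult:
    """Two-proportion comparison of event rates: up-classified individuals
    versus those whose category did not change."""

    n_up: int
    events_up: int
    proportion_up: float | None
    n_reference: int
    events_reference: int
    proportion_reference: float | None
    z: float | None
    p_two_sided: float | None


def combine_risk(framingham_risk10: pd.Series, gene_score: pd.Series,
                 outcome: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Update conventional risk with the gene score by logistic recalibration.

    Fits ``outcome ~ a + b * logit(framingham) + c * gene_score`` by maximum
    likelihood on the analysis cohort and returns the per-individual updated
    probabilities together with the fitted ``(a, b, c)``.  The identity
    configuration ``(0, 1, 0)`` reproduces the Framingham risk exactly, so
    the combined model nests the conventional one.
    """
    df = pd.DataFrame({
        "risk": framingham_risk10, "gs": gene_score, "y": outcome,
    }).dropna()
    if len(df) == 0:
        raise ValueError("no complete cases to fit on")
    risk = df["risk"].to_numpy(float)
    if ((risk <= 0) | (risk >= 1)).any():
        raise ValueError("framingham risks must lie strictly inside (0, 1) "
                         "for the logit transform")
    X = np.column_stack([np.log(risk / (1 - risk)), df["gs"].to_numpy(float)])
    if np.any(np.ptp(X, axis=0) == 0.0):
        raise DegenerateFitError("zero-variance predictor in recalibration fit")
    try:
        fit = sm.Logit(df["y"].to_numpy(float), sm.add_constant(X)).fit(
            disp=0, maxiter=200)
    except Exception as err:  # statsmodels raises on perfect separation
        raise DegenerateFitError(f"recalibration fit failed: {err}") from err
    if not np.all(np.isfinite(fit.params)) or not fit.mle_retvals["converged"]:
        raise DegenerateFitError("recalibration fit did not converge")
    eta = fit.params[0] + X @ fit.params[1:]
    updated = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=df.index,
                        name="updated_risk")
    return updated.reindex(framingham_risk10.index), fit.params


def classify_risk(risk, thresholds: RiskThresholds = RiskThresholds()
                  ) -> np.ndarray:
    """Ordinal category = number of cutpoints <= risk (boundary goes up)."""
    r = np.atleast_1d(np.asarray(risk, dtype=float))
    if np.nanmin(r) < 0 or np.nanmax(r) > 1:
        raise ValueError("risks must lie in [0, 1]")
    cps = np.asarray(thresholds.cutpoints)
    cat = np.searchsorted(cps, r, side="right").astype(float)
    # a risk exactly on a cutpoint belongs to the higher category
    cat = np.where(np.isnan(r), np.nan, cat)
    return cat if np.ndim(risk) else cat.item()


def reclassification_table(old_cat, new_cat, outcome) -> ReclassificationResult:
    """Count upward/downward/unchanged category moves per outcome stratum."""
    old = np.asarray(old_cat, dtype=float)
    new = np.asarray(new_cat, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("old_cat, new_cat and outcome must have equal length")
    keep = ~(np.isnan(old) | np.isnan(new) | np.isnan(y))
    old, new, y = old[keep], new[keep], y[keep]
    ev, ne = y == 1, y == 0

    def counts(mask):
        return (int(np.sum((new > old) & mask)),
                int(np.sum((new < old) & mask)),
                int(np.sum((new == old) & mask)))

    up_e, down_e, same_e = counts(ev)
    up_n, down_n, same_n = counts(ne)
    return ReclassificationResult(
        up_event=up_e, down_event=down_e, unchanged_event=same_e,
        up_nonevent=up_n, down_nonevent=down_n, unchanged_nonevent=same_n,
        n_event=int(ev.sum()), n_nonevent=int(ne.sum()),
    )


def nri(counts: ReclassificationResult) -> ReclassificationResult:
    """Complete a count table with the NRI, its SE, 95% CI, z and p."""
    n_e, n_ne = counts.n_event, counts.n_nonevent
    if n_e <= 0 or n_ne <= 0:
        raise ValueError("both outcome strata must be non-empty")
    net_e = (counts.up_event - counts.down_event) / n_e
    net_ne = (counts.up_nonevent - counts.down_nonevent) / n_ne
    value = net_e - net_ne
    var = (((counts.up_event + counts.down_event) / n_e - net_e ** 2) / n_e
           + ((counts.up_nonevent + counts.down_nonevent) / n_ne
              - net_ne ** 2) / n_ne)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        # no sampling variability (e.g. nobody reclassified): z/p undefined
        return ReclassificationResult(
            **{f: getattr(counts, f) for f in (
                "up_event", "down_event", "unchanged_event", "up_nonevent",
                "down_nonevent", "unchanged_nonevent", "n_event",
                "n_nonevent")},
            nri=value, se_nri=0.0, ci95=(value, value), z=None,
            p_two_sided=None)
    z = value / se
    return ReclassificationResult(
        **{f: getattr(counts, f) for f in (
            "up_event", "down_event", "unchanged_event", "up_nonevent",
            "down_nonevent", "unchanged_nonevent", "n_event", "n_nonevent")},
        nri=value, se_nri=se,
        ci95=(value - _Z975 * se, value + _Z975 * se),
        z=z, p_two_sided=2.0 * stats.norm.sf(abs(z)))


def upclassified_analysis(old_cat, new_cat, outcome) -> UpclassifiedResult:
    """Event rate among up-classified individuals versus the non-reclassified.

    The construction behind the published per-direction test is not uniquely
    determined; this operation's documented choice is a pooled two-proportion
    z-test of the event rate in the up-classified group against the event
    rate among individuals whose category did not change.
    """
    old = np.asarray(old_cat, dtype=float)
    new = np.asarray(new_cat, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(old) | np.isnan(new) | np.isnan(y))
    old, new, y = old[keep], new[keep], y[keep]
    up = new > old
    same = new == old
    n_up, n_ref = int(up.sum()), int(same.sum())
    e_up, e_ref = int(y[up].sum()), int(y[same].sum())
    if n_up == 0:
        return UpclassifiedResult(0, 0, None, n_ref, e_ref,
                                  e_ref / n_ref if n_ref else None, None, None)
    p_up, p_ref = e_up / n_up, (e_ref / n_ref if n_ref else float("nan"))
    if n_ref == 0:
        return UpclassifiedResult(n_up, e_up, p_up, 0, 0, None, None, None)
    pooled = (e_up + e_ref) / (n_up + n_ref)
    denom = pooled * (1 - pooled) * (1 / n_up + 1 / n_ref)
    if denom == 0.0:
        return UpclassifiedResult(n_up, e_up, p_up, n_ref, e_ref, p_ref,
                                  0.0, 1.0)
    z = (p_up - p_ref) / math.sqrt(denom)
    return UpclassifiedResult(n_up, e_up, p_up, n_ref, e_ref, p_ref,
                              z, 2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# ROC area and the DeLong comparison of paired AUCs


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc(scores, outcome) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    ranks = _midrank(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg))


def _delong_components(scores: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Structural components (placement values) of one score's AUC."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
    a = auc(scores, y)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # V10 components
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # V01 components
    return a, v_pos, v_neg


def auc_compare(scores_a, scores_b, outcome
                ) -> tuple[float, float, float, float]:
    """Compare two paired ROC areas on the same individuals (DeLong).

    Returns ``(auc_a, auc_b, delta, p)`` where ``delta = auc_a - auc_b`` and
    ``p`` is the two-sided normal p-value from the DeLong covariance of the
    paired empirical AUCs.  Identical score vectors give delta 0, p 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("score vectors and outcome must have equal length")
    auc_a, va_pos, va_neg = _delong_components(sa, y)
    auc_b, vb_pos, vb_neg = _delong_components(sb, y)
    m, n = len(va_pos), len(va_neg)
    s_pos = np.cov(np.stack([va_pos, vb_pos]), ddof=1) if m > 1 else np.zeros((2, 2))
    s_neg = np.cov(np.stack([va_neg, vb_neg]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s_pos / m + s_neg / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(delta) / math.sqrt(var_delta))
    return float(auc_a), float(auc_b), float(delta), float(p)
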