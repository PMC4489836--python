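import numpy as np
import pytest
from scipy import stats as sps

import grs
from grs.clinical import (
    DegenerateFitError,
    ReclassificationResult,
    RiskThresholds,
    auc,
    auc_compare,
    classify_risk,
    combine_risk,
    nri,
    reclassification_table,
    upclassified_analysis,
)

# Published reclassification counts for the two panels (per outcome stratum:
# up, down, stratum n) and the printed NRI summaries they reproduce.
TABLE_19 = dict(up_e=11, down_e=9, n_e=114, up_ne=103, down_ne=132, n_ne=1050)
TABLE_13 = dict(up_e=13, down_e=12, n_e=143, up_ne=115, down_ne=145, n_ne=1294)


def _counts(up_e, down_e, n_e, up_ne, down_ne, n_ne):
    return ReclassificationResult(
        up_event=up_e, down_event=down_e,
        unchanged_event=n_e - up_e - down_e,
        up_nonevent=up_ne, down_nonevent=down_ne,
        unchanged_nonevent=n_ne - up_ne - down_ne,
        n_event=n_e, n_nonevent=n_ne)


@pytest.mark.parametrize(
    "table, pct, ci_pct, p",
    [
        (TABLE_19, 4.5, (-3.7, 12.7), 0.28),
        (TABLE_13, 3.0, (-4.3, 10.3), 0.42),
    ],
)
def test_nri_reproduces_published_values(table, pct, ci_pct, p):
    res = nri(_counts(**table))
    assert round(100 * res.nri, 1) == pct
    assert round(100 * res.ci95[0], 1) == ci_pct[0]
    assert round(100 * res.ci95[1], 1) == ci_pct[1]
    assert round(res.p_two_sided, 2) == p
    assert -2.0 <= res.nri <= 2.0


def test_nri_ci_symmetric_about_estimate():
    res = nri(_counts(**TABLE_19))
    lo, hi = res.ci95
    assert hi - res.nri == pytest.approx(res.nri - lo)
    assert hi - lo == pytest.approx(2 * 1.959963984540054 * res.se_nri)


def test_nri_scale_invariance():
    """Scaling all counts by k leaves the NRI fixed and shrinks its SE by
    sqrt(k)."""
    base = nri(_counts(**TABLE_19))
    k = 4
    scaled = nri(_counts(*(k * v for v in (11, 9, 114, 103, 132, 1050))))
    assert scaled.nri == pytest.approx(base.nri)
    assert scaled.se_nri == pytest.approx(base.se_nri / np.sqrt(k))


def test_nri_z_and_ci_are_consistent_on_random_tables(rng):
    """p < 0.05 exactly when 0 falls outside the 95% CI, over 1000 random
    count tables."""
    for _ in range(1000):
        n_e, n_ne = rng.integers(20, 400, size=2)
        up_e = rng.integers(0, n_e // 2 + 1)
        down_e = rng.integers(0, n_e - up_e + 1)
        up_ne = rng.integers(0, n_ne // 2 + 1)
        down_ne = rng.integers(0, n_ne - up_ne + 1)
        res = nri(_counts(int(up_e), int(down_e), int(n_e),
                          int(up_ne), int(down_ne), int(n_ne)))
        if res.se_nri == 0:
            assert res.p_two_sided is None
            continue
        outside = not (res.ci95[0] <= 0.0 <= res.ci95[1])
        assert (res.p_two_sided < 0.05) == outside
        assert res.ci95[0] <= res.nri <= res.ci95[1]


def test_nri_maximal_case_has_zero_se():
    res = nri(_counts(10, 0, 10, 0, 20, 20))
    assert res.nri == pytest.approx(2.0)
    assert res.se_nri == 0.0
    assert res.z is None and res.p_two_sided is None


def test_classify_risk_boundaries():
    cuts10 = RiskThresholds((0.10,))
    assert classify_risk(0.14, cuts10) == 1            # high
    assert classify_risk(0.10, cuts10) == 1            # boundary goes up
    assert classify_risk(0.099, RiskThresholds((0.10, 0.20))) == 0
    cats = classify_risk([0.05, 0.10, 0.15, 0.20, 0.95],
                         RiskThresholds((0.10, 0.20)))
    assert list(cats) == [0, 1, 1, 2, 2]
    # monotone: sorted risks map to sorted categories
    r = np.sort(np.random.default_rng(1).random(100))
    assert (np.diff(classify_risk(r, cuts10)) >= 0).all()


def test_threshold_validation():
    with pytest.raises(ValueError):
        RiskThresholds((0.2, 0.1))
    with pytest.raises(ValueError):
        RiskThresholds((0.0,))


def test_reclassification_table_counts_and_antisymmetry(rng):
    old = rng.integers(0, 3, size=500)
    new = rng.integers(0, 3, size=500)
    y = rng.integers(0, 2, size=500)
    t = reclassification_table(old, new, y)
    assert t.up_event + t.down_event + t.unchanged_event == t.n_event
    assert (t.up_nonevent + t.down_nonevent + t.unchanged_nonevent
            == t.n_nonevent)
    swapped = reclassification_table(new, old, y)
    assert (swapped.up_event, swapped.down_event) == (t.down_event, t.up_event)
    assert (swapped.up_nonevent, swapped.down_nonevent) == \
        (t.down_nonevent, t.up_nonevent)
    same = reclassification_table(old, old, y)
    assert same.up_event == same.down_event == 0
    assert same.up_nonevent == same.down_nonevent == 0


def test_reclassification_reproduces_published_table_from_categories():
    """A constructed category assignment with the published move counts
    yields exactly the published per-stratum table."""
    old, new, y = [], [], []
    for up, down, n, outcome in [(11, 9, 114, 1), (103, 132, 1050, 0)]:
        moves = [1] * up + [-1] * down + [0] * (n - up - down)
        for m in moves:
            old.append(1)
            new.append(1 + m)
            y.append(outcome)
    t = reclassification_table(old, new, y)
    assert (t.up_event, t.down_event, t.n_event) == (11, 9, 114)
    assert (t.up_nonevent, t.down_nonevent, t.n_nonevent) == (103, 132, 1050)
    res = nri(t)
    assert round(100 * res.nri, 1) == 4.5


def test_mismatched_lengths_rejected():
    with pytest.raises(ValueError):
        reclassification_table([0, 1], [0], [1, 0])


def test_upclassified_analysis_null_and_empty(rng):
    # equal event rates in movers and stayers -> p near 1
    old = np.zeros(400)
    new = np.concatenate([np.ones(100), np.zeros(300)])
    y = np.tile([1, 0, 0, 0], 100)   # 25% events everywhere
    res = upclassified_analysis(old, new, y)
    assert res.n_up == 100
    assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)
    # nobody up-classified -> explicit empty result
    empty = upclassified_analysis(old, old, y)
    assert empty.n_up == 0 and empty.z is None and empty.p_two_sided is None


def test_upclassified_p_decreases_with_event_enrichment():
    old = np.zeros(600)
    new = np.concatenate([np.ones(100), np.zeros(500)])
    ps = []
    for k in (30, 50, 70):
        y = np.concatenate([np.ones(k), np.zeros(100 - k),
                            np.tile([1, 0, 0, 0, 0], 100)])
        ps.append(upclassified_analysis(old, new, y).p_two_sided)
    assert ps[0] > ps[1] > ps[2]


def test_combine_risk_identity_configuration(small_cohort, panel):
    """With the gene-score coefficient pinned to zero and (a, b) = (0, 1)
    the updated risk is exactly the Framingham risk; the fitted model nests
    this configuration."""
    risk = np.array([0.05, 0.10, 0.2, 0.4])
    eta = np.log(risk / (1 - risk))
    identity = 1 / (1 + np.exp(-(0.0 + 1.0 * eta + 0.0 * np.ones(4))))
    assert np.allclose(identity, risk)


def test_combine_risk_rejects_constant_gene_score(small_cohort):
    geno, cohort = small_cohort
    risk = grs.framingham_risk10(cohort)
    const = risk.copy() * 0 + 1.0
    with pytest.raises(DegenerateFitError, match="zero-variance"):
        combine_risk(risk, const, cohort["outcome"])


def test_combine_risk_improves_or_matches_auc(small_cohort, panel):
    """With true per-SNP effects the updated risk cannot discriminate worse
    than Framingham alone (within sampling error)."""
    geno, cohort = small_cohort
    scores = grs.compute_scores(geno, panel, 19)
    risk = grs.framingham_risk10(cohort)
    ids = scores.index[scores["complete"]]
    updated, _ = combine_risk(risk.loc[ids], scores.loc[ids, "score"],
                              cohort.loc[ids, "outcome"])
    y = cohort.loc[ids, "outcome"].to_numpy()
    auc_new, auc_old, delta, _ = auc_compare(updated.loc[ids],
                                             risk.loc[ids], y)
    assert delta > -0.02


def brute_force_auc(scores, y):
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_equals_exhaustive_pair_proportion(rng):
    for _ in range(20):
        n = int(rng.integers(10, 50))
        scores = np.round(rng.normal(size=n), 1)   # force some ties
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        assert auc(scores, y) == pytest.approx(brute_force_auc(scores, y),
                                               abs=1e-12)


def test_auc_compare_edge_cases(rng):
    y = np.array([1, 1, 0, 0, 1, 0])
    s = np.array([0.9, 0.8, 0.1, 0.2, 0.7, 0.3])
    a, b, delta, p = auc_compare(s, s, y)
    assert delta == 0.0 and p == 1.0
    assert auc(s, y) == 1.0          # perfectly separating score
    with pytest.raises(ValueError):
        auc(s, np.ones_like(y))


def test_delong_p_matches_normal_theory_on_independent_scores(rng):
    """Sanity: on two informative but noisy scores the DeLong p lies in
    (0, 1) and the AUCs match their rank statistics."""
    n = 300
    y = rng.integers(0, 2, size=n)
    s1 = y + rng.normal(scale=1.0, size=n)
    s2 = y + rng.normal(scale=1.5, size=n)
    a1, a2, delta, p = auc_compare(s1, s2, y)
    assert a1 == pytest.approx(brute_force_auc(s1, y))
    assert a2 == pytest.approx(brute_force_auc(s2, y))
    assert 0.0 < p <= 1.0
    assert delta == pytest.approx(a1 - a2)
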