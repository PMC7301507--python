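import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats as sps

from lcrisk import association as assoc
from lcrisk.errors import (ClassError, ConsistencyError, DegenerateBinningError,
                           DesignError, DomainError, FeasibilityError,
                           SeparationError)


# ---------------------------------------------------------------------------
# pack-years and smoking classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cigs, years, expected", [
    (20, 30, 30.0),   # one pack a day for 30 years
    (0, 25, 0.0),
    (15, 40, 30.0),
    (10, 10, 5.0),
])
def test_pack_years_formula(cigs, years, expected):
    assert assoc.compute_pack_years(cigs, years) == pytest.approx(expected)


def test_pack_years_rejects_negative():
    with pytest.raises(DomainError):
        assoc.compute_pack_years(-1, 10)


def _subject(status, py, ysq):
    return pd.DataFrame({"smoking_status": [status], "pack_years": [py],
                         "years_since_quit": [ysq]})


@pytest.mark.parametrize("status, py, ysq, ever, heavy", [
    ("current", 35, 0.0, True, True),
    ("former", 35, 16.0, True, False),   # quit too long ago
    ("former", 30, 15.0, True, True),    # both thresholds inclusive
    ("former", 29.9, 2.0, True, False),  # under the dose threshold
    ("never", 0, np.nan, False, False),
])
def test_smoking_classification(status, py, ysq, ever, heavy):
    flags = assoc.classify_smoking(_subject(status, py, ysq))
    assert bool(flags["ever"].iloc[0]) is ever
    assert bool(flags["heavy"].iloc[0]) is heavy


def test_smoking_classification_rejects_contradiction():
    with pytest.raises(ConsistencyError):
        assoc.classify_smoking(_subject("never", 12.0, np.nan))


# ---------------------------------------------------------------------------
# quartile binning among controls
# ---------------------------------------------------------------------------

def test_quartile_bin_boundaries_follow_published_convention():
    # controls engineered so the cut-points are exactly (24, 27, 30):
    # Q1 = (-inf, 24), Q4 = [30, inf) as in the published quartile labels
    ctrl = np.array([18, 24, 24, 24, 27, 27, 30, 30, 30])  # type-7 quartiles
    scores = pd.Series(np.concatenate([ctrl, [30.0, 27.0, 23.0]]))
    mask = np.array([True] * 9 + [False] * 3)
    binning, bins = assoc.control_quartile_bins(scores, mask)
    assert binning.cutpoints == (24.0, 27.0, 30.0)
    assert list(bins.iloc[9:]) == [4.0, 3.0, 1.0]


def test_quartile_bins_match_interval_membership(rng):
    scores = pd.Series(rng.normal(size=300))
    mask = rng.random(300) < 0.8
    binning, bins = assoc.control_quartile_bins(scores, mask)
    q25, q50, q75 = binning.cutpoints
    for s, b in zip(scores, bins):
        expected = 1 + (s >= q25) + (s >= q50) + (s >= q75)
        assert b == expected
    # controls split about evenly across distinct-valued scores
    counts = bins[mask].value_counts()
    assert counts.min() >= 0.8 * mask.sum() / 4


def test_quartile_bins_all_below_first_cut():
    scores = pd.Series([0.0] * 10 + list(range(1, 9)))
    mask = np.array([False] * 10 + [True] * 8)
    _, bins = assoc.control_quartile_bins(scores, mask)
    assert (bins.iloc[:10] == 1).all()


def test_quartile_bins_degenerate_controls():
    with pytest.raises(DegenerateBinningError):
        assoc.control_quartile_bins(pd.Series([1.0] * 20), np.ones(20, dtype=bool))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_logistic_2x2_equals_cross_product_ratio():
    a, b, c, d = 13, 37, 29, 71  # exposed cases/controls, unexposed cases/controls
    fit = assoc.fit_logistic_from_counts([c, a], [d, b])
    assert np.exp(fit.params["level_2"]) == pytest.approx(a * d / (b * c), rel=1e-8)


def test_logistic_loglik_matches_independent_optimizer(rng):
    # direct minimisation of the negative log-likelihood from a zero start
    n = 50
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    y = (rng.random(n) < 0.4).astype(float)
    fit = assoc.fit_logistic(pd.Series(y), X)

    Xd = np.column_stack([np.ones(n), X.to_numpy()])

    def nll(beta):
        eta = Xd @ beta
        return -(y * eta - np.logaddexp(0, eta)).sum()

    res = scipy.optimize.minimize(nll, np.zeros(3), method="BFGS")
    assert fit.llf == pytest.approx(-res.fun, abs=1e-6)
    assert np.allclose(fit.params.to_numpy(),
                       [res.x[0], res.x[1], res.x[2]], atol=1e-4)


def test_logistic_separation_raises():
    y = pd.Series([0.0] * 10 + [1.0] * 10)
    X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
    with pytest.raises(SeparationError):
        assoc.fit_logistic(y, X)


def test_logistic_rank_deficiency_raises(rng):
    y = pd.Series((rng.random(40) < 0.5).astype(float))
    x = rng.normal(size=40)
    X = pd.DataFrame({"x": x, "x2": 2 * x})
    with pytest.raises(DesignError):
        assoc.fit_logistic(y, X)


def test_logistic_complete_cases_reports_n(rng):
    y = pd.Series((rng.random(60) < 0.5).astype(float))
    X = pd.DataFrame({"x": rng.normal(size=60)})
    X.iloc[:7, 0] = np.nan
    fit = assoc.fit_logistic(y, X)
    assert fit.n_used == 53


# ---------------------------------------------------------------------------
# OR tables
# ---------------------------------------------------------------------------

def test_quartile_or_table_null_score_ors_near_one(rng):
    # a score independent of outcome should give ORs near 1 and roughly
    # uniform trend p-values over replicates
    trend_ps = []
    ors = []
    for rep in range(120):
        r = np.random.default_rng(rep)
        n = 500
        sub = pd.DataFrame({
            "case": (r.random(n) < 0.15).astype(int),
            "grs": r.normal(size=n),
        })
        tab = assoc.quartile_or_table(sub, "grs", model=1, population="all")
        trend_ps.append(tab["p_trend"].iloc[0])
        ors.append(tab["odds_ratio"].iloc[3])
    assert np.mean(np.log(ors)) == pytest.approx(0.0, abs=0.15)
    assert sps.kstest(trend_ps, "uniform").pvalue > 0.01


def test_quartile_or_table_structure(small_scored_cohort):
    tab = assoc.quartile_or_table(small_scored_cohort, "mrs", model=2,
                                  population="all")
    assert list(tab["quartile"]) == ["Q1", "Q2", "Q3", "Q4"]
    assert tab["odds_ratio"].iloc[0] == 1.0
    assert (tab["cases"] + tab["controls"]).sum() == tab["n_used"].iloc[0]
    est = tab.iloc[1:]
    assert ((est["ci_low"] <= est["odds_ratio"])
            & (est["odds_ratio"] <= est["ci_high"])).all()


def test_joint_groups_multiplicative_risk_ordering():
    # multiplicative risks on two median-split scores: the double-high group
    # should carry the largest OR, single-high groups intermediate
    highs, singles = [], []
    for rep in range(100):
        r = np.random.default_rng(1000 + rep)
        n = 600
        grs = r.normal(size=n)
        mrs = r.normal(size=n)
        eta = -1.5 + 0.7 * (mrs > 0) + 0.4 * (grs > 0)
        sub = pd.DataFrame({
            "case": (r.random(n) < sps.norm.cdf(eta)).astype(int),
            "grs": grs, "mrs": mrs, "batch": "B1",
        })
        tab = assoc.joint_group_or_table(sub, model=1)
        highs.append(np.log(tab["odds_ratio"].iloc[3]))
        singles.append(np.log(tab["odds_ratio"].iloc[2]))
    assert np.mean(highs) > np.mean(singles) > 0


def test_joint_groups_separation_surfaces(small_scored_cohort):
    sub = small_scored_cohort.copy()
    sub["grs"] = sub["case"].astype(float)
    sub["mrs"] = sub["case"].astype(float)
    # degenerate input must surface as an explicit error, never as silently
    # huge coefficients (which guard fires depends on which cells empty out)
    with pytest.raises((SeparationError, DesignError, ClassError)):
        assoc.joint_group_or_table(sub, model=1)


# ---------------------------------------------------------------------------
# Fisher exact 2xK
# ---------------------------------------------------------------------------

def test_fisher_2x2_exchangeable_table():
    assert assoc.fisher_exact_2xk([[1, 1], [1, 1]]) == pytest.approx(1.0)


@pytest.mark.parametrize("table", [
    [[3, 7], [9, 2]],
    [[10, 10], [10, 10]],
    [[1, 12], [8, 3]],
    [[0, 5], [7, 2]],
])
def test_fisher_2x2_matches_scipy(table):
    ours = assoc.fisher_exact_2xk(table)
    ref = sps.fisher_exact(np.asarray(table))[1]
    assert ours == pytest.approx(ref, rel=1e-9)


def test_fisher_enumeration_total_probability():
    _, total = assoc._fisher_enumerate([[4, 9, 2], [11, 3, 8]])
    assert total == pytest.approx(1.0, abs=1e-9)


def test_fisher_feasibility_guard():
    big = [[40000, 40000, 40000, 40000]] * 2
    with pytest.raises(FeasibilityError):
        assoc.fisher_exact_2xk(big)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def test_wilcoxon_identical_samples_exact():
    assert assoc.wilcoxon_rank_sum([1, 2, 3], [3, 1, 2]) == pytest.approx(1.0)


def test_wilcoxon_complete_separation_exact():
    # U = 0: the two one-in-twenty tails of the C(6,3) enumeration
    assert assoc.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_all_tied_warns():
    with pytest.warns(UserWarning):
        assert assoc.wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0


def test_wilcoxon_monotone_in_shift(rng):
    x = rng.normal(size=40)
    base = rng.normal(size=40)
    ps = [assoc.wilcoxon_rank_sum(x, base + shift) for shift in (0.2, 0.6, 1.2, 2.0)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_wilcoxon_asymptotic_matches_scipy(rng):
    x, y = rng.normal(size=30), rng.normal(0.4, 1, size=25)
    assert assoc.wilcoxon_rank_sum(x, y) == pytest.approx(
        sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
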