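import numpy as np
import pandas as pd
import pytest

from lcrisk import genetics as gen
from lcrisk.cohort_sim import SimConfig, default_snp_panel, simulate_genotypes
from lcrisk.errors import ConsistencyError, DegenerateLocusError
from lcrisk.errors import DomainError


def _annotation(snp_ids, chrom="1", positions=None, ranks=None, maf=0.3):
    n = len(snp_ids)
    return pd.DataFrame({
        "snp_id": snp_ids,
        "chromosome": [chrom] * n,
        "position": positions if positions is not None else range(1000, 1000 + n),
        "risk_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "maf": [maf] * n,
        "assoc_rank": ranks if ranks is not None else range(1, n + 1),
    })


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def test_qc_excludes_high_missingness():
    g = pd.DataFrame({"s1": [1.0] * 89 + [np.nan] * 11,
                      "s2": [0.0, 1.0] * 50})
    kept, log = gen.qc_filter_snps(g, _annotation(["s1", "s2"]))
    assert kept == ["s2"]
    assert log.iloc[0]["reason"] == "missingness"


def test_qc_maf_boundary_inclusive():
    # sample MAF exactly 0.005: only strictly lower frequencies are excluded
    g = pd.DataFrame({"s1": [1.0] + [0.0] * 99})  # MAF 0.005
    kept, log = gen.qc_filter_snps(g, _annotation(["s1"]))
    assert kept == ["s1"] and log.empty


def test_qc_pass_through():
    rng = np.random.default_rng(0)
    g = pd.DataFrame(rng.integers(0, 3, size=(50, 4)).astype(float),
                     columns=list("abcd"))
    kept, log = gen.qc_filter_snps(g, _annotation(list("abcd")))
    assert kept == list("abcd") and log.empty


def test_qc_unannotated_snp_raises():
    g = pd.DataFrame({"mystery": [0.0, 1.0]})
    with pytest.raises(ConsistencyError):
        gen.qc_filter_snps(g, _annotation(["other"]))


# ---------------------------------------------------------------------------
# haplotype EM
# ---------------------------------------------------------------------------

def test_em_no_double_heterozygotes_equals_gamete_counting():
    # phase unambiguous: haplotypes countable directly
    a = np.array([2, 2, 0, 0, 1, 1])
    b = np.array([2, 0, 2, 0, 0, 2])
    f = gen.em_haplotype_frequencies(a, b)
    # direct gamete counts: subject (2,2)->AB,AB; (2,0)->Ab,Ab; (0,2)->aB,aB;
    # (0,0)->ab,ab; (1,0)->Ab,ab; (1,2)->AB,aB
    expected = np.array([3, 3, 3, 3]) / 12
    assert np.allclose(f, expected, atol=1e-9)


def test_em_independent_loci_product_of_marginals():
    rng = np.random.default_rng(42)
    a = rng.binomial(2, 0.5, size=5000).astype(float)
    b = rng.binomial(2, 0.5, size=5000).astype(float)
    f = gen.em_haplotype_frequencies(a, b)
    assert f[0] == pytest.approx(0.25, abs=0.02)


@pytest.mark.parametrize("seed", range(5))
def test_em_beats_profile_grid_search(seed):
    # the marginal allele frequencies are preserved by every EM step, so the
    # MLE lies on the one-parameter profile over p_AB; a 0.001-step grid over
    # that profile may not beat the EM solution's log-likelihood
    rng = np.random.default_rng(seed)
    n = 200
    h = rng.random((n, 4)) < rng.uniform(0.2, 0.8)
    a = (h[:, 0].astype(int) + h[:, 1]).astype(float)
    b = ((h[:, 0] ^ (rng.random(n) < 0.3)).astype(int)
         + (h[:, 1] ^ (rng.random(n) < 0.3))).astype(float)
    f = gen.em_haplotype_frequencies(a, b)
    table = gen._genotype_table(a, b)
    ll_em = gen.haplotype_log_likelihood(f, table)

    pa, pb = f[0] + f[1], f[0] + f[2]
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    best = -np.inf
    for pab in np.arange(lo, hi + 1e-12, 0.001):
        cand = np.array([pab, pa - pab, pb - pab, 1 - pa - pb + pab])
        if np.any(cand < 0):
            continue
        best = max(best, gen.haplotype_log_likelihood(cand, table))
    assert ll_em >= best - 1e-6


def test_em_simplex_and_label_swap(rng):
    a = rng.binomial(2, 0.4, size=300).astype(float)
    b = rng.binomial(2, 0.3, size=300).astype(float)
    f = gen.em_haplotype_frequencies(a, b)
    assert f.sum() == pytest.approx(1.0, abs=1e-9) and (f >= 0).all()
    # swapping loci relabels AB<->BA consistently: (AB,Ab,aB,ab)->(AB,aB,Ab,ab)
    g = gen.em_haplotype_frequencies(b, a)
    assert np.allclose(f, g[[0, 2, 1, 3]], atol=1e-8)


def test_em_monomorphic_raises():
    with pytest.raises(DegenerateLocusError):
        gen.em_haplotype_frequencies(np.zeros(10), np.ones(10))


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def test_ld_equilibrium_is_zero():
    pA, pB = 0.3, 0.6
    f = [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    ld = gen.ld_statistics(f)
    assert ld["d_prime"] == pytest.approx(0.0, abs=1e-12)
    assert ld["r_squared"] == pytest.approx(0.0, abs=1e-12)


def test_ld_complete_equal_frequencies():
    ld = gen.ld_statistics([0.4, 0.0, 0.0, 0.6])  # p_AB = min(p_A, p_B), equal
    assert ld["d_prime"] == pytest.approx(1.0)
    assert ld["r_squared"] == pytest.approx(1.0)


def test_ld_matches_direct_formulas(rng):
    for _ in range(20):
        f = rng.dirichlet([2, 2, 2, 2])
        ld = gen.ld_statistics(f)
        pA, pB = f[0] + f[1], f[0] + f[2]
        d = f[0] - pA * pB
        dmax = min(pA * (1 - pB), (1 - pA) * pB) if d > 0 else \
            min(pA * pB, (1 - pA) * (1 - pB))
        assert ld["d"] == pytest.approx(d)
        assert ld["d_prime"] == pytest.approx(min(abs(d) / dmax, 1.0))
        assert ld["r_squared"] == pytest.approx(
            min(d * d / (pA * (1 - pA) * pB * (1 - pB)), 1.0))
        assert 0 <= ld["d_prime"] <= 1 and 0 <= ld["r_squared"] <= 1


def test_ld_boundary_marginal_raises():
    with pytest.raises(DegenerateLocusError):
        gen.ld_statistics([0.5, 0.5, 0.0, 0.0])  # p_B = 0.5+0... p_b = 0


def test_composite_r2_agrees_with_em_under_hwe(rng):
    n = 4000
    h = rng.random((n, 2)) < 0.4
    a = h.sum(axis=1).astype(float)
    flip = rng.random((n, 2)) < 0.1
    b = (h ^ flip).sum(axis=1).astype(float)
    em_r2 = gen.ld_statistics(gen.em_haplotype_frequencies(a, b))["r_squared"]
    assert gen.composite_r2(a, b) == pytest.approx(em_r2, abs=0.02)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_prune_perfect_ld_pair_keeps_better_rank(rng):
    col = rng.binomial(2, 0.3, size=200).astype(float)
    g = pd.DataFrame({"s1": col, "s2": col})
    ann = _annotation(["s1", "s2"], positions=[100_000, 110_000], ranks=[2, 1])
    assert gen.ld_prune(ann, g) == ["s2"]


def test_prune_outside_window_keeps_both(rng):
    col = rng.binomial(2, 0.3, size=200).astype(float)
    g = pd.DataFrame({"s1": col, "s2": col})
    ann = _annotation(["s1", "s2"], positions=[100_000, 400_000], ranks=[2, 1])
    assert gen.ld_prune(ann, g) == ["s1", "s2"]


def test_prune_51_panel_with_20_redundancies_leaves_31():
    cfg = SimConfig(seed=3)
    rng = np.random.default_rng(99)
    panel = default_snp_panel(cfg, rng)
    g = simulate_genotypes(800, panel, seed=7, copy_prob=0.995)
    ann = panel.copy()
    ann["assoc_rank"] = range(len(ann))
    retained = gen.ld_prune(ann, g)
    assert len(retained) == 31


def test_prune_idempotent(rng):
    cfg = SimConfig(seed=3, n_snps=12, n_redundant_snps=4)
    panel = default_snp_panel(cfg, np.random.default_rng(1))
    g = simulate_genotypes(500, panel, seed=2, copy_prob=1.0)
    ann = panel.copy()
    ann["assoc_rank"] = range(len(ann))
    once = gen.ld_prune(ann, g)
    twice = gen.ld_prune(ann[ann["snp_id"].isin(once)], g[once])
    assert once == twice


# ---------------------------------------------------------------------------
# the score
# ---------------------------------------------------------------------------

def test_grs_null_and_maximum():
    g0 = pd.DataFrame(np.zeros((3, 31)), columns=[f"s{i}" for i in range(31)])
    grs, _ = gen.compute_grs(g0, list(g0.columns))
    assert (grs == 0).all()
    g2 = pd.DataFrame(np.full((3, 31), 2.0), columns=g0.columns)
    grs2, _ = gen.compute_grs(g2, list(g0.columns))
    assert (grs2 == 62).all()


def test_grs_equals_row_sums(rng):
    g = pd.DataFrame(rng.integers(0, 3, size=(5, 4)).astype(float),
                     columns=list("abcd"))
    grs, log = gen.compute_grs(g, list("abcd"))
    assert np.allclose(grs, g.sum(axis=1))
    assert log == []
    assert np.allclose(grs, np.round(grs))  # integer without missingness


def test_grs_mean_imputation_and_all_missing_flag():
    g = pd.DataFrame({"a": [0.0, 2.0, np.nan, np.nan],
                      "b": [1.0, 1.0, 1.0, np.nan]})
    grs, log = gen.compute_grs(g, ["a", "b"])
    assert grs.iloc[2] == pytest.approx(1.0 + 1.0)  # mean dosage of a is 1.0
    assert np.isnan(grs.iloc[3])
    assert any(isinstance(e, tuple) for e in log)
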