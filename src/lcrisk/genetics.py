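"""Genetic risk score construction: SNP QC, linkage disequilibrium, pruning.

The GRS is an unweighted count of risk alleles over a curated SNP panel.
Candidate SNPs pass missingness/MAF filters, redundant SNPs in high pairwise
LD (D' and r-squared both above threshold, within a genomic window) are
pruned keeping the most significant member, and the score is the row sum of
risk-allele dosages over the retained panel.

Dosages are unphased counts in {0, 1, 2} (NaN = missing), so two-locus
haplotype frequencies — needed for D'/r² — are estimated by the standard EM
algorithm over the 3x3 genotype table, where only the double heterozygote is
phase-ambiguous.

Annotation tables are pandas DataFrames with columns ``snp_id, chromosome,
position, risk_allele, other_allele, maf, assoc_rank`` (smaller rank = more
significant; how the rank is computed is the caller's choice, typically a
per-SNP univariate association p-value in the analysis sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, DegenerateLocusError, DomainError

__all__ = [
    "qc_filter_snps",
    "em_haplotype_frequencies",
    "haplotype_log_likelihood",
    "ld_statistics",
    "composite_r2",
    "ld_prune",
    "compute_grs",
]


def _check_annotation(genotypes: pd.DataFrame, snps: pd.DataFrame) -> None:
    missing = set(genotypes.columns) - set(snps["snp_id"])
    if missing:
        raise ConsistencyError(
            f"SNPs in dosage matrix absent from annotation: {sorted(missing)[:5]}")


def qc_filter_snps(genotypes: pd.DataFrame, snps: pd.DataFrame,
                   missing_max: float = 0.10,
                   maf_min: float = 0.005) -> tuple[list[str], pd.DataFrame]:
    """Per-SNP quality filters on the dosage matrix.

    A SNP is kept iff its missingness is <= `missing_max` (strictly more than
    the threshold excludes) AND its sample MAF is >= `maf_min` (only strictly
    lower frequencies are excluded). Returns the kept snp_id list in matrix
    column order and an exclusion log with one row per dropped SNP.
    """
    if not (0 < missing_max < 1) or not (0 < maf_min < 1):
        raise ConfigurationError("missing_max and maf_min must lie in (0, 1)")
    _check_annotation(genotypes, snps)
    kept, log = [], []
    for snp in genotypes.columns:
        col = genotypes[snp]
        miss = float(col.isna().mean())
        if miss > missing_max:
            log.append({"snp_id": snp, "reason": "missingness", "value": miss})
            continue
        p = float(col.mean() / 2.0)  # risk-allele frequency from dosage mean
        maf = min(p, 1.0 - p)
        if maf < maf_min:
            log.append({"snp_id": snp, "reason": "maf", "value": maf})
            continue
        kept.append(snp)
    return kept, pd.DataFrame(log, columns=["snp_id", "reason", "value"])


# ---------------------------------------------------------------------------
# two-locus haplotype EM and LD statistics
# ---------------------------------------------------------------------------

def _genotype_table(dosage_a, dosage_b) -> np.ndarray:
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise DomainError("dosage vectors must be 1-D, equal length >= 2")
    ok = ~(np.isnan(a) | np.isnan(b))  # pairwise-complete subjects
    a, b = a[ok].astype(int), b[ok].astype(int)
    if len(a) < 2:
        raise DomainError("fewer than 2 pairwise-complete subjects")
    n = np.zeros((3, 3))
    np.add.at(n, (a, b), 1)
    return n


def haplotype_log_likelihood(freqs, table: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under haplotype
    frequencies (pAB, pAb, paB, pab) with random mating."""
    pab_, pAb, paB, pAB = freqs[3], freqs[1], freqs[2], freqs[0]
    g = np.empty((3, 3))
    # P(genotype) as products of the two constituent haplotypes
    g[2, 2] = pAB ** 2
    g[2, 1] = 2 * pAB * pAb
    g[2, 0] = pAb ** 2
    g[1, 2] = 2 * pAB * paB
    g[1, 1] = 2 * (pAB * pab_ + pAb * paB)
    g[1, 0] = 2 * pAb * pab_
    g[0, 2] = paB ** 2
    g[0, 1] = 2 * paB * pab_
    g[0, 0] = pab_ ** 2
    with np.errstate(divide="ignore"):
        logg = np.log(g)
    mask = table > 0
    if np.any(np.isneginf(logg[mask])):
        return -np.inf
    return float((table[mask] * logg[mask]).sum())


def em_haplotype_frequencies(dosage_a, dosage_b, tol: float = 1e-10,
                             max_iter: int = 1000) -> np.ndarray:
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab).

    A/B are the alleles counted by the dosages. Only the double heterozygote
    is phase-ambiguous; the E-step splits it between AB/ab and Ab/aB in
    proportion to the current frequency products. Converges when the largest
    frequency change falls below `tol` (log-likelihood is monotone).
    Raises DegenerateLocusError for a monomorphic locus.
    """
    n = _genotype_table(dosage_a, dosage_b)
    ntot = n.sum()
    pa = (n * np.arange(3)[:, None]).sum() / (2 * ntot)
    pb = (n * np.arange(3)[None, :]).sum() / (2 * ntot)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise DegenerateLocusError("monomorphic locus: both alleles must be present")

    # start at linkage equilibrium
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    ndh = n[1, 1]  # double heterozygotes
    # unambiguous haplotype counts contributed by the other 8 genotype cells
    base = np.array([
        2 * n[2, 2] + n[2, 1] + n[1, 2],  # AB
        2 * n[2, 0] + n[2, 1] + n[1, 0],  # Ab
        2 * n[0, 2] + n[0, 1] + n[1, 2],  # aB
        2 * n[0, 0] + n[0, 1] + n[1, 0],  # ab
    ], dtype=float)
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        w = 0.5 if denom == 0 else f[0] * f[3] / denom
        counts = base + ndh * np.array([w, 1 - w, 1 - w, w])
        f_new = counts / (2 * ntot)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f


def ld_statistics(hap_freqs) -> dict:
    """D, D' and r² from haplotype frequencies (AB, Ab, aB, ab).

    D  = pAB - pA*pB
    D' = |D| / Dmax,  Dmax = min(pA*pb, pa*pB) if D > 0 else min(pA*pB, pa*pb)
    r² = D² / (pA*pa*pB*pb)
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-8 or np.any(f < -1e-12):
        raise DomainError("haplotype frequencies must be 4 non-negatives summing to 1")
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        raise DegenerateLocusError("boundary allele frequency (0 or 1)")
    d = f[0] - pA * pB
    dmax = min(pA * pb, pa * pB) if d > 0 else min(pA * pB, pa * pb)
    d_prime = 0.0 if d == 0 else abs(d) / dmax
    r2 = d * d / (pA * pa * pB * pb)
    return {"d": float(d), "d_prime": float(min(d_prime, 1.0)),
            "r_squared": float(min(r2, 1.0))}


def composite_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of dosages (composite LD, phase-free).

    Exposed as a cross-check on the EM-based r²; equals it exactly under
    Hardy-Weinberg genotype frequencies.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise DegenerateLocusError("monomorphic locus")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# LD pruning and the score itself
# ---------------------------------------------------------------------------

def pairwise_ld(genotypes: pd.DataFrame, snp_a: str, snp_b: str) -> dict:
    """D'/r² between two SNPs of the dosage matrix via haplotype EM."""
    f = em_haplotype_frequencies(genotypes[snp_a], genotypes[snp_b])
    return ld_statistics(f)


def ld_prune(snps: pd.DataFrame, genotypes: pd.DataFrame,
             window_bp: int = 200_000, dprime_min: float = 0.95,
             r2_min: float = 0.80) -> list[str]:
    """Greedy best-rank-first LD pruning of a SNP panel.

    SNPs are visited in order of `assoc_rank` (smaller = more significant;
    ties broken by chromosome then position). A SNP is retained unless it is
    within `window_bp` of an already-retained SNP on the same chromosome with
    D' >= `dprime_min` AND r² >= `r2_min`. Monomorphic pairs cannot be in LD
    and never trigger removal. Returns the retained snp_ids in genomic order.
    Idempotent: pruning a pruned panel removes nothing further.
    """
    ann = snps.set_index("snp_id").loc[list(genotypes.columns)]
    if ann["assoc_rank"].isna().any():
        raise ConfigurationError("every SNP needs an assoc_rank for pruning")
    order = ann.sort_values(["assoc_rank", "chromosome", "position"]).index
    kept: list[str] = []
    for snp in order:
        chrom, pos = ann.at[snp, "chromosome"], ann.at[snp, "position"]
        redundant = False
        for other in kept:
            if ann.at[other, "chromosome"] != chrom:
                continue
            if abs(int(ann.at[other, "position"]) - int(pos)) > window_bp:
                continue
            try:
                ld = pairwise_ld(genotypes, snp, other)
            except DegenerateLocusError:
                continue
            if ld["d_prime"] >= dprime_min and ld["r_squared"] >= r2_min:
                redundant = True
                break
        if not redundant:
            kept.append(snp)
    return sorted(kept, key=lambda s: (str(ann.at[s, "chromosome"]),
                                       int(ann.at[s, "position"])))


def univariate_assoc_rank(genotypes: pd.DataFrame, outcome) -> pd.Series:
    """Per-SNP association rank: univariate logistic Wald p against case status.

    Fits case ~ dosage separately per SNP (complete cases) and returns the
    Wald p-values; smaller = more significant, suitable as `assoc_rank` for
    :func:`ld_prune`. A SNP whose fit separates or degenerates gets rank 1.0
    (least significant).
    """
    from .association import fit_logistic  # deferred: association is independent
    from .errors import LcriskError

    y = pd.Series(outcome)
    ps = {}
    for snp in genotypes.columns:
        X = genotypes[[snp]].astype(float)
        try:
            fit = fit_logistic(y, X)
            ps[snp] = fit.wald_p(snp)
        except LcriskError:
            ps[snp] = 1.0
    return pd.Series(ps, name="assoc_rank")


def compute_grs(genotypes: pd.DataFrame,
                retained_snps: list[str]) -> tuple[pd.Series, list]:
    """Genetic risk score: sum of risk-allele dosages over the retained panel.

    Missing dosages are imputed per SNP as twice the sample risk-allele
    frequency (the column mean) before summation, so the score stays on the
    0..2m scale; subjects imputed at one or more SNPs are returned in the log.
    A subject missing every retained SNP gets a missing (NaN) score.
    """
    if not retained_snps:
        raise ConfigurationError("retained_snps must be non-empty")
    g = genotypes[list(retained_snps)].astype(float)
    all_missing = g.isna().all(axis=1)
    imputed_subjects = list(g.index[g.isna().any(axis=1) & ~all_missing])
    grs = g.fillna(g.mean()).sum(axis=1)
    grs[all_missing] = np.nan
    grs.name = "grs"
    log = imputed_subjects + [(s, "all dosages missing") for s in g.index[all_missing]]
    return grs, log
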