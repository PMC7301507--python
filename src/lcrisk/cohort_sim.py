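"""Synthetic nested case-control cohorts with genotype and methylation layers.

Generates cohorts with the statistical structure the downstream analysis
assumes: an older adult population (ages 50-75) with detailed smoking
history, risk-allele dosages for a candidate SNP panel containing deliberate
high-LD redundancies (so LD pruning has work to do), smoking-responsive CpG
beta-values with batch and leukocyte-composition structure, and a logistic
disease model in which smoking dose, the risk-allele count and the
methylation burden all raise risk independently.

Default parameters mirror a nested case-control sample of 1,603 subjects
(143 cases / 1,460 controls) drawn from a population-based cohort: a 51-SNP
candidate panel that prunes to 31 independent SNPs, 151 smoking-associated
CpGs with signed direction weights, 3 processing batches and 6 leukocyte
types.

Reproducibility: one global seed is expanded into independent substreams per
generator (annotation, phenotypes, smoking, genotypes, methylation, outcome),
so adding or re-running one generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.optimize import brentq
from scipy.special import expit

from .association import compute_pack_years
from .errors import AlignmentError, ConfigurationError, DomainError

__all__ = [
    "SimConfig",
    "CELL_TYPES",
    "default_snp_panel",
    "default_cpg_panel",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_smoking",
    "simulate_methylation",
    "assign_outcomes",
]

#: leukocyte types for the cell-composition covariates (columns cf_<type>)
CELL_TYPES = ("neu", "cd4t", "cd8t", "bcell", "nk", "mono")

_BETA_EPS = 1e-6  # betas kept strictly inside (0, 1) for logit transforms


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Outcome generation modes: ``bernoulli`` draws case status from the
    logistic model with an intercept calibrated so the expected case count
    equals `target_case_count`; ``fixed_count`` adds standard-logistic noise
    to the linear predictor and labels exactly the top `target_case_count`
    subjects as cases (useful for exact-count fixtures).
    """

    n_subjects: int = 1603
    target_case_count: int = 143
    outcome_mode: str = "bernoulli"  # or "fixed_count"
    seed: int = 0

    # demographics
    age_mean: float = 62.0
    age_sd: float = 6.5
    age_range: tuple[float, float] = (50.0, 75.0)
    male_fraction: float = 0.46

    # smoking: status mix over (never, former, current); pack-years among
    # ever smokers follow a gamma with the given shape/scale (mean 24)
    smoking_mix: tuple[float, float, float] = (0.48, 0.33, 0.19)
    packyear_shape: float = 1.6
    packyear_scale: float = 15.0

    # genotypes: candidate panel with high-LD redundancies
    n_snps: int = 51
    n_redundant_snps: int = 20
    block_copy_prob: float = 0.99
    snp_missing_rate: float = 0.0
    snp_effect_logor: float = 0.08  # per risk allele

    # methylation
    cpg_count: int = 151
    hyper_fraction: float = 0.5  # fraction of CpGs hypermethylated in smokers
    cpg_smoking_effect: float = 0.015  # beta shift per 10 pack-years, signed by W_c
    # per-subject biological smoking response shared across the panel (beta
    # scale); models true internal dose not captured by self-reported
    # pack-years, giving methylation predictive value beyond smoking history
    cpg_shared_response_sd: float = 0.02
    cpg_noise_sd: float = 0.05
    batch_levels: int = 3
    batch_effect_sd: float = 0.005
    cell_effect_sd: float = 0.02
    cell_fraction_concentration: tuple[float, ...] = (30.0, 7.5, 5.0, 2.5, 2.5, 4.0)

    # outcome model (log-odds scale)
    age_effect_logor: float = 0.03      # per year
    male_effect_logor: float = 0.40
    packyear_effect_logor: float = 0.035  # per pack-year
    methylation_outcome_logor: float = 1.00  # per unit standardised burden

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not (0 < self.target_case_count < self.n_subjects):
            raise ConfigurationError("target_case_count must lie in (0, n_subjects)")
        if self.outcome_mode not in ("bernoulli", "fixed_count"):
            raise ConfigurationError(f"outcome_mode: unknown mode {self.outcome_mode!r}")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        mix = np.asarray(self.smoking_mix, dtype=float)
        if len(mix) != 3 or np.any(mix < 0) or np.any(mix > 1) or abs(mix.sum() - 1) > 1e-9:
            raise ConfigurationError("smoking_mix must be 3 proportions summing to 1")
        if self.packyear_shape <= 0 or self.packyear_scale <= 0:
            raise ConfigurationError("packyear_shape/scale must be positive")
        for name in ("n_snps", "cpg_count", "batch_levels"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.n_redundant_snps < self.n_snps:
            raise ConfigurationError("n_redundant_snps must lie in [0, n_snps)")
        if not 0 <= self.hyper_fraction <= 1:
            raise ConfigurationError("hyper_fraction must lie in [0, 1]")
        if not 0 <= self.snp_missing_rate < 1:
            raise ConfigurationError("snp_missing_rate must lie in [0, 1)")
        conc = np.asarray(self.cell_fraction_concentration, dtype=float)
        if len(conc) != len(CELL_TYPES) or np.any(conc <= 0):
            raise ConfigurationError(
                f"cell_fraction_concentration needs {len(CELL_TYPES)} positive values")
        if min(self.cpg_noise_sd, self.batch_effect_sd, self.cell_effect_sd,
               self.cpg_shared_response_sd) < 0:
            raise ConfigurationError("noise/effect SDs must be non-negative")


# ---------------------------------------------------------------------------
# annotation panels
# ---------------------------------------------------------------------------

def default_snp_panel(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Candidate SNP panel with `n_redundant_snps` high-LD partner SNPs.

    Independent index SNPs are placed > 1 Mb apart; each redundant partner
    sits 10 kb from its index SNP and shares its haplotypes with probability
    `block_copy_prob` (see :func:`simulate_genotypes`), so the pair exceeds
    typical D'/r² pruning thresholds and the panel prunes back to the index
    SNPs. assoc_rank is left NaN; the analysis fills it from the sample.
    """
    n_index = config.n_snps - config.n_redundant_snps
    rows = []
    alleles = ("A", "C", "G", "T")
    for i in range(n_index):
        chrom = (i % 22) + 1
        pos = 1_000_000 + (i // 22) * 2_000_000
        maf = float(rng.uniform(0.08, 0.5))
        ra, oa = rng.choice(alleles, size=2, replace=False)
        rows.append({"snp_id": f"rs{i + 1:04d}", "chromosome": str(chrom),
                     "position": pos, "risk_allele": ra, "other_allele": oa,
                     "maf": maf, "assoc_rank": np.nan,
                     "block_id": i, "is_index": True})
    for j in range(config.n_redundant_snps):
        idx = rows[j]  # partner the first n_redundant index SNPs
        rows.append({"snp_id": f"rs{n_index + j + 1:04d}",
                     "chromosome": idx["chromosome"],
                     "position": idx["position"] + 10_000,
                     "risk_allele": idx["risk_allele"],
                     "other_allele": idx["other_allele"],
                     "maf": idx["maf"], "assoc_rank": np.nan,
                     "block_id": idx["block_id"], "is_index": False})
    return pd.DataFrame(rows)


def default_cpg_panel(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Smoking-associated CpG panel with signed direction weights.

    weight is +1 (hypermethylated in smokers) for `hyper_fraction` of probes
    and -1 otherwise; baselines are uniform on (0.15, 0.85) so smoking shifts
    rarely clip.
    """
    n = config.cpg_count
    n_hyper = int(round(config.hyper_fraction * n))
    weights = np.array([1] * n_hyper + [-1] * (n - n_hyper))
    return pd.DataFrame({
        "probe_id": [f"cg{i + 1:07d}" for i in range(n)],
        "chromosome": [str((i % 22) + 1) for i in range(n)],
        "weight": weights,
        "baseline": rng.uniform(0.15, 0.85, size=n),
        "detection_fail_fraction": 0.0,
        "missing_fraction": 0.0,
    })


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_smoking(n: int, config: SimConfig, rng: np.random.Generator,
                     age=None) -> pd.DataFrame:
    """Smoking-history columns: status, cigarettes/day, years, quit time.

    Pack-years are *derived* from simulated cigarettes/day and years smoked
    (via :func:`~lcrisk.association.compute_pack_years`), with the gamma
    distribution targeting the pack-year marginal among ever smokers; years
    smoked are capped at age - 18 when ages are supplied.
    """
    mix = np.asarray(config.smoking_mix, dtype=float)
    if abs(mix.sum() - 1) > 1e-9:
        raise ConfigurationError("smoking_mix must sum to 1")
    if config.packyear_shape <= 0 or config.packyear_scale <= 0:
        raise DomainError("gamma parameters must be positive")
    status = rng.choice(["never", "former", "current"], size=n, p=mix)
    ever = status != "never"
    cigs = np.zeros(n)
    years = np.zeros(n)
    ysq = np.full(n, np.nan)
    n_ever = int(ever.sum())
    if n_ever:
        target_py = rng.gamma(config.packyear_shape, config.packyear_scale, size=n_ever)
        c = rng.integers(5, 41, size=n_ever).astype(float)
        y = np.clip(target_py * 20.0 / c, 0.5, None)
        if age is not None:
            y = np.minimum(y, np.maximum(np.asarray(age, dtype=float)[ever] - 18.0, 1.0))
        cigs[ever] = c
        years[ever] = np.round(y, 1)
    former = status == "former"
    ysq[former] = np.round(rng.exponential(8.0, size=int(former.sum())), 1)
    ysq[status == "current"] = 0.0
    pack_years = compute_pack_years(cigs, years)
    return pd.DataFrame({
        "smoking_status": status, "cigs_per_day": cigs, "years_smoked": years,
        "years_since_quit": ysq, "pack_years": pack_years,
    })


def simulate_genotypes(n: int, snps: pd.DataFrame, seed,
                       missing_rate: float = 0.0,
                       copy_prob: float = 0.99) -> pd.DataFrame:
    """Risk-allele dosages under Hardy-Weinberg, with optional LD blocks.

    SNPs sharing a ``block_id`` are generated from shared haplotypes: the
    block's index SNP draws two haploid alleles per subject, and each partner
    SNP copies each haplotype with probability `copy_prob` (redrawing from
    its own MAF otherwise), which makes D' ≈ 1 and r² ≈ copy-prob-dependent
    high values. copy_prob = 1 yields identical dosage columns.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.asarray(snps["maf"], dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise DomainError("every SNP MAF must lie in (0, 0.5]")
    cols: dict[str, np.ndarray] = {}
    if "block_id" in snps.columns:
        block_ids = snps["block_id"].to_numpy()
    else:
        block_ids = np.arange(len(snps))  # every SNP its own block
    order = snps.reset_index(drop=True)
    for block in pd.unique(block_ids):
        members = order[block_ids == block]
        idx = members.iloc[0]
        h1 = rng.random(n) < idx["maf"]
        h2 = rng.random(n) < idx["maf"]
        cols[idx["snp_id"]] = (h1.astype(int) + h2.astype(int)).astype(float)
        for _, part in members.iloc[1:].iterrows():
            k1 = np.where(rng.random(n) < copy_prob, h1, rng.random(n) < part["maf"])
            k2 = np.where(rng.random(n) < copy_prob, h2, rng.random(n) < part["maf"])
            cols[part["snp_id"]] = (k1.astype(int) + k2.astype(int)).astype(float)
    g = pd.DataFrame(cols)[list(snps["snp_id"])]
    if missing_rate > 0:
        mask = rng.random(g.shape) < missing_rate
        g = g.mask(mask)
    return g


def simulate_methylation(subjects: pd.DataFrame, cpgs: pd.DataFrame,
                         config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """CpG beta-values responding to pack-years in the direction of W_c.

    beta = clip(baseline + W_c * effect * pack_years/10 + batch shift
                + cell-composition shift + noise,  [eps, 1 - eps])

    Batch shifts are a fixed draw per (batch level, probe); cell shifts load
    each probe on the centred cell fractions with N(0, cell_effect_sd)
    loadings.
    """
    base = np.asarray(cpgs["baseline"], dtype=float)
    if np.any(base <= 0) or np.any(base >= 1):
        raise ConfigurationError("cpg baselines must lie in (0, 1)")
    n, m = len(subjects), len(cpgs)
    w = np.asarray(cpgs["weight"], dtype=float)
    py = subjects["pack_years"].fillna(0).to_numpy()
    smoking = np.outer(py / 10.0, w * config.cpg_smoking_effect)
    # shared per-subject response: the component of the smoking-methylation
    # signature not explained by self-reported dose
    u = rng.normal(0.0, 1.0, size=n)
    smoking += np.outer(u * config.cpg_shared_response_sd, w)

    batch_shift = rng.normal(0.0, config.batch_effect_sd, size=(config.batch_levels, m))
    batch_idx = subjects["batch"].str.replace("B", "").astype(int).to_numpy() - 1

    conc = np.asarray(config.cell_fraction_concentration, dtype=float)
    fracs = subjects[[f"cf_{t}" for t in CELL_TYPES]].to_numpy()
    loadings = rng.normal(0.0, config.cell_effect_sd, size=(len(CELL_TYPES), m))
    cell_shift = (fracs - conc / conc.sum()) @ loadings

    noise = rng.normal(0.0, config.cpg_noise_sd, size=(n, m))
    betas = np.clip(base + smoking + batch_shift[batch_idx] + cell_shift + noise,
                    _BETA_EPS, 1.0 - _BETA_EPS)
    return pd.DataFrame(betas, index=subjects.index, columns=list(cpgs["probe_id"]))


def _methylation_burden(methylation: pd.DataFrame, cpgs: pd.DataFrame,
                        config: SimConfig) -> pd.Series:
    """Simulator-internal standardised smoking-methylation burden.

    Mean over probes of W_c * (beta - baseline) / noise SD — the latent
    quantity the observable methylation risk score estimates.
    """
    w = np.asarray(cpgs["weight"], dtype=float)
    base = np.asarray(cpgs["baseline"], dtype=float)
    z = (methylation.to_numpy() - base) / max(config.cpg_noise_sd, 1e-12)
    return pd.Series((z * w).mean(axis=1), index=methylation.index)


def assign_outcomes(subjects: pd.DataFrame, genotypes: pd.DataFrame,
                    methylation: pd.DataFrame, cpgs: pd.DataFrame,
                    config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Case status from a logistic model on smoking, genotype and methylation.

    Linear predictor (continuous terms centred at their sample means so the
    intercept controls prevalence):

        alpha + b_age*age + b_sex*male + b_py*pack_years
              + b_g*(risk-allele count) + b_m*(methylation burden)

    ``bernoulli`` mode calibrates alpha so the expected case count hits
    `target_case_count`; ``fixed_count`` mode adds standard-logistic noise
    and labels exactly the top `target_case_count` subjects — the two modes
    share the same conditional model.
    """
    if not (subjects.index.equals(genotypes.index)
            and subjects.index.equals(methylation.index)):
        raise AlignmentError("subjects, genotypes and methylation must share an index")
    g = genotypes.astype(float)
    allele_count = g.fillna(g.mean()).sum(axis=1)
    burden = _methylation_burden(methylation, cpgs, config)
    eta = (
        config.age_effect_logor * (subjects["age"] - subjects["age"].mean())
        + config.male_effect_logor * (subjects["sex"] == "male").astype(float)
        + config.packyear_effect_logor * subjects["pack_years"].fillna(0)
        + config.snp_effect_logor * (allele_count - allele_count.mean())
        + config.methylation_outcome_logor * (burden - burden.mean())
    ).to_numpy()
    target = config.target_case_count
    if config.outcome_mode == "fixed_count":
        z = eta + rng.logistic(size=len(eta))
        order = np.argsort(-z, kind="stable")
        case = np.zeros(len(eta), dtype=int)
        case[order[:target]] = 1
    else:
        alpha = brentq(lambda a: expit(a + eta).mean() - target / len(eta), -30, 30)
        case = (rng.random(len(eta)) < expit(alpha + eta)).astype(int)
    return pd.Series(case, index=subjects.index, name="case")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig):
    """Generate one synthetic cohort.

    Returns ``(subjects, genotypes, methylation, snp_annotation,
    cpg_annotation)``, all keyed by subject_id; byte-identical for identical
    config + seed.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_ann, rng_pheno, rng_smoke, rng_geno, rng_meth, rng_out = (
        np.random.default_rng(s) for s in streams)

    snp_ann = default_snp_panel(config, rng_ann)
    cpg_ann = default_cpg_panel(config, rng_ann)

    n = config.n_subjects
    ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id")
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = np.round(sps.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                                     size=n, random_state=rng_pheno), 1)
    sex = np.where(rng_pheno.random(n) < config.male_fraction, "male", "female")
    batch = np.array([f"B{i + 1}" for i in
                      rng_pheno.integers(0, config.batch_levels, size=n)])
    conc = np.asarray(config.cell_fraction_concentration, dtype=float)
    fracs = rng_pheno.dirichlet(conc, size=n)

    subjects = pd.DataFrame({"age": age, "sex": sex, "batch": batch}, index=ids)
    for j, t in enumerate(CELL_TYPES):
        subjects[f"cf_{t}"] = fracs[:, j]
    smoking = simulate_smoking(n, config, rng_smoke, age=age)
    smoking.index = ids
    subjects = pd.concat([subjects, smoking], axis=1)

    genotypes = simulate_genotypes(n, snp_ann, rng_geno,
                                   missing_rate=config.snp_missing_rate,
                                   copy_prob=config.block_copy_prob)
    genotypes.index = ids
    methylation = simulate_methylation(subjects, cpg_ann, config, rng_meth)
    subjects["case"] = assign_outcomes(subjects, genotypes, methylation, cpg_ann,
                                       config, rng_out)
    return subjects, genotypes, methylation, snp_ann, cpg_ann
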