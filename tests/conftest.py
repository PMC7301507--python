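import numpy as np
import pytest

from lcrisk import genetics, methylation
from lcrisk.cohort_sim import SimConfig, simulate_cohort


def score_cohort(subjects, genotypes, betas, snp_ann, cpg_ann):
    """Run the scoring chain (QC, ranks, pruning, GRS, reference, MRS)."""
    kept, _ = genetics.qc_filter_snps(genotypes, snp_ann)
    ranks = genetics.univariate_assoc_rank(genotypes[kept], subjects["case"])
    ann = snp_ann.copy()
    ann["assoc_rank"] = ann["snp_id"].map(ranks)
    retained = genetics.ld_prune(ann[ann["snp_id"].isin(kept)], genotypes[kept])
    grs, _ = genetics.compute_grs(genotypes, retained)
    probes, _ = methylation.qc_filter_probes(betas, cpg_ann)
    never = subjects.index[subjects["smoking_status"] == "never"]
    ref = methylation.compute_reference_stats(betas[probes], never)
    mrs, _ = methylation.compute_mrs(betas, ref, cpg_ann)
    out = subjects.copy()
    out["grs"], out["mrs"] = grs, mrs
    return out, retained, ref


@pytest.fixture(scope="session")
def cohort():
    """Full-size synthetic cohort (1603 subjects), raw tables."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def scored_cohort(cohort):
    """Subject table of the full cohort with GRS and MRS columns attached."""
    subjects, genotypes, betas, snp_ann, cpg_ann = cohort
    scored, retained, ref = score_cohort(subjects, genotypes, betas, snp_ann, cpg_ann)
    return scored


@pytest.fixture(scope="session")
def small_scored_cohort():
    """400-subject cohort with scores, for the faster model-level tests."""
    cfg = SimConfig(seed=5, n_subjects=400, target_case_count=60)
    subjects, genotypes, betas, snp_ann, cpg_ann = simulate_cohort(cfg)
    scored, _, _ = score_cohort(subjects, genotypes, betas, snp_ann, cpg_ann)
    return scored


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
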