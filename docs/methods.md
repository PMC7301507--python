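# Methods

## Scientific setting

`lcrisk` implements a risk-stratification analysis for lung cancer (LC) in a
nested case-control design: cases with incident LC and LC-free controls are
drawn from a population-based cohort of older adults (ages 50–75) with
detailed baseline smoking history, genome-wide genotyping and whole-blood
450K methylation data. Two molecular scores are built and evaluated for the
incremental predictive value they add to self-reported smoking dose
(pack-years):

* **GRS** — an unweighted count of risk alleles over a curated panel of
  LC-associated SNPs;
* **MRS** — the average of signed, reference-standardised deviations of
  methylation beta-values at smoking-associated CpGs,

  MRS_s = (1/n) Σ_c W_c (β_cs − μ_c) / σ_c,

  with μ_c, σ_c the mean and sample SD among never smokers (the reference)
  and W_c = +1 (−1) for CpGs hyper-(hypo-)methylated in smokers.

## Score construction

**SNP QC and pruning.** Candidate SNPs are dropped when sample missingness
exceeds 10% (strictly) or sample MAF falls below 0.5% (boundary kept). Pairs
within 200 kb on the same chromosome with D′ ≥ 0.95 **and** r² ≥ 0.80 are
redundant; a greedy pass over SNPs ordered by association rank (smaller =
more significant; ties broken by genomic position) keeps the best-ranked
member of each redundant cluster. The rank is an input; the pipeline fills
it with per-SNP univariate logistic Wald p-values against case status.
Because dosages are unphased, two-locus haplotype frequencies are estimated
by EM over the 3×3 genotype table (only the double heterozygote is
phase-ambiguous; convergence at max frequency change < 1e-10, ≤ 1000
iterations), and D′/r² follow the textbook normalisations. A composite r²
from the Pearson correlation of dosages is exposed as a cross-check.
Missing dosages in the retained panel are mean-imputed per SNP (twice the
sample allele frequency), the standard choice in polygenic-score tooling; it
preserves the score scale and is logged per subject.

**Probe QC and the MRS.** Probes on sex chromosomes are excluded, as are
probes with > 10% missingness or failing detection. Detection is consumed as
a per-probe summary (fraction of samples failing the detection-p criterion)
because probe-level exclusion is the only reproducible reading of an
aggregate rule; a strict mode drops any probe with a single failure.
σ_c uses the n−1 denominator (negligible at reference sizes of several
hundred, but pinned for reproducibility). For subjects with missing betas
the score renormalises by that subject's non-missing probe count, keeping
the scale comparable across subjects; a strict mode refuses missingness
instead. Structural identities used as tests: the mean MRS over the
reference set is 0 to 1e-10; a one-σ deviation in the smoking direction at a
single probe scores exactly 1; the score is linear in β and sign-flipping
every W_c negates it.

## Association models

Scores are binned by quartiles **among the analysis population's controls**
using type-7 (linear-interpolation) empirical percentiles — the quantile
rule is pinned in configuration since different conventions move integer GRS
cut-points. Bins are half-open on the left: Q1 = (−∞, q25), Q4 = [q75, ∞),
matching the "Q1 (< 24) … Q4 (≥ 30)" labelling convention. Three logistic
adjustment models are fitted with Q1 as reference:

1. no covariates for the GRS; batch (3 levels) + leukocyte composition for
   the MRS (technical covariates only);
2. model 1 + age + sex;
3. model 2 + smoking status + pack-years.

Smoking status enters model 3 as a two-level factor (never/former vs
current). Leukocyte composition enters as 5 of the 6 cell fractions
(neutrophils dropped as reference, since fractions sum to one). The trend
p-value refits with the ordinal bin index 1–4 — the conventional reading of
a "p for trend". Joint GRS/MRS groups use control-median splits (high = at
or above the median, same half-open convention), ordered low/low →
high/high with low/low as reference; all joint models carry the technical
covariates. Analyses are complete-case and every fit reports its n.

Fits use maximum likelihood (IRLS via statsmodels GLM/binomial, frequency
weights for grouped count data) with Wald 95% CIs, exp(b ± 1.96·SE).
Separation is detected on the per-SD log-odds scale (|coef|·SD(x) > 15)
so small-scale covariates such as cell fractions are not misflagged;
separated or rank-deficient designs raise explicit errors instead of
returning unstable estimates. Profile-likelihood CIs are not implemented;
published CIs for count-only refits are slightly wider than Wald CIs,
consistent with a profile method, so only point ORs are compared.

The baseline-table tests are a 2×K Fisher exact test (full enumeration of
fixed-margin tables in log-space; a table counts toward the p-value when its
multivariate hypergeometric probability is ≤ the observed probability with
relative tolerance 1e-12; enumeration is refused above 5×10⁷ tables) and a
Wilcoxon rank-sum test (exact permutation enumeration for pooled n ≤ 12,
ties allowed, two-sided tail defined by |U − E U|; otherwise the normal
approximation with tie and continuity corrections).

## Predictive evaluation

AUC is the Mann–Whitney probability that a random case outscores a random
control (ties half), with DeLong placement-based variance for the CI.
Optimism correction follows the 0.632+ bootstrap on the error scale
err = 1 − AUC: the model is refitted on each of B case/control-stratified
resamples and evaluated on that replicate's out-of-bag subjects; with
no-information error γ = 0.5 (the analytic value for a rank-based AUC under
label independence), the relative overfitting rate
R = (err_oob − err_app)/(γ − err_app) (clipped to [0,1], R = 0 when
err_oob ≤ err_app) sets the weight w = 0.632/(1 − 0.368·R) and
err_632+ = (1−w)·err_app + w·min(err_oob, γ). Stratified resampling is used
because unstratified resampling of a ~70-case subgroup frequently yields
single-class replicates; invalid replicates are redrawn and counted.
Replicate r draws from substream (seed, r), so enlarging B preserves
earlier replicates.

Continuous NRI counts risk moves strictly larger than 5 percentage points
(the boundary is pinned strict); its p-value is the standard asymptotic
z-test. IDI is the change in discrimination slope, tested with within-class
paired-difference SEs combined in quadrature. Both compare each combined
model (pack-years + score(s)) against pack-years alone. The evaluation grid
crosses three populations (all participants; ever smokers; heavy smokers,
defined as ≥ 30 pack-years and current or quit ≤ 15 years — both boundaries
inclusive) with seven predictor sets, scores entered as quantitative
variables. Confusion matrices default to the population's case prevalence
as probability threshold (configurable); precision at zero predicted
positives is reported as 1 by convention and flagged.

## Synthetic cohort

No individual-level data accompany the analysis, so `cohort_sim` generates
cohorts with the structure the method assumes. Defaults: 1,603 subjects with
an expected 143 cases; ages truncated-normal (62 ± 6.5) on [50, 75]; 46%
male; smoking mix (never/former/current) = (0.48, 0.33, 0.19), close to the
control distribution of a general older population; pack-years among ever
smokers gamma(1.6, 15) (mean 24), *derived* from simulated cigarettes/day
and years smoked so the pack-year computation is exercised; quit times
exponential (mean 8 y). The candidate SNP panel holds 51 SNPs of which 20
are high-LD partners of index SNPs (haplotype copy probability 0.99, 10 kb
apart), so LD pruning recovers the 31 independent members; MAFs are uniform
(0.08, 0.5) under Hardy–Weinberg. The 151 CpGs have baselines uniform
(0.15, 0.85), half hyper-/half hypomethylated in smokers, a beta shift of
0.015 per 10 pack-years in the W_c direction, batch (3 levels, SD 0.005) and
cell-composition structure (6 leukocyte types from a Dirichlet concentrated
on a neutrophil-dominant profile), and i.i.d. noise SD 0.05; betas are
clipped to [1e-6, 1 − 1e-6] so logit transforms stay finite.

A per-subject **shared smoking-response factor** (SD 0.02 on the beta scale,
loading all CpGs in the W_c direction) models true internal smoking dose not
captured by self-report. This is what gives methylation predictive value
*beyond* pack-years: without it, the methylation signal is fully mediated by
recorded dose and the adjusted MRS association is null by construction.

Case status follows a logistic model on age, sex, pack-years, total
risk-allele count (log-OR 0.08/allele) and the standardised methylation
burden (log-OR 1.0/unit), continuous terms centred so the intercept controls
prevalence. Effect sizes were chosen once for adequate power at n ≈ 1,600 —
they are not estimates of any published cohort's liability-scale effects.
Two outcome modes share this conditional model: `bernoulli` (default)
calibrates the intercept by root-finding so the expected case count hits the
target; `fixed_count` adds standard-logistic noise to the linear predictor
and labels exactly the top-k subjects, for exact-count fixtures. One master
seed expands into independent substreams per generator, so adding a
generator never perturbs the others.

What the simulation does *not* emulate: array chemistry and probe-level
intensities, realistic reference-panel LD maps, genotype imputation
uncertainty, cell-type deconvolution (fractions are consumed as given
covariates), and real confounding between batch and outcome. Tests passing
on this cohort therefore validate the statistical machinery and its
calibration, not the field performance of the scores on real data.

## Problem sizes and numerical choices

Tests run the optimism experiments at n = 300 with B = 100–200 and 30–100
simulation replicates, parameter recovery at n = 2,000 over 200 replicates
(coverage asserted within ±4% of nominal 95%), and end-to-end determinism on
the full 1,603-subject cohort with B = 100 — sizes chosen so the whole suite
completes in minutes on one CPU while keeping Monte Carlo error well inside
the asserted tolerances. The acceptance script uses B = 200 for the grid.
EM convergence 1e-10; logistic IRLS tolerance 1e-10, 200 iterations; Fisher
tie tolerance 1e-12 in log-space; quantile rule type 7; all file outputs use
`%.10g` floats so byte-identical reruns are well-defined.

## Known limitations

Only Wald CIs are available for ORs; the trend test is the ordinal-index
Wald test; the Fisher enumeration is exact but refuses margins beyond its
budget (no Monte Carlo fallback yet); the no-information error of the 0.632+
procedure is fixed at the analytic γ = 0.5 rather than re-permutation; and
NRI/IDI p-values are asymptotic. The simulator's LD structure is block-wise
only, and its methylation covariance is a single shared factor plus
independent noise — adequate for calibration tests, far simpler than real
co-methylation.
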