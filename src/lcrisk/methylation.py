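"""Methylation risk score (MRS) from smoking-associated CpGs.

The score averages signed, reference-standardised deviations of methylation
beta-values:

    MRS_s = (1/n) * sum_c  W_c * (beta_cs - mu_c) / sigma_c

where the reference mean mu_c and sample standard deviation sigma_c are taken
over never smokers, and W_c is +1 for CpGs hypermethylated in smokers and -1
for hypomethylated ones. Positive scores therefore indicate a blood
methylation profile shifted in the smoking direction, in units of
never-smoker standard deviations averaged over the panel.

Annotation tables carry columns ``probe_id, chromosome, weight,
detection_fail_fraction, missing_fraction``; beta matrices are subjects x
probes DataFrames with values in [0, 1] (NaN = missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, DomainError, ZeroVarianceError

__all__ = ["ReferenceStats", "qc_filter_probes", "compute_reference_stats", "compute_mrs"]

_SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "23", "24"}


@dataclass(frozen=True)
class ReferenceStats:
    """Never-smoker reference distribution per probe (mean, sample SD, n)."""

    stats: pd.DataFrame  # index probe_id, columns mu / sigma / n_reference

    @property
    def mu(self) -> pd.Series:
        return self.stats["mu"]

    @property
    def sigma(self) -> pd.Series:
        return self.stats["sigma"]


def qc_filter_probes(betas: pd.DataFrame, annotation: pd.DataFrame,
                     detection_p_max: float = 0.05,
                     missing_max: float = 0.10,
                     strict_detection: bool = False) -> tuple[list[str], pd.DataFrame]:
    """Probe-level quality filters.

    Excludes probes on the sex chromosomes, probes whose missingness exceeds
    `missing_max`, and probes failing the detection criterion. Detection is
    consumed as a per-probe summary — the fraction of samples with detection
    p above the significance cut-off — and a probe is dropped when that
    fraction exceeds `detection_p_max` (any failure at all under
    ``strict_detection``). Returns kept probes in matrix column order and an
    exclusion log.
    """
    if not (0 < missing_max < 1):
        raise ConfigurationError("missing_max must lie in (0, 1)")
    ann = annotation.set_index("probe_id")
    missing = set(betas.columns) - set(ann.index)
    if missing:
        raise ConsistencyError(
            f"probes in beta matrix absent from annotation: {sorted(missing)[:5]}")
    kept, log = [], []
    for probe in betas.columns:
        chrom = str(ann.at[probe, "chromosome"])
        fail = float(ann.at[probe, "detection_fail_fraction"])
        miss = float(ann.at[probe, "missing_fraction"])
        if chrom in _SEX_CHROMOSOMES:
            log.append({"probe_id": probe, "reason": "sex chromosome", "value": chrom})
        elif (fail > 0) if strict_detection else (fail > detection_p_max):
            log.append({"probe_id": probe, "reason": "detection", "value": fail})
        elif miss > missing_max:
            log.append({"probe_id": probe, "reason": "missingness", "value": miss})
        else:
            kept.append(probe)
    return kept, pd.DataFrame(log, columns=["probe_id", "reason", "value"])


def compute_reference_stats(betas: pd.DataFrame, never_smoker_ids) -> ReferenceStats:
    """Per-probe mean and sample SD (n-1 denominator) among never smokers.

    Pairwise-complete: each probe uses its non-missing never-smoker values.
    Raises ZeroVarianceError naming the first probe whose reference values
    are constant, and DomainError when a probe has < 2 reference values.
    """
    ref = betas.loc[list(never_smoker_ids)]
    counts = ref.notna().sum()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])[:5]
        raise DomainError(f"probes with < 2 never-smoker values: {bad}")
    mu = ref.mean()
    sigma = ref.std(ddof=1)
    if (sigma == 0).any():
        bad = list(sigma.index[sigma == 0])
        raise ZeroVarianceError(f"zero never-smoker variance at probe {bad[0]!r}")
    return ReferenceStats(pd.DataFrame({"mu": mu, "sigma": sigma, "n_reference": counts}))


def compute_mrs(betas: pd.DataFrame, ref: ReferenceStats,
                annotation: pd.DataFrame,
                strict_missing: bool = False) -> tuple[pd.Series, pd.DataFrame]:
    """Methylation risk score per subject.

    Scores the probes present in `ref`; each subject's score averages
    W_c*(beta - mu)/sigma over that subject's non-missing probes, so partially
    missing subjects keep a comparable scale (use ``strict_missing=True`` to
    refuse any missingness instead). Subjects missing every probe get NaN.
    Returns the score series and a per-subject log with the probe count used.
    """
    ann = annotation.set_index("probe_id")
    probes = list(ref.stats.index)
    bad_w = set(ann.loc[probes, "weight"]) - {1, -1, 1.0, -1.0}
    if bad_w:
        raise DomainError(f"weights must be +1/-1, found {sorted(bad_w)}")
    b = betas[probes].astype(float)
    if ((b < 0) | (b > 1)).any().any():
        raise DomainError("beta values must lie in [0, 1]")
    w = ann.loc[probes, "weight"].astype(float)
    z = (b - ref.mu[probes]) / ref.sigma[probes]
    signed = z * w
    n_used = signed.notna().sum(axis=1)
    if strict_missing and (n_used < len(probes)).any():
        bad = list(n_used.index[n_used < len(probes)])[:5]
        raise DomainError(f"missing betas under strict mode for subjects {bad}")
    mrs = signed.mean(axis=1)  # skips NaN => renormalises by n_used
    mrs[n_used == 0] = np.nan
    mrs.name = "mrs"
    log = pd.DataFrame({"n_probes_used": n_used,
                        "flag": np.where(n_used == 0, "all probes missing", "")})
    return mrs, log
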