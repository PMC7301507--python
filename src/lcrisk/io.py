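"""Readers and writers for the pipeline's plain-text table formats.

Formats (all with a leading ``#`` comment line carrying the config hash):

* phenotypes.csv — one row per subject: demographics, smoking history,
  batch, six ``cf_<type>`` leukocyte fractions, case indicator.
* dosages.tsv — subjects x SNPs risk-allele dosages in {0,1,2}, NA missing.
* betas.tsv — subjects x probes methylation beta-values in [0,1], NA missing.
* snp_annotation.tsv / cpg_annotation.tsv — panel metadata.
* scores.csv, reference_stats.tsv — derived per-subject scores and the
  never-smoker reference distribution they standardise against.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParseError

_FLOAT_FMT = "%.10g"

PHENOTYPE_COLUMNS = [
    "age", "sex", "smoking_status", "cigs_per_day", "years_smoked",
    "years_since_quit", "pack_years", "case", "batch",
    "cf_neu", "cf_cd4t", "cf_cd8t", "cf_bcell", "cf_nk", "cf_mono",
]


def _write(df: pd.DataFrame, path: str, sep: str, header_comment: str,
           index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep, index=index, float_format=_FLOAT_FMT, na_rep="NA")


def write_phenotypes(subjects: pd.DataFrame, path: str, comment: str = "lcrisk") -> None:
    _write(subjects[PHENOTYPE_COLUMNS], path, ",", comment)


def write_matrix(matrix: pd.DataFrame, path: str, comment: str = "lcrisk") -> None:
    _write(matrix, path, "\t", comment)


def write_annotation(ann: pd.DataFrame, path: str, comment: str = "lcrisk") -> None:
    _write(ann, path, "\t", comment, index=False)


def write_table(df: pd.DataFrame, path: str, comment: str = "lcrisk") -> None:
    """Result tables (OR tables, prediction grid, ...) as comma-separated."""
    _write(df, path, ",", comment, index=False)


def write_scores(scores: pd.DataFrame, path: str, comment: str = "lcrisk") -> None:
    _write(scores, path, ",", comment)


def _read(path: str, sep: str, index_col=0) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ParseError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep=sep, comment="#", index_col=index_col,
                           na_values=["NA"])
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_phenotypes(path: str) -> pd.DataFrame:
    df = _read(path, ",")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_dosages(path: str) -> pd.DataFrame:
    df = _read(path, "\t")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: dosage {vals[i, j]!r} outside {{0,1,2,NA}} at "
            f"subject {df.index[i]!r}, SNP {df.columns[j]!r}")
    return df


def read_betas(path: str) -> pd.DataFrame:
    df = _read(path, "\t")
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if np.nansum(bad):
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: beta {vals[i, j]!r} outside [0,1] at "
            f"subject {df.index[i]!r}, probe {df.columns[j]!r}")
    return df


def read_annotation(path: str) -> pd.DataFrame:
    return _read(path, "\t", index_col=None)


def read_scores(path: str) -> pd.DataFrame:
    return _read(path, ",")


def load_inputs(phenotype_path: str, dosage_path: str, beta_path: str,
                snp_annotation_path: str, cpg_annotation_path: str) -> dict:
    """Read and cross-validate the five input tables.

    Enforces subject-ID agreement between the phenotype table and both
    matrices, and SNP/probe-ID coverage by the annotations. Returns a dict
    with keys subjects / genotypes / methylation / snp_annotation /
    cpg_annotation.
    """
    subjects = read_phenotypes(phenotype_path)
    genotypes = read_dosages(dosage_path)
    betas = read_betas(beta_path)
    snp_ann = read_annotation(snp_annotation_path)
    cpg_ann = read_annotation(cpg_annotation_path)

    for name, other in (("genotypes", genotypes), ("methylation", betas)):
        extra = other.index.difference(subjects.index)
        if len(extra):
            raise ConsistencyError(
                f"subjects in {name} absent from phenotypes: {list(extra[:5])}")
        missing = subjects.index.difference(other.index)
        if len(missing):
            raise ConsistencyError(
                f"subjects missing from {name}: {list(missing[:5])}")
    bad_snps = set(genotypes.columns) - set(snp_ann["snp_id"])
    if bad_snps:
        raise ConsistencyError(f"unannotated SNPs: {sorted(bad_snps)[:5]}")
    bad_probes = set(betas.columns) - set(cpg_ann["probe_id"])
    if bad_probes:
        raise ConsistencyError(f"unannotated probes: {sorted(bad_probes)[:5]}")
    return {
        "subjects": subjects,
        "genotypes": genotypes.loc[subjects.index],
        "methylation": betas.loc[subjects.index],
        "snp_annotation": snp_ann,
        "cpg_annotation": cpg_ann,
    }
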