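"""Pipeline configuration and stage orchestration.

Stages: ``simulate`` (synthetic cohort to disk), ``scores`` (SNP/probe QC,
LD pruning, GRS + MRS), ``associate`` (baseline tests, quartile and joint
OR tables), ``predict`` (AUC / 0.632+ / NRI / IDI grid). ``run_all`` chains
them and writes a manifest from which any output is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import pandas as pd
import yaml

from . import __version__, association, genetics, io, methylation, prediction
from .cohort_sim import SimConfig, simulate_cohort
from .errors import ConfigurationError, DependencyError

__all__ = ["PipelineConfig", "run_simulate", "run_scores", "run_associate",
           "run_predict", "run_all"]


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline, with validated domains.

    Defaults mirror the published analysis: 10% SNP/probe missingness caps,
    0.5% MAF floor, D' >= 0.95 & r² >= 0.80 within 200 kb for pruning, 5%
    NRI threshold, 1000 bootstrap replications, type-7 quantiles, Wald CIs.
    """

    seed: int = 0
    outdir: str = "lcrisk_out"
    sim: dict = dataclasses.field(default_factory=dict)

    snp_missing_max: float = 0.10
    maf_min: float = 0.005
    dprime_min: float = 0.95
    r2_min: float = 0.80
    window_bp: int = 200_000
    detection_p_max: float = 0.05
    probe_missing_max: float = 0.10
    nri_threshold: float = 0.05
    bootstrap_B: int = 1000
    quantile_method: str = "linear"  # type-7 empirical percentiles
    ci_method: str = "wald"

    def __post_init__(self):
        for name in ("snp_missing_max", "maf_min", "dprime_min", "r2_min",
                     "detection_p_max", "probe_missing_max", "nri_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name}={v} outside (0, 1)")
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be positive")
        if self.bootstrap_B < 1:
            raise ConfigurationError("bootstrap_B must be >= 1")
        if self.quantile_method != "linear":
            raise ConfigurationError("only the type-7 'linear' quantile rule is implemented")
        if self.ci_method != "wald":
            raise ConfigurationError("only Wald confidence intervals are implemented")
        if not isinstance(self.sim, dict):
            raise ConfigurationError("sim must be a mapping of SimConfig overrides")
        known = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(self.sim) - known
        if unknown:
            raise ConfigurationError(f"unknown sim keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _comment(cfg: PipelineConfig) -> str:
    return f"lcrisk config_hash={cfg.config_hash()} seed={cfg.seed}"


def _require(path: str, producer: str) -> str:
    if not os.path.exists(path):
        raise DependencyError(f"missing {path}; run the '{producer}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig) -> dict:
    os.makedirs(cfg.outdir, exist_ok=True)
    subjects, genotypes, betas, snp_ann, cpg_ann = simulate_cohort(cfg.sim_config())
    c = _comment(cfg)
    io.write_phenotypes(subjects, os.path.join(cfg.outdir, "phenotypes.csv"), c)
    io.write_matrix(genotypes, os.path.join(cfg.outdir, "dosages.tsv"), c)
    io.write_matrix(betas, os.path.join(cfg.outdir, "betas.tsv"), c)
    io.write_annotation(snp_ann, os.path.join(cfg.outdir, "snp_annotation.tsv"), c)
    io.write_annotation(cpg_ann, os.path.join(cfg.outdir, "cpg_annotation.tsv"), c)
    return {"n_subjects": len(subjects), "n_cases": int(subjects["case"].sum())}


def _load(cfg: PipelineConfig) -> dict:
    d = cfg.outdir
    return io.load_inputs(
        _require(os.path.join(d, "phenotypes.csv"), "simulate"),
        _require(os.path.join(d, "dosages.tsv"), "simulate"),
        _require(os.path.join(d, "betas.tsv"), "simulate"),
        _require(os.path.join(d, "snp_annotation.tsv"), "simulate"),
        _require(os.path.join(d, "cpg_annotation.tsv"), "simulate"),
    )


def run_scores(cfg: PipelineConfig) -> dict:
    data = _load(cfg)
    subjects = data["subjects"]
    genotypes = data["genotypes"]
    c = _comment(cfg)

    kept, snp_log = genetics.qc_filter_snps(
        genotypes, data["snp_annotation"],
        missing_max=cfg.snp_missing_max, maf_min=cfg.maf_min)
    ranks = genetics.univariate_assoc_rank(genotypes[kept], subjects["case"])
    ann = data["snp_annotation"].copy()
    ann["assoc_rank"] = ann["snp_id"].map(ranks)
    retained = genetics.ld_prune(
        ann[ann["snp_id"].isin(kept)], genotypes[kept],
        window_bp=cfg.window_bp, dprime_min=cfg.dprime_min, r2_min=cfg.r2_min)
    grs, _ = genetics.compute_grs(genotypes, retained)

    probes, probe_log = methylation.qc_filter_probes(
        data["methylation"], data["cpg_annotation"],
        detection_p_max=cfg.detection_p_max, missing_max=cfg.probe_missing_max)
    never = subjects.index[subjects["smoking_status"] == "never"]
    ref = methylation.compute_reference_stats(data["methylation"][probes], never)
    mrs, _ = methylation.compute_mrs(data["methylation"], ref, data["cpg_annotation"])

    scores = pd.DataFrame({"grs": grs, "mrs": mrs})
    io.write_scores(scores, os.path.join(cfg.outdir, "scores.csv"), c)
    io._write(ref.stats.rename_axis("probe_id"),
              os.path.join(cfg.outdir, "reference_stats.tsv"), "\t", c)
    io.write_annotation(snp_log, os.path.join(cfg.outdir, "snp_exclusions.tsv"), c)
    io.write_annotation(probe_log, os.path.join(cfg.outdir, "probe_exclusions.tsv"), c)
    with open(os.path.join(cfg.outdir, "retained_snps.txt"), "w") as fh:
        fh.write(f"# {c}\n" + "\n".join(retained) + "\n")
    return {"n_snps_retained": len(retained), "n_probes_scored": len(probes)}


def _subjects_with_scores(cfg: PipelineConfig) -> pd.DataFrame:
    data = io.read_phenotypes(
        _require(os.path.join(cfg.outdir, "phenotypes.csv"), "simulate"))
    scores = io.read_scores(
        _require(os.path.join(cfg.outdir, "scores.csv"), "scores"))
    return data.join(scores)


def run_associate(cfg: PipelineConfig) -> dict:
    sub = _subjects_with_scores(cfg)
    c = _comment(cfg)
    case = sub["case"] == 1

    # baseline-characteristics hypothesis tests
    tests = []
    for col in ("age", "pack_years"):
        p = association.wilcoxon_rank_sum(sub.loc[case, col].dropna(),
                                          sub.loc[~case, col].dropna())
        tests.append({"characteristic": col, "test": "wilcoxon", "p": p})
    sex_tab = pd.crosstab(sub["case"], sub["sex"]).loc[[1, 0]].to_numpy()
    tests.append({"characteristic": "sex", "test": "fisher",
                  "p": association.fisher_exact_2xk(sex_tab)})
    smk_tab = pd.crosstab(sub["case"], sub["smoking_status"]).loc[[1, 0]].to_numpy()
    tests.append({"characteristic": "smoking_status", "test": "fisher",
                  "p": association.fisher_exact_2xk(smk_tab)})
    for score in ("grs", "mrs"):
        _, bins = association.control_quartile_bins(sub[score], ~case)
        tab = pd.crosstab(sub["case"], bins).loc[[1, 0]].to_numpy()
        tests.append({"characteristic": f"{score}_quartiles", "test": "fisher",
                      "p": association.fisher_exact_2xk(tab)})
    io.write_table(pd.DataFrame(tests),
                   os.path.join(cfg.outdir, "table1_tests.csv"), c)

    t2 = pd.concat([
        association.quartile_or_table(sub, score, model, population)
        for population in ("all", "ever", "heavy")
        for score in ("grs", "mrs") for model in (1, 2, 3)
    ], ignore_index=True)
    io.write_table(t2, os.path.join(cfg.outdir, "table2_quartile_or.csv"), c)

    t3 = pd.concat([
        association.joint_group_or_table(sub, model, population)
        for population in ("all", "ever", "heavy") for model in (1, 2, 3)
    ], ignore_index=True)
    io.write_table(t3, os.path.join(cfg.outdir, "table3_joint_or.csv"), c)
    return {"n_or_rows": len(t2) + len(t3)}


def run_predict(cfg: PipelineConfig) -> dict:
    sub = _subjects_with_scores(cfg)
    c = _comment(cfg)
    reports = prediction.evaluate_table4(sub, seed=cfg.seed, B=cfg.bootstrap_B)
    frame = prediction.table4_frame(reports)
    io.write_table(frame, os.path.join(cfg.outdir, "table4_prediction.csv"), c)

    conf_rows, curves = [], []
    for r in reports:
        conf_rows.append({"population": r.spec.population,
                          "predictors": r.spec.name, **r.confusion})
        cur = r.pr_curve.copy()
        cur.insert(0, "predictors", r.spec.name)
        cur.insert(0, "population", r.spec.population)
        curves.append(cur)
    io.write_table(pd.DataFrame(conf_rows),
                   os.path.join(cfg.outdir, "confusion_matrices.csv"), c)
    io.write_table(pd.concat(curves, ignore_index=True),
                   os.path.join(cfg.outdir, "pr_curves.csv"), c)
    json_path = os.path.join(cfg.outdir, "table4_prediction.json")
    with open(json_path, "w") as fh:
        json.dump(json.loads(frame.to_json(orient="records")), fh, indent=1)
    return {"n_models": len(reports)}


def run_all(cfg: PipelineConfig) -> dict:
    info = {}
    info.update(run_simulate(cfg))
    info.update(run_scores(cfg))
    info.update(run_associate(cfg))
    info.update(run_predict(cfg))
    manifest = {
        "package": "lcrisk",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if k != "outdir"},
        "outputs": {},
        "summary": info,
    }
    for name in sorted(os.listdir(cfg.outdir)):
        path = os.path.join(cfg.outdir, name)
        if os.path.isfile(path) and name != "manifest.json":
            with open(path, "rb") as fh:
                manifest["outputs"][name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return info
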