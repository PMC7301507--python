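"""Predictive-performance evaluation for risk-score models.

Covers the rank-based (Mann-Whitney) AUC with DeLong confidence intervals,
the Efron-Tibshirani 0.632+ bootstrap optimism correction, continuous net
reclassification improvement (NRI) with a minimum-change threshold,
integrated discrimination improvement (IDI), confusion matrices and
precision-recall curves, and the full evaluation grid of seven predictor
sets (GRS, MRS, pack-years and their combinations) across three analysis
populations (all participants, ever smokers, heavy smokers).

NRI and IDI compare each combined model (pack-years plus score(s)) against
the pack-years-only baseline, which is the clinically relevant increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import expit

from .association import LogisticFit, _population_mask, fit_logistic
from .errors import ClassError, DomainError
from sklearn.metrics import precision_recall_curve

__all__ = [
    "PredictorSpec",
    "PredictionReport",
    "auc_mann_whitney",
    "fit_and_score",
    "auc_632plus",
    "continuous_nri",
    "idi",
    "confusion_and_pr",
    "evaluate_table4",
    "table4_frame",
    "PREDICTOR_SETS",
    "POPULATIONS",
]

_Z = 1.959963984540054

POPULATIONS = ("all", "ever", "heavy")

#: the seven predictor sets of the evaluation grid, in display order
PREDICTOR_SETS = (
    ("GRS", ("grs",)),
    ("MRS", ("mrs",)),
    ("GRS + MRS", ("grs", "mrs")),
    ("Pack-years", ("pack_years",)),
    ("Pack-years + GRS", ("pack_years", "grs")),
    ("Pack-years + MRS", ("pack_years", "mrs")),
    ("Pack-years + GRS + MRS", ("pack_years", "grs", "mrs")),
)


@dataclass(frozen=True)
class PredictorSpec:
    """One model of the evaluation grid: named predictor columns + population."""

    name: str
    predictors: tuple[str, ...]
    population: str = "all"

    def __post_init__(self):
        if not self.predictors:
            raise DomainError("predictor list must be non-empty")


@dataclass
class PredictionReport:
    """Per-model performance summary."""

    spec: PredictorSpec
    n_cases: int
    n_controls: int
    apparent_auc: float
    apparent_ci: tuple[float, float]
    auc_632plus: float
    B: int
    nri: dict | None = None
    idi: dict | None = None
    confusion: dict = field(default_factory=dict, repr=False)
    pr_curve: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ClassError("both outcome classes must be present")


def auc_mann_whitney(scores, labels) -> tuple[float, float, float]:
    """Rank-based AUC with a DeLong 95% confidence interval.

    AUC is the probability a random case outscores a random control, ties
    counted one half; the variance uses DeLong's case/control placement
    decomposition. Returns (auc, ci_low, ci_high), CI clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    # placements: V10_i = P(case_i > control) with ties half, via midranks
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:n1] - pos_ranks) / n0
    v01 = 1.0 - (all_ranks[n1:] - neg_ranks) / n1
    auc = float(v10.mean())
    if n1 > 1 and n0 > 1:
        var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    else:
        var = 0.0
    half = _Z * np.sqrt(var)
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


# ---------------------------------------------------------------------------
# model fitting / scoring
# ---------------------------------------------------------------------------

def _predict(fit: LogisticFit, X: pd.DataFrame) -> np.ndarray:
    eta = fit.params["const"] + X[fit.params.index.drop("const")].to_numpy() @ \
        fit.params.drop("const").to_numpy()
    return expit(np.asarray(eta, dtype=float))


def _complete_cases(subjects: pd.DataFrame, spec: PredictorSpec):
    mask = _population_mask(subjects, spec.population)
    sub = subjects[mask]
    cols = list(spec.predictors)
    keep = sub["case"].notna() & sub[cols].notna().all(axis=1)
    sub = sub[keep]
    return sub["case"].astype(float), sub[cols].astype(float)


def fit_and_score(subjects: pd.DataFrame, spec: PredictorSpec):
    """Logistic fit of case status on the spec's predictors (complete cases).

    Returns (fitted probabilities indexed by subject, LogisticFit). By the
    maximum-likelihood score equation the probabilities average to the case
    fraction.
    """
    y, X = _complete_cases(subjects, spec)
    fit = fit_logistic(y, X)
    return pd.Series(_predict(fit, X), index=X.index, name="p_hat"), fit


def auc_632plus(subjects: pd.DataFrame, spec: PredictorSpec, B: int = 1000,
                seed=0) -> dict:
    """0.632+ bootstrap optimism-corrected AUC for one predictor set.

    Works on the error scale err = 1 - AUC. The apparent error comes from the
    full-data fit; the out-of-bag error averages, over B case/control-
    stratified bootstrap refits, the AUC evaluated on each replicate's
    out-of-bag subjects. With no-information error gamma = 0.5 (rank AUC
    under label independence), the relative overfitting rate

        R = (err_oob - err_app) / (gamma - err_app), clipped to [0, 1],

    weights the blend w = 0.632 / (1 - 0.368 R) and

        err_632+ = (1 - w) * err_app + w * min(err_oob, gamma).

    Replicates whose resample or out-of-bag set lacks a class are redrawn
    (counted in the output, at most 10B attempts). Replicate r draws from
    substream (seed, r), so increasing B keeps earlier replicates intact.
    """
    if B < 1:
        raise DomainError("B must be >= 1")
    y, X = _complete_cases(subjects, spec)
    yv = y.to_numpy()
    _check_two_classes(yv)
    fit = fit_logistic(y, X)
    p_full = _predict(fit, X)
    auc_app, ci_lo, ci_hi = auc_mann_whitney(p_full, yv)
    err_app = 1.0 - auc_app

    case_idx = np.flatnonzero(yv == 1)
    ctrl_idx = np.flatnonzero(yv == 0)
    n = len(yv)
    Xv = X.reset_index(drop=True)
    ys = pd.Series(yv)

    oob_errs = []
    redrawn = 0
    seed_base = [seed] if np.isscalar(seed) else list(seed)
    for r in range(B):
        for attempt in range(10):
            rng = np.random.default_rng(seed_base + [r, attempt])
            boot = np.concatenate([
                rng.choice(case_idx, size=len(case_idx), replace=True),
                rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
            ])
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) == 0 or len(np.unique(yv[oob])) < 2:
                redrawn += 1
                continue
            try:
                bfit = fit_logistic(ys.iloc[boot].reset_index(drop=True),
                                    Xv.iloc[boot].reset_index(drop=True))
            except Exception:
                redrawn += 1
                continue
            p_oob = _predict(bfit, Xv.iloc[oob])
            a, _, _ = auc_mann_whitney(p_oob, yv[oob])
            oob_errs.append(1.0 - a)
            break
        else:
            raise ClassError(f"bootstrap replicate {r}: no valid resample in 10 attempts")

    err_oob = float(np.mean(oob_errs))
    gamma = 0.5
    if err_oob <= err_app or gamma <= err_app:
        R = 0.0
    else:
        R = min((err_oob - err_app) / (gamma - err_app), 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    err_632 = (1.0 - w) * err_app + w * min(err_oob, gamma)
    return {
        "apparent_auc": auc_app, "apparent_ci": (ci_lo, ci_hi),
        "auc_oob": 1.0 - err_oob, "auc_632plus": 1.0 - err_632,
        "R": R, "w": w, "B": B, "replicates_redrawn": redrawn,
        "n_cases": int((yv == 1).sum()), "n_controls": int((yv == 0).sum()),
    }


# ---------------------------------------------------------------------------
# reclassification / discrimination increments
# ---------------------------------------------------------------------------

def _nri_idi_inputs(p_base, p_new, labels):
    pb = np.asarray(p_base, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    y = np.asarray(labels)
    if pb.shape != pn.shape or pb.shape != y.shape:
        raise DomainError("probability vectors and labels must align")
    if np.any((pb < 0) | (pb > 1) | (pn < 0) | (pn > 1)):
        raise DomainError("probabilities must lie in [0, 1]")
    if not (y == 1).any() or not (y == 0).any():
        raise ClassError("both events and non-events are required")
    return pb, pn, y


def continuous_nri(p_base, p_new, labels, threshold: float = 0.05) -> dict:
    """Continuous NRI counting only moves larger than `threshold` (strict).

    up/down = predicted risk rising/falling by more than the threshold;
    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)].
    The p-value is the asymptotic z-test with
    SE = sqrt((P(up|e)+P(down|e))/n_e + (P(up|ne)+P(down|ne))/n_ne).
    """
    pb, pn, y = _nri_idi_inputs(p_base, p_new, labels)
    d = pn - pb
    up, down = d > threshold, d < -threshold
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    p_up_e, p_dn_e = up[ev].mean(), down[ev].mean()
    p_up_ne, p_dn_ne = up[ne].mean(), down[ne].mean()
    nri_e = p_up_e - p_dn_e
    nri_ne = p_dn_ne - p_up_ne
    nri = nri_e + nri_ne
    se = np.sqrt((p_up_e + p_dn_e) / n_e + (p_up_ne + p_dn_ne) / n_ne)
    z = nri / se if se > 0 else 0.0
    return {"nri": float(nri), "nri_events": float(nri_e),
            "nri_nonevents": float(nri_ne), "se": float(se), "z": float(z),
            "p": float(2 * sps.norm.sf(abs(z))) if se > 0 else 1.0}


def idi(p_base, p_new, labels) -> dict:
    """Integrated discrimination improvement between two models.

    IDI = [mean(p_new|event) - mean(p_base|event)]
        - [mean(p_new|nonevent) - mean(p_base|nonevent)],
    i.e. the change in discrimination slope. The z-test combines the standard
    errors of the within-class paired differences in quadrature.
    """
    pb, pn, y = _nri_idi_inputs(p_base, p_new, labels)
    ev, ne = y == 1, y == 0
    d_e = pn[ev] - pb[ev]
    d_ne = pn[ne] - pb[ne]
    idi_val = d_e.mean() - d_ne.mean()
    se_e = d_e.std(ddof=1) / np.sqrt(len(d_e)) if len(d_e) > 1 else 0.0
    se_ne = d_ne.std(ddof=1) / np.sqrt(len(d_ne)) if len(d_ne) > 1 else 0.0
    se = float(np.sqrt(se_e ** 2 + se_ne ** 2))
    z = idi_val / se if se > 0 else 0.0
    return {"idi": float(idi_val), "se": se, "z": float(z),
            "p": float(2 * sps.norm.sf(abs(z))) if se > 0 else 1.0}


def confusion_and_pr(probabilities, labels, threshold: float) -> dict:
    """Confusion matrix at a probability threshold plus the full PR curve.

    Predicted positive means probability >= threshold. Precision at zero
    predicted positives is reported as 1 by convention (flagged in the
    output). PR curve points sweep all distinct probability cut-offs.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    if not (0 < threshold < 1):
        raise DomainError("threshold must lie in (0, 1)")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    zero_pos = (tp + fp) == 0
    precision = 1.0 if zero_pos else tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    prec, rec, thr = precision_recall_curve(y, p)
    curve = pd.DataFrame({"precision": prec, "recall": rec,
                          "threshold": np.append(thr, np.nan)})
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": float(precision), "recall": float(recall),
            "f1": float(f1), "threshold": float(threshold),
            "precision_undefined": bool(zero_pos), "pr_curve": curve}


# ---------------------------------------------------------------------------
# the full evaluation grid
# ---------------------------------------------------------------------------

def evaluate_table4(subjects: pd.DataFrame, seed: int = 0, B: int = 1000,
                    populations=POPULATIONS) -> list[PredictionReport]:
    """Evaluate every (population x predictor set) cell of the grid.

    For each population, the seven predictor sets are fitted and scored;
    apparent and 0.632+ corrected AUCs are reported for all, while NRI and
    IDI are computed only for the pack-years-plus-score models against the
    pack-years-only baseline. The confusion matrix uses the population's case
    prevalence as the default probability threshold.
    """
    reports: list[PredictionReport] = []
    for pi, population in enumerate(populations):
        base_spec = PredictorSpec("Pack-years", ("pack_years",), population)
        p_base, _ = fit_and_score(subjects, base_spec)
        for si, (name, cols) in enumerate(PREDICTOR_SETS):
            spec = PredictorSpec(name, cols, population)
            res = auc_632plus(subjects, spec, B=B, seed=(seed, pi, si))
            p_new, _ = fit_and_score(subjects, spec)
            y = subjects.loc[p_new.index, "case"].astype(int).to_numpy()
            nri_d = idi_d = None
            if "pack_years" in cols and set(cols) != {"pack_years"}:
                common = p_new.index.intersection(p_base.index)
                yc = subjects.loc[common, "case"].astype(int).to_numpy()
                nri_d = continuous_nri(p_base.loc[common], p_new.loc[common], yc)
                idi_d = idi(p_base.loc[common], p_new.loc[common], yc)
            prevalence = float(y.mean())
            conf = confusion_and_pr(p_new.to_numpy(), y, threshold=prevalence)
            curve = conf.pop("pr_curve")
            reports.append(PredictionReport(
                spec=spec, n_cases=res["n_cases"], n_controls=res["n_controls"],
                apparent_auc=res["apparent_auc"], apparent_ci=res["apparent_ci"],
                auc_632plus=res["auc_632plus"], B=B,
                nri=nri_d, idi=idi_d, confusion=conf, pr_curve=curve))
    return reports


def table4_frame(reports: list[PredictionReport]) -> pd.DataFrame:
    """Tidy one-row-per-model frame of the evaluation grid (NRI/IDI in %)."""
    rows = []
    for r in reports:
        rows.append({
            "population": r.spec.population, "predictors": r.spec.name,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
            "auc_apparent": r.apparent_auc,
            "auc_ci_low": r.apparent_ci[0], "auc_ci_high": r.apparent_ci[1],
            "auc_632plus": r.auc_632plus, "B": r.B,
            "nri_pct": 100 * r.nri["nri"] if r.nri else np.nan,
            "nri_p": r.nri["p"] if r.nri else np.nan,
            "idi_pct": 100 * r.idi["idi"] if r.idi else np.nan,
            "idi_p": r.idi["p"] if r.idi else np.nan,
        })
    return pd.DataFrame(rows)
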