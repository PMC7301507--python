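"""Case-control association analysis for genetic and methylation risk scores.

Implements the derived smoking variables (pack-years, ever/heavy smoker
classification), control-based quartile binning, the three covariate-adjustment
logistic models with odds-ratio tables and trend tests, and the baseline-table
hypothesis tests (2xK Fisher exact, Wilcoxon rank-sum).

Covariate-adjustment models
---------------------------
model 1 : no covariates for the GRS; batch (3 levels) + leukocyte composition
          for the MRS (and for the joint GRS/MRS groups).
model 2 : model 1 + age + sex.
model 3 : model 2 + smoking status (never/former vs current) + pack-years.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from scipy.special import gammaln

from .errors import (
    ClassError,
    ConsistencyError,
    DegenerateBinningError,
    DesignError,
    DomainError,
    FeasibilityError,
    SeparationError,
)

__all__ = [
    "QuartileBinning",
    "LogisticFit",
    "compute_pack_years",
    "classify_smoking",
    "control_quartile_bins",
    "fit_logistic",
    "fit_logistic_from_counts",
    "quartile_or_table",
    "joint_group_or_table",
    "fisher_exact_2xk",
    "wilcoxon_rank_sum",
]

#: per-SD log-odds magnitude beyond which we declare (quasi-)separation;
#: scale-aware so small-scale covariates (e.g. cell fractions) with
#: legitimately large raw coefficients are not misflagged
_SEPARATION_PER_SD = 15.0


# ---------------------------------------------------------------------------
# derived smoking variables
# ---------------------------------------------------------------------------

def compute_pack_years(cigs_per_day, years_smoked):
    """Lifetime cumulative smoking dose: (cigarettes/day / 20) x years smoked.

    One pack-year is one pack (20 cigarettes) per day for one year. Accepts
    scalars or aligned array-likes; NaN propagates.
    """
    c = np.asarray(cigs_per_day, dtype=float)
    y = np.asarray(years_smoked, dtype=float)
    if np.nanmin(c, initial=0.0) < 0 or np.nanmin(y, initial=0.0) < 0:
        raise DomainError("cigs_per_day and years_smoked must be non-negative")
    out = (c / 20.0) * y
    if out.ndim == 0:
        return float(out)
    return out


def classify_smoking(subjects: pd.DataFrame) -> pd.DataFrame:
    """Derive ever/heavy smoker flags from smoking history columns.

    ever  : former or current smoker.
    heavy : >= 30 pack-years AND (current smoker OR quit <= 15 years ago);
            both thresholds inclusive. This is the eligibility definition used
            for low-dose CT screening of high-risk smokers.

    Requires columns ``smoking_status`` in {never, former, current},
    ``pack_years`` and ``years_since_quit`` (NaN for never smokers, 0 for
    current). Rows with missing smoking_status get NA flags. Raises
    ConsistencyError for a never smoker with positive pack-years.
    """
    status = subjects["smoking_status"]
    bad = (status == "never") & (subjects["pack_years"].fillna(0) > 0)
    if bad.any():
        raise ConsistencyError(
            f"never smokers with pack_years > 0: {list(subjects.index[bad])[:5]}"
        )
    ever = status.isin(["former", "current"])
    recency = (status == "current") | (
        (status == "former") & (subjects["years_since_quit"] <= 15)
    )
    heavy = (subjects["pack_years"] >= 30) & recency
    out = pd.DataFrame({"ever": ever, "heavy": heavy}, index=subjects.index)
    out[status.isna()] = pd.NA
    return out


# ---------------------------------------------------------------------------
# quartile binning among controls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuartileBinning:
    """Quartile cut-points of a risk score computed among controls.

    Bin j covers [cut_{j-1}, cut_j) with Q1 = (-inf, q25) and Q4 = [q75, inf),
    mirroring the "Q1 (< 24) ... Q4 (>= 30)" convention of the published
    tables. Cut-points use the linear-interpolation ("type 7") empirical
    percentile.
    """

    score_name: str
    cutpoints: tuple[float, float, float]
    labels: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")

    def assign(self, scores) -> pd.Series:
        """Map scores to integer bins 1..4 (NaN stays NaN)."""
        s = pd.Series(scores, dtype=float)
        bins = np.searchsorted(np.asarray(self.cutpoints), s.to_numpy(), side="right") + 1.0
        bins[s.isna().to_numpy()] = np.nan
        return pd.Series(bins, index=s.index, name=f"{self.score_name}_bin")


def control_quartile_bins(scores, control_mask) -> tuple[QuartileBinning, pd.Series]:
    """Quartile-bin a score using cut-points from the controls only.

    Returns the binning object and the per-subject integer bin (1..4).
    Raises DegenerateBinningError when the control scores admit no split.
    """
    s = pd.Series(scores, dtype=float)
    mask = np.asarray(control_mask, dtype=bool)
    ctrl = s[mask].dropna()
    if len(ctrl) < 4:
        raise DegenerateBinningError("need at least 4 controls with finite scores")
    cuts = tuple(float(np.quantile(ctrl, q, method="linear")) for q in (0.25, 0.50, 0.75))
    if cuts[0] == cuts[2]:
        raise DegenerateBinningError(
            f"control {s.name or 'score'} quartile cut-points collapse at {cuts[0]}"
        )
    binning = QuartileBinning(score_name=str(s.name or "score"), cutpoints=cuts)
    return binning, binning.assign(s)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic fit.

    Coefficients are on the log-odds scale; `cov` is the inverse observed
    information (Wald covariance). `n_used` counts complete-case rows (sum of
    frequency weights when supplied).
    """

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool
    n_used: float
    fitted: pd.Series = field(repr=False, default=None)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def odds_ratio(self, name: str, z: float = 1.959963984540054):
        """(OR, CI low, CI high) for one coefficient via exp(coef +/- z*SE)."""
        b = self.params[name]
        s = self.se()[name]
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))

    def wald_p(self, name: str) -> float:
        z = self.params[name] / self.se()[name]
        return float(2.0 * sps.norm.sf(abs(z)))


def fit_logistic(outcome, design: pd.DataFrame, add_constant: bool = True,
                 freq_weights=None) -> LogisticFit:
    """Maximum-likelihood logistic regression with complete-case handling.

    Parameters
    ----------
    outcome : binary (0/1) series aligned with `design`.
    design : covariate matrix WITHOUT an intercept column unless
        ``add_constant=False``.
    freq_weights : optional frequency weights (grouped-data fits).

    Raises SeparationError instead of returning silently huge coefficients,
    and DesignError for a rank-deficient design.
    """
    y = pd.Series(outcome).astype(float)
    X = pd.DataFrame(design).astype(float)
    if not y.index.equals(X.index):
        X = X.loc[y.index]
    w = None if freq_weights is None else pd.Series(freq_weights, index=y.index, dtype=float)

    keep = y.notna() & X.notna().all(axis=1)
    if w is not None:
        keep &= w.notna()
    y, X = y[keep], X[keep]
    if w is not None:
        w = w[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    if len(set(np.unique(y))) < 2:
        raise ClassError("outcome has a single class after complete-case filtering")

    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError(f"design matrix is rank deficient (columns: {list(X.columns)})")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc

    scale = X.std(ddof=0).to_numpy()  # 0 for the constant column
    per_sd = np.abs(res.params.to_numpy()) * scale
    if not res.converged or np.max(per_sd) > _SEPARATION_PER_SD:
        raise SeparationError(
            "perfect or quasi-perfect separation detected "
            f"(max per-SD |coef| = {np.max(per_sd):.1f})"
        )
    n_used = float(len(y) if w is None else w.sum())
    return LogisticFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        llf=float(res.llf),
        converged=bool(res.converged),
        n_used=n_used,
        fitted=pd.Series(res.fittedvalues, index=y.index),
    )


def fit_logistic_from_counts(cases, controls) -> LogisticFit:
    """Unadjusted quartile (or any K-level) logistic fit from a 2xK count table.

    `cases` and `controls` are per-level counts with the first level as
    reference. Equivalent to an individual-level fit of case status on level
    dummies, using frequency weights; exp(coefficients) are the stratified
    cross-product odds ratios.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    k = len(cases)
    if len(controls) != k or k < 2:
        raise DomainError("cases and controls must be equal-length with K >= 2")
    rows, ys, ws = [], [], []
    for j in range(k):
        dummies = [1.0 if i == j else 0.0 for i in range(1, k)]
        rows += [dummies, dummies]
        ys += [1.0, 0.0]
        ws += [cases[j], controls[j]]
    X = pd.DataFrame(rows, columns=[f"level_{i + 1}" for i in range(1, k)])
    return fit_logistic(pd.Series(ys), X, freq_weights=pd.Series(ws))


# ---------------------------------------------------------------------------
# model covariates (shared by the OR tables and the prediction module)
# ---------------------------------------------------------------------------

def cell_fraction_columns(subjects: pd.DataFrame) -> list[str]:
    """Leukocyte-composition covariates: all but one cell fraction.

    The fractions sum to one, so one type (neutrophils when present, else the
    first alphabetically) is dropped as the reference to keep the design
    full-rank.
    """
    cols = sorted(c for c in subjects.columns if c.startswith("cf_"))
    if not cols:
        return []
    ref = "cf_neu" if "cf_neu" in cols else cols[0]
    return [c for c in cols if c != ref]


def model_covariates(subjects: pd.DataFrame, model: int,
                     technical: bool) -> pd.DataFrame:
    """Covariate block for adjustment model 1, 2 or 3.

    `technical=True` adds batch dummies + leukocyte composition (used for MRS
    and joint-group models); the GRS model 1 has no covariates at all.
    Smoking status enters model 3 as a single indicator for current smoking
    (never/former pooled as the reference).
    """
    if model not in (1, 2, 3):
        raise DomainError(f"model must be 1, 2 or 3, got {model!r}")
    parts = []
    if technical:
        if "batch" in subjects:
            parts.append(pd.get_dummies(subjects["batch"], prefix="batch",
                                        drop_first=True, dtype=float))
        cells = cell_fraction_columns(subjects)
        if cells:
            parts.append(subjects[cells].astype(float))
    if model >= 2:
        parts.append(pd.DataFrame({
            "age": subjects["age"].astype(float),
            "male": (subjects["sex"] == "male").astype(float),
        }))
    if model >= 3:
        current = subjects["smoking_status"].map(
            {"never": 0.0, "former": 0.0, "current": 1.0})
        parts.append(pd.DataFrame({
            "current_smoker": current,
            "pack_years": subjects["pack_years"].astype(float),
        }))
    if not parts:
        return pd.DataFrame(index=subjects.index)
    return pd.concat(parts, axis=1)


def _population_mask(subjects: pd.DataFrame, population: str) -> pd.Series:
    if population == "all":
        return pd.Series(True, index=subjects.index)
    flags = classify_smoking(subjects)
    if population not in ("ever", "heavy"):
        raise DomainError(f"population must be all/ever/heavy, got {population!r}")
    return flags[population].fillna(False).astype(bool)


# ---------------------------------------------------------------------------
# OR tables
# ---------------------------------------------------------------------------

def quartile_or_table(subjects: pd.DataFrame, score: str, model: int,
                      population: str = "all") -> pd.DataFrame:
    """Quartile odds-ratio table for one risk score, one adjustment model.

    The score column (e.g. ``grs`` or ``mrs``) is binned by quartiles among
    the analysis population's controls (Q1 reference); the logistic model adds
    the adjustment-model covariates (technical covariates for the MRS only,
    matching the published convention). The trend p-value refits with the
    ordinal bin index 1..4 in place of the dummies.

    Returns one row per quartile with counts, OR and 95% Wald CI, plus the
    trend p and the complete-case n. A quartile with an empty case or control
    cell is reported non-estimable rather than dropped.
    """
    mask = _population_mask(subjects, population)
    sub = subjects[mask]
    binning, bins = control_quartile_bins(sub[score], sub["case"] == 0)
    keep = bins.notna() & sub["case"].notna()
    sub, bins = sub[keep], bins[keep]

    covs = model_covariates(sub, model, technical=(score == "mrs"))
    dummies = pd.DataFrame(
        {f"{score}_q{j}": (bins == j).astype(float) for j in (2, 3, 4)},
        index=sub.index)
    design = pd.concat([dummies, covs], axis=1)

    counts = pd.crosstab(bins, sub["case"]).reindex(
        index=[1.0, 2.0, 3.0, 4.0], columns=[0, 1], fill_value=0)
    estimable = (counts[1] > 0).all() and (counts[0] > 0).all()

    rows = []
    fit = trend_p = None
    if estimable:
        fit = fit_logistic(sub["case"], design)
        trend = pd.concat(
            [pd.DataFrame({f"{score}_bin": bins.astype(float)}), covs], axis=1)
        trend_fit = fit_logistic(sub["case"], trend)
        trend_p = trend_fit.wald_p(f"{score}_bin")
    for j, lab in zip((1, 2, 3, 4), binning.labels):
        row = {
            "population": population, "score": score, "model": model,
            "quartile": lab,
            "cases": int(counts.loc[float(j), 1]),
            "controls": int(counts.loc[float(j), 0]),
        }
        if j == 1:
            row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan, note="reference")
        elif fit is not None:
            or_, lo, hi = fit.odds_ratio(f"{score}_q{j}")
            row.update(odds_ratio=or_, ci_low=lo, ci_high=hi, note="")
        else:
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       note="non-estimable (empty cell)")
        row["p_trend"] = trend_p if trend_p is not None else np.nan
        row["n_used"] = fit.n_used if fit is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


_JOINT_LABELS = ("MRS low / GRS low", "MRS low / GRS high",
                 "MRS high / GRS low", "MRS high / GRS high")


def joint_group_or_table(subjects: pd.DataFrame, model: int,
                         population: str = "all",
                         grs_col: str = "grs", mrs_col: str = "mrs") -> pd.DataFrame:
    """Joint GRS/MRS risk-group odds ratios from median splits among controls.

    Scores are dichotomised at the control median (high = at or above, same
    half-open convention as the quartiles); the four ordered groups are
    low/low (reference), low-MRS/high-GRS, high-MRS/low-GRS, high/high. All
    models adjust for batch + leukocyte composition, models 2 and 3 add the
    demographic and smoking covariates.
    """
    mask = _population_mask(subjects, population)
    sub = subjects[mask]
    ctrl = sub["case"] == 0
    med_g = float(np.quantile(sub.loc[ctrl, grs_col].dropna(), 0.5, method="linear"))
    med_m = float(np.quantile(sub.loc[ctrl, mrs_col].dropna(), 0.5, method="linear"))
    hi_g = (sub[grs_col] >= med_g).astype(float)
    hi_m = (sub[mrs_col] >= med_m).astype(float)
    group = (1 + hi_g + 2 * hi_m)
    group[sub[grs_col].isna() | sub[mrs_col].isna() | sub["case"].isna()] = np.nan
    keep = group.notna()
    sub, group = sub[keep], group[keep]

    covs = model_covariates(sub, model, technical=True)
    dummies = pd.DataFrame({f"joint_g{j}": (group == j).astype(float) for j in (2, 3, 4)},
                           index=sub.index)
    fit = fit_logistic(sub["case"], pd.concat([dummies, covs], axis=1))
    trend_fit = fit_logistic(
        sub["case"],
        pd.concat([pd.DataFrame({"joint_group": group.astype(float)}), covs], axis=1))
    trend_p = trend_fit.wald_p("joint_group")

    counts = pd.crosstab(group, sub["case"]).reindex(
        index=[1.0, 2.0, 3.0, 4.0], columns=[0, 1], fill_value=0)
    rows = []
    for j, lab in zip((1, 2, 3, 4), _JOINT_LABELS):
        row = {"population": population, "model": model, "group": lab,
               "cases": int(counts.loc[float(j), 1]),
               "controls": int(counts.loc[float(j), 0]),
               "p_trend": trend_p, "n_used": fit.n_used}
        if j == 1:
            row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan)
        else:
            or_, lo, hi = fit.odds_ratio(f"joint_g{j}")
            row.update(odds_ratio=or_, ci_low=lo, ci_high=hi)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact / rank tests for the baseline characteristics table
# ---------------------------------------------------------------------------

def _fisher_enumerate(table, max_tables: float = 5e7) -> tuple[float, float]:
    """Enumerate the 2xK fixed-margin tables; return (tail mass, total mass)."""
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise DomainError("table must be 2xK with K >= 2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise DomainError("table entries must be non-negative integers")
        t = t.astype(int)
    col = t.sum(axis=0)
    r1 = int(t[0].sum())

    budget = np.prod([min(c, r1) + 1.0 for c in col[:-1]])
    if budget > max_tables:
        raise FeasibilityError(
            f"~{budget:.2g} candidate tables exceed the enumeration budget; "
            "use a Monte Carlo approximation instead")

    # log P(a) = sum_j log C(col_j, a_j) - log C(N, r1)
    logc = [gammaln(c + 1) - gammaln(np.arange(c + 1) + 1)
            - gammaln(c - np.arange(c + 1) + 1) for c in col]
    log_denom = (gammaln(col.sum() + 1) - gammaln(r1 + 1)
                 - gammaln(col.sum() - r1 + 1))
    obs_logp = sum(logc[j][t[0, j]] for j in range(len(col))) - log_denom

    k = len(col)
    total = 0.0
    psum = 0.0

    def recurse(j: int, remaining: int, acc: float) -> None:
        nonlocal total, psum
        if j == k - 2:
            # vectorise over the last two free cells
            a = np.arange(0, min(col[j], remaining) + 1)
            rem = remaining - a
            ok = rem <= col[-1]
            a, rem = a[ok], rem[ok]
            lp = acc + logc[j][a] + logc[-1][rem] - log_denom
            p = np.exp(lp)
            total += p.sum()
            psum += p[lp <= obs_logp + 1e-12].sum()
            return
        for a in range(0, min(col[j], remaining) + 1):
            recurse(j + 1, remaining - a, acc + logc[j][a])

    recurse(0, r1, 0.0)
    return psum, total


def fisher_exact_2xk(table, max_tables: float = 5e7) -> float:
    """Two-sided Fisher exact test for a 2xK contingency table.

    Enumerates every 2xK table with the observed margins; the p-value sums the
    multivariate hypergeometric probabilities of all tables no more probable
    than the observed one (relative tie tolerance 1e-12, log-space
    throughout). For K = 2 this reduces to the classical two-sided Fisher
    test. Raises FeasibilityError when the enumeration would exceed
    `max_tables` tables.
    """
    psum, total = _fisher_enumerate(table, max_tables=max_tables)
    # total is 1 up to accumulation error; normalise so p <= 1 exactly
    return float(min(psum / total, 1.0))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum p-value.

    Uses exact enumeration of all C(n, n_x) group assignments of the pooled
    sample when n_x + n_y <= `exact_max_n` (ties allowed; two-sided p is
    P(|U - mean U| >= observed) under the permutation null), otherwise the
    normal approximation with tie and continuity corrections. Returns p = 1
    with a warning when every pooled value is tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return 1.0
    nx, n = len(x), len(pooled)
    if n <= exact_max_n:
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
        us = np.array([ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
                       for idx in itertools.combinations(range(n), nx)])
        mu = us.mean()
        return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.pvalue)
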