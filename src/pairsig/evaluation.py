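"""Validation of a fitted risk score against right-censored survival.

Covers: time-dependent ROC/AUC at fixed horizons (cumulative/dynamic,
Kaplan-Meier weighted), the AIC-minimizing dichotomization cutoff,
Kaplan-Meier curves with the two-group log-rank test, univariate and
multivariate Cox independence analysis against clinical covariates,
stratified (subgroup) log-rank analysis, and AUC comparison between
competing signatures.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats

from ._cox import cox_fit, cox_loglik, CoxConvergenceError

log = logging.getLogger(__name__)

# bound on |log HR| when evaluating the profile likelihood of a
# dichotomized score; keeps perfectly separating cutoffs finite
MAX_ABS_LOGHR = 15.0


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RocCurve:
    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _km_event_weights(time: np.ndarray, event: np.ndarray, horizon: float) -> np.ndarray:
    """Per-subject probability of being a case (event by the horizon).

    1 for observed events at or before the horizon, 0 for subjects still
    under observation past it, and the Kaplan-Meier conditional
    probability 1 - S(horizon)/S(c) for subjects censored at c < horizon.
    """
    km = KaplanMeierFitter().fit(time, event)
    s_h = float(km.predict(horizon))
    w = np.zeros(len(time))
    cases = (time <= horizon) & (event == 1)
    w[cases] = 1.0
    cens_early = (time <= horizon) & (event == 0)
    if cens_early.any():
        s_c = km.predict(time[cens_early]).to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(s_c > 0, 1.0 - s_h / np.maximum(s_c, 1e-300), 1.0)
        w[cens_early] = np.clip(frac, 0.0, 1.0)
    return w


def time_dependent_roc(scores, time, event, horizon: float) -> RocCurve:
    """Cumulative/dynamic ROC at a horizon with Kaplan-Meier weighting.

    Each subject contributes to the case pool with weight
    P(T <= horizon | observed data), estimated from the overall KM curve,
    and to the control pool with the complement; the sweep over score
    cutoffs is therefore monotone and, with no censoring before the
    horizon, reduces exactly to the empirical ROC of the binary outcome
    1{T <= horizon}. AUC is the trapezoidal area.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if horizon <= 0 or horizon > time.max():
        raise ValueError(f"horizon {horizon} outside the observed follow-up range")
    if not ((time <= horizon) & (event == 1)).any():
        raise ValueError(f"no events observed before horizon {horizon}")
    w = _km_event_weights(time, event, horizon)
    w_case, w_ctrl = w, 1.0 - w
    if w_ctrl.sum() <= 0:
        raise ValueError("no controls at this horizon")

    uniq = np.unique(scores)
    cutoffs = np.concatenate(([-np.inf], uniq))
    sens = np.empty(len(cutoffs))
    spec = np.empty(len(cutoffs))
    for k, c in enumerate(cutoffs):
        pos = scores > c
        sens[k] = w_case[pos].sum() / w_case.sum()
        spec[k] = w_ctrl[~pos].sum() / w_ctrl.sum()
    # descending-cutoff order makes sens and fpr jointly nondecreasing,
    # so the trapezoid handles tied-score diagonal jumps correctly
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocCurve(horizon=float(horizon), cutoffs=cutoffs, sensitivity=sens,
                    specificity=spec, auc=auc)


# ---------------------------------------------------------------------------
# AIC-optimal cutoff
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CutoffResult:
    cutoff: float
    candidates: np.ndarray
    aics: np.ndarray


def _binary_cox_aic(indicator: np.ndarray, time, event) -> float:
    """AIC of the one-covariate Cox model on a group indicator.

    The log partial likelihood is profiled over |log HR| <= MAX_ABS_LOGHR
    so that perfectly separating cutoffs get a finite (and minimal) AIC.
    """
    res = optimize.minimize_scalar(
        lambda b: -cox_loglik(np.array([b]), indicator, time, event),
        bounds=(-MAX_ABS_LOGHR, MAX_ABS_LOGHR), method="bounded",
        options={"xatol": 1e-8},
    )
    return 2.0 * res.fun + 2.0


def optimal_cutoff_aic(scores, time, event) -> CutoffResult:
    """Exhaustive AIC-minimizing dichotomization of the risk score.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    scores; each candidate's AIC is -2 log PL + 2 for the Cox model with
    the single binary covariate 1{score > cutoff}. Ties in AIC resolve
    to the lower cutoff.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("cutoff search needs at least 2 distinct scores")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    aics = np.array([_binary_cox_aic((scores > c).astype(float), time, event)
                     for c in candidates])
    best = int(np.argmin(aics))  # argmin takes the first (= lowest) on ties
    return CutoffResult(cutoff=float(candidates[best]), candidates=candidates, aics=aics)


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.DataFrame:
    """Per-patient risk assignment: high iff score > cutoff."""
    scores = pd.Series(scores)
    return pd.DataFrame(
        {
            "score": scores,
            "group": np.where(scores.to_numpy() > cutoff, "high", "low"),
            "cutoff": cutoff,
        },
        index=scores.index,
    )


# ---------------------------------------------------------------------------
# KM + log-rank
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KmLogRank:
    curves: dict[str, pd.DataFrame]  # per group: columns time, survival
    chi2: float
    p: float
    n_per_group: dict[str, int]


def km_logrank(groups, time, event) -> KmLogRank:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError(f"log-rank needs >=2 nonempty groups, got {list(labels)}")
    curves = {}
    for lab in labels:
        m = groups == lab
        km = KaplanMeierFitter().fit(time[m], event[m], label=str(lab))
        sf = km.survival_function_
        curves[str(lab)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    res = multivariate_logrank_test(time, groups, event)
    return KmLogRank(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        n_per_group={str(l): int(c) for l, c in zip(labels, counts)},
    )


# ---------------------------------------------------------------------------
# independence from clinical covariates
# ---------------------------------------------------------------------------

def _design_matrix(surv: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = surv[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.astype(float)
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=cov, drop_first=True)
            for c in dummies:
                cols[c] = dummies[c].astype(float)
    return pd.DataFrame(cols, index=surv.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        aliased = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")


def independence_analysis(
    scores: pd.Series,
    surv: pd.DataFrame,
    covariates=("age", "gender", "grade", "stage"),
) -> pd.DataFrame:
    """Univariate and multivariate Cox of risk score vs clinical factors.

    Rows with missing values are dropped (complete case, logged).
    Categorical covariates are dummy-coded against the first (sorted)
    level. Returns one row per design term with univariate and
    multivariate hr / ci / p columns.
    """
    df = surv.set_index("patient_id") if "patient_id" in surv.columns else surv.copy()
    df = df.loc[scores.index]
    df["risk_score"] = pd.Series(scores)
    use = ["risk_score"] + [c for c in covariates if c in df.columns]
    complete = df.dropna(subset=use + ["time", "event"])
    n_drop = len(df) - len(complete)
    if n_drop:
        log.info("independence_analysis: %d incomplete rows dropped", n_drop)
    time = complete["time"].to_numpy(float)
    event = complete["event"].to_numpy(int)

    X = _design_matrix(complete, use)
    _check_full_rank(X)

    rows = {}
    for cov in use:
        sub = _design_matrix(complete, [cov])
        fit = cox_fit(sub.to_numpy(), time, event)
        lo, hi = fit.ci()
        for j, term in enumerate(sub.columns):
            rows[term] = {
                "covariate": cov,
                "uni_hr": fit.hr[j], "uni_ci_low": lo[j], "uni_ci_high": hi[j],
                "uni_p": fit.wald_p[j],
            }
    mfit = cox_fit(X.to_numpy(), time, event)
    mlo, mhi = mfit.ci()
    for j, term in enumerate(X.columns):
        rows[term].update(
            multi_hr=mfit.hr[j], multi_ci_low=mlo[j], multi_ci_high=mhi[j],
            multi_p=mfit.wald_p[j],
        )
    out = pd.DataFrame(rows).T
    out.index.name = "term"
    return out


# ---------------------------------------------------------------------------
# stratified analysis
# ---------------------------------------------------------------------------

def age_strata(surv: pd.DataFrame, cut: float = 65.0) -> pd.Series:
    """Young (age <= cut) vs old (age > cut)."""
    return pd.Series(
        np.where(surv["age"].to_numpy(float) <= cut, "young", "old"),
        index=surv.index, name="stratum",
    )


def stage_strata(surv: pd.DataFrame) -> pd.Series:
    """Early (stages I-II) vs late (stages III-IV)."""
    early = surv["stage"].astype(str).isin(["I", "II"])
    return pd.Series(np.where(early, "early", "late"), index=surv.index, name="stratum")


def stratified_analysis(
    groups: pd.Series, surv: pd.DataFrame, strata: pd.Series
) -> dict[str, KmLogRank | None]:
    """Within each stratum, high/low log-rank using the global grouping.

    A stratum whose patients all fall in one risk group is reported as
    ``None`` (not testable).
    """
    out: dict[str, KmLogRank | None] = {}
    for label in pd.unique(strata):
        m = (strata == label).to_numpy()
        if not m.any():
            raise ValueError(f"empty stratum {label!r}")
        g = np.asarray(groups)[m]
        if len(np.unique(g)) < 2:
            log.warning("stratified_analysis: stratum %s has a single risk group", label)
            out[str(label)] = None
            continue
        out[str(label)] = km_logrank(
            g, surv["time"].to_numpy(float)[m], surv["event"].to_numpy(int)[m]
        )
    return out


# ---------------------------------------------------------------------------
# signature comparison
# ---------------------------------------------------------------------------

def compare_signatures(
    score_sets: dict[str, pd.Series], time, event, horizon: float
) -> pd.DataFrame:
    """Time-dependent AUC of several risk scores at a shared horizon."""
    idx = None
    for name, s in score_sets.items():
        s = pd.Series(s)
        if idx is None:
            idx = s.index
        elif not s.index.equals(idx):
            raise ValueError(f"score set {name!r} covers different patients")
    rows = [
        {"signature": name,
         "auc": time_dependent_roc(pd.Series(s).to_numpy(), time, event, horizon).auc}
        for name, s in score_sets.items()
    ]
    return pd.DataFrame(rows)
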