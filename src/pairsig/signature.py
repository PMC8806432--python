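"""Prognostic pair-signature fitting.

Three nested selection stages mirror the published protocol:

1. univariate Cox screen — one PH model per candidate pair (single
   binary covariate, Efron ties, Wald p), keeping pairs with p < 0.01;
2. LASSO-Cox — L1-penalized Cox over a descending penalty grid with
   k-fold cross-validated partial-likelihood deviance, keeping the
   nonzero coefficients at the deviance-minimizing penalty;
3. backward elimination — from the full multivariate Cox model, the
   term whose removal most decreases AIC is dropped until no removal
   decreases AIC.

The surviving terms and their multivariate coefficients beta_i define
the risk score  score(patient) = sum_i beta_i * P_i(patient)  over the
binary pair indicators P_i.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import CoxConvergenceError, cox_fit, cox_loglik

log = logging.getLogger(__name__)

SCREEN_COLUMNS = ["pair_id", "beta", "hr", "ci_low", "ci_high", "p"]


def _as_time_event(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (time, event) tuple, a DataFrame with time/event columns,
    or a sksurv structured array."""
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        ev = y[names[0]].astype(int)
        tm = y[names[1]].astype(float)
        return tm, ev
    tm, ev = y
    return np.asarray(tm, float), np.asarray(ev, int)


# ---------------------------------------------------------------------------
# stage 1: univariate screen
# ---------------------------------------------------------------------------

def univariate_cox_screen(
    P: pd.DataFrame, time, event, p_max: float = 0.01, *, return_all: bool = False
) -> pd.DataFrame:
    """Per-pair univariate Cox PH screen.

    ``P`` is a pairs x patients binary DataFrame aligned with ``time`` /
    ``event``. Pairs with a constant indicator, or whose fit does not
    converge (monotone likelihood), are skipped with a logged warning.
    Returns pairs with Wald p < ``p_max`` (all fitted pairs if
    ``return_all``), columns ``pair_id, beta, hr, ci_low, ci_high, p``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 2:
        raise ValueError("univariate screen needs at least 2 events")
    if P.shape[1] != len(time):
        raise ValueError("pair matrix and survival data are not aligned")
    rows = []
    for pid, x in zip(P.index, P.to_numpy(float)):
        if x.min() == x.max():
            log.warning("univariate_cox_screen: constant pair %s skipped", pid)
            continue
        try:
            fit = cox_fit(x, time, event)
        except CoxConvergenceError as exc:
            log.warning("univariate_cox_screen: pair %s skipped (%s)", pid, exc)
            continue
        (lo,), (hi,) = fit.ci()
        rows.append((pid, fit.beta[0], fit.hr[0], lo, hi, fit.wald_p[0]))
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if return_all:
        return out
    return out[out["p"] < p_max].reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 2: LASSO-Cox with cross-validated penalty
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LassoPath:
    """L1 path and CV curve. ``lambdas`` descending; ``coefs`` is a
    pairs x lambdas DataFrame; ``cv_mean``/``cv_se`` the cross-validated
    partial-likelihood deviance per lambda; ``lambda_min`` its minimizer."""

    lambdas: np.ndarray
    coefs: pd.DataFrame
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float

    @property
    def selected(self) -> list[str]:
        j = int(np.argmin(self.cv_mean))
        col = self.coefs.iloc[:, j]
        return list(col.index[col.to_numpy() != 0])


def _heldout_deviance(beta: np.ndarray, X_test, time_test, event_test) -> float:
    if event_test.sum() == 0:
        return np.nan
    ll = cox_loglik(beta, X_test, time_test, event_test)
    ll0 = cox_loglik(np.zeros_like(beta), X_test, time_test, event_test)
    return 2.0 * (ll0 - ll)


def lasso_cox_select(
    P: pd.DataFrame,
    time,
    event,
    *,
    cv_folds: int = 10,
    cv_repeats: int = 1,
    n_lambdas: int = 100,
    seed: int = 0,
    coxnet_tol: float = 1e-7,
) -> LassoPath:
    """Cross-validated L1-penalized Cox selection over the screened pairs.

    The penalty grid comes from a full-data glmnet-style fit; each fold
    refits the path on the training samples and scores the held-out
    partial-likelihood deviance (null minus fitted, times two). The
    selected set is the nonzero support at the deviance-minimizing
    penalty (lambda_min).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if P.shape[0] < 2:
        raise ValueError("LASSO selection needs at least 2 candidate pairs")
    if event.sum() < 10:
        raise ValueError("LASSO selection needs at least 10 events")
    X = P.T.to_numpy(float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_lambdas, tol=coxnet_tol, fit_baseline_model=False
    ).fit(X, y)
    alphas = np.asarray(full.alphas_)
    coefs = pd.DataFrame(full.coef_, index=P.index, columns=alphas)

    dev = np.full((cv_repeats * cv_folds, len(alphas)), np.nan)
    row = 0
    for rep in range(cv_repeats):
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed + rep)
        for tr, te in kf.split(X):
            if event[tr].sum() < 2 or event[te].sum() < 1:
                row += 1
                continue
            try:
                fold = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, alphas=alphas, tol=coxnet_tol, fit_baseline_model=False
                ).fit(X[tr], y[tr])
            except (ArithmeticError, ValueError) as exc:
                log.warning("lasso_cox_select: fold skipped (%s)", exc)
                row += 1
                continue
            fit_alphas = list(fold.alphas_)
            for j, a in enumerate(alphas):
                if a in fit_alphas:
                    b = fold.coef_[:, fit_alphas.index(a)]
                    dev[row, j] = _heldout_deviance(b, X[te], time[te], event[te])
            row += 1

    with np.errstate(invalid="ignore"):
        cv_mean = np.nanmean(dev, axis=0)
        n_ok = np.sum(np.isfinite(dev), axis=0)
        cv_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    cv_mean = np.where(np.isfinite(cv_mean), cv_mean, np.inf)
    lambda_min = float(alphas[int(np.argmin(cv_mean))])
    path = LassoPath(
        lambdas=alphas, coefs=coefs, cv_mean=cv_mean, cv_se=cv_se, lambda_min=lambda_min
    )
    if not path.selected:
        log.warning("lasso_cox_select: empty selection (all-zero path at lambda_min)")
    return path


# ---------------------------------------------------------------------------
# stage 3: backward AIC elimination + signature
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Signature:
    """Fitted pair signature: terms (pair_id, beta, hr, ci, p) and fit
    metadata. ``score`` of a patient is sum(beta_i * P_i)."""

    terms: pd.DataFrame  # columns SCREEN_COLUMNS
    n: int
    loglik: float
    aic: float

    @property
    def pair_ids(self) -> list[str]:
        return list(self.terms["pair_id"])

    @property
    def betas(self) -> pd.Series:
        return self.terms.set_index("pair_id")["beta"]


def _fit_subset(P: pd.DataFrame, pairs, time, event):
    X = P.loc[list(pairs)].T.to_numpy(float)
    try:
        return cox_fit(X, time, event)
    except CoxConvergenceError as exc:
        log.warning("multivariate Cox: ridge-stabilized restart (%s)", exc)
        warm = cox_fit(X, time, event, ridge=1.0)
        return cox_fit(X, time, event, ridge=1e-6, beta0=warm.beta)


def stepwise_multivariate_cox(P: pd.DataFrame, time, event, candidates) -> Signature:
    """Backward AIC elimination from the full multivariate Cox model.

    At each step the term whose removal most decreases AIC is dropped;
    elimination stops when every removal would increase AIC. A single
    candidate is returned as-is with its (multivariate = univariate) fit.
    """
    current = list(candidates)
    if not current:
        raise ValueError("stepwise elimination needs a nonempty candidate set")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    fit = _fit_subset(P, current, time, event)
    while len(current) > 1:
        best_aic, best_drop, best_fit = fit.aic, None, None
        for j, pid in enumerate(current):
            reduced = current[:j] + current[j + 1:]
            try:
                f = _fit_subset(P, reduced, time, event)
            except CoxConvergenceError:
                continue
            if f.aic < best_aic - 1e-10:
                best_aic, best_drop, best_fit = f.aic, pid, f
        if best_drop is None:
            break
        log.info("stepwise: dropped %s (AIC %.3f -> %.3f)", best_drop, fit.aic, best_aic)
        current.remove(best_drop)
        fit = best_fit
    lo, hi = fit.ci()
    terms = pd.DataFrame(
        {
            "pair_id": current,
            "beta": fit.beta,
            "hr": fit.hr,
            "ci_low": lo,
            "ci_high": hi,
            "p": fit.wald_p,
        }
    )
    return Signature(terms=terms, n=fit.n, loglik=fit.loglik, aic=fit.aic)


def risk_score(sig: Signature | pd.Series, P: pd.DataFrame) -> pd.Series:
    """Per-patient risk score sum_i beta_i * P_i.

    ``P`` is pairs x patients; every signature pair must be present.
    """
    betas = sig.betas if isinstance(sig, Signature) else sig
    missing = [p for p in betas.index if p not in P.index]
    if missing:
        raise KeyError(f"pair(s) missing from pair matrix: {', '.join(missing)}")
    scores = betas.to_numpy(float) @ P.loc[list(betas.index)].to_numpy(float)
    return pd.Series(scores, index=P.columns, name="score")


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class PairSignatureCox(BaseEstimator):
    """Sklearn-style estimator for the pair-based prognostic signature.

    ``fit(X, y)`` takes a samples x pairs binary indicator DataFrame
    (e.g. the output of :class:`~pairsig.pairing.PairMatrixTransformer`)
    and right-censored survival ``y`` (DataFrame with ``time``/``event``
    columns, a ``(time, event)`` tuple, or a sksurv structured array),
    runs the univariate screen, the cross-validated LASSO-Cox selection
    and backward AIC elimination, and stores the fitted signature.
    ``predict(X)`` returns the risk score (higher = worse prognosis).

    Attributes (after fit)
    ----------------------
    screen_results_ : univariate screen survivors.
    lasso_path_ : the L1 path with its CV deviance curve.
    signature_ : the final :class:`Signature`.
    coef_ : signature coefficients (ndarray, order of ``pair_ids_``).
    pair_ids_ : pairs in the final signature.
    """

    def __init__(
        self,
        p_uni: float = 0.01,
        cv_folds: int = 10,
        cv_repeats: int = 1,
        n_lambdas: int = 100,
        random_state: int = 0,
    ):
        self.p_uni = p_uni
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.n_lambdas = n_lambdas
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "PairSignatureCox":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x pairs DataFrame of 0/1 indicators")
        time, event = _as_time_event(y)
        if len(time) != len(X):
            raise ValueError("X and y have different lengths")
        P = X.T  # pairs x patients
        screened = univariate_cox_screen(P, time, event, p_max=self.p_uni)
        if screened.empty:
            raise ValueError("no pairs passed the univariate Cox screen")
        self.screen_results_ = screened
        cand_ids = list(screened["pair_id"])
        if len(cand_ids) >= 2 and event.sum() >= 10:
            self.lasso_path_ = lasso_cox_select(
                P.loc[cand_ids], time, event,
                cv_folds=self.cv_folds, cv_repeats=self.cv_repeats,
                n_lambdas=self.n_lambdas, seed=self.random_state,
            )
            selected = self.lasso_path_.selected
            if not selected:
                raise ValueError("LASSO selected no pairs (all-zero path)")
        else:
            self.lasso_path_ = None
            selected = cand_ids
        self.selected_pairs_ = selected
        self.signature_ = stepwise_multivariate_cox(P, time, event, selected)
        self.pair_ids_ = self.signature_.pair_ids
        self.coef_ = self.signature_.betas.to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "signature_")
        return risk_score(self.signature_, X.T)
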