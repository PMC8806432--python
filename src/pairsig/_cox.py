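"""Cox proportional-hazards fitting via Newton-Raphson on the Efron
partial likelihood.

A dedicated implementation is used instead of a general survival package
because the pipeline fits thousands of tiny Cox models (one per candidate
pair in the univariate screen, O(k^2) during backward AIC elimination,
one per candidate cutoff in the dichotomization search); it is validated
against lifelines in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


class CoxConvergenceError(RuntimeError):
    """Newton iteration failed (typically monotone likelihood)."""


@dataclasses.dataclass
class CoxFit:
    """Result of a Cox PH fit.

    ``beta`` are log hazard ratios; ``se`` Wald standard errors from the
    inverse observed information; ``loglik`` the Efron log partial
    likelihood at the optimum and ``loglik_null`` at beta = 0.
    """

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)


def _prepare(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def _efron_blocks(time: np.ndarray, event: np.ndarray):
    """Start indices of tied-time blocks (ascending time order)."""
    n = len(time)
    starts = [0]
    for i in range(1, n):
        if time[i] != time[i - 1]:
            starts.append(i)
    starts.append(n)
    return starts


def efron_loglik_grad_hess(beta, X, time, event, want_derivs=True):
    """Efron log partial likelihood with gradient and Hessian.

    Inputs must be pre-sorted by ascending time. Returns
    ``(ll, grad, hess)``; the derivative slots are ``None`` when
    ``want_derivs`` is False.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    theta = np.exp(eta)
    # suffix sums over the risk set {j : t_j >= t_i}
    S = np.cumsum(theta[::-1])[::-1]
    no_ties = len(np.unique(time)) == n
    if want_derivs or no_ties:
        tx = theta[:, None] * X
        Z = np.cumsum(tx[::-1], axis=0)[::-1]
    if want_derivs:
        txx = tx[:, :, None] * X[:, None, :]
        Q = np.cumsum(txx[::-1], axis=0)[::-1]

    if no_ties:
        # Efron == Breslow when every event time is unique; vectorized path
        e = event == 1
        ll = float(eta[e].sum() - np.log(S[e]).sum())
        if not want_derivs:
            return ll, None, None
        Se = S[e][:, None]
        grad = X[e].sum(axis=0) - (Z[e] / Se).sum(axis=0)
        hess = -(
            (Q[e] / Se[:, :, None]).sum(axis=0)
            - np.einsum("ij,ik->jk", Z[e] / Se, Z[e] / Se)
        )
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p) if want_derivs else None
    hess = np.zeros((p, p)) if want_derivs else None
    starts = _efron_blocks(time, event)
    for b in range(len(starts) - 1):
        a, e_ = starts[b], starts[b + 1]
        D = np.arange(a, e_)[event[a:e_] == 1]
        d = len(D)
        if d == 0:
            continue
        S_D = theta[D].sum()
        ll += eta[D].sum()
        if want_derivs:
            Z_D = tx[D].sum(axis=0)
            Q_D = txx[D].sum(axis=0)
            grad += X[D].sum(axis=0)
        for r in range(d):
            f = r / d
            s = S[a] - f * S_D
            ll -= np.log(s)
            if want_derivs:
                z = Z[a] - f * Z_D
                q = Q[a] - f * Q_D
                grad -= z / s
                hess -= q / s - np.outer(z, z) / (s * s)
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    *,
    ridge: float = 0.0,
    beta0=None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson (Efron ties, Wald inference).

    ``ridge`` adds an L2 penalty 0.5*ridge*||beta||^2 to stabilise
    near-separable designs; the reported log likelihood is unpenalized.
    """
    Xs, ts, es = _prepare(X, time, event)
    n, p = Xs.shape
    n_events = int(es.sum())
    if n_events == 0:
        raise CoxConvergenceError("no events: partial likelihood is constant")

    ll_null, _, _ = efron_loglik_grad_hess(np.zeros(p), Xs, ts, es, want_derivs=False)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    ll, grad, hess = efron_loglik_grad_hess(beta, Xs, ts, es)
    pll = ll
    for _ in range(max_iter):
        g = grad - ridge * beta
        H = hess - ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving: the penalized log likelihood must not decrease
        for k in range(30):
            cand = beta - step / (2**k)
            ll_c, grad_c, hess_c = efron_loglik_grad_hess(cand, Xs, ts, es)
            pll_c = ll_c - 0.5 * ridge * cand @ cand
            if pll_c >= pll - 1e-12:
                break
        else:
            raise CoxConvergenceError("step halving failed")
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, hess, pll = cand, ll_c, grad_c, hess_c, pll_c
        if delta < tol or np.max(np.abs(grad - ridge * beta)) < 1e-7:
            break
    else:
        raise CoxConvergenceError("Newton iteration did not converge")
    if np.max(np.abs(beta)) > 50:
        raise CoxConvergenceError("monotone likelihood: coefficient diverged")

    info = -(hess - ridge * np.eye(p))
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxConvergenceError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFit(beta=beta, se=se, loglik=ll, loglik_null=ll_null, n=n, n_events=n_events)


def cox_loglik(beta, X, time, event) -> float:
    """Efron log partial likelihood of ``beta`` on (possibly unsorted) data."""
    Xs, ts, es = _prepare(X, time, event)
    ll, _, _ = efron_loglik_grad_hess(np.atleast_1d(np.asarray(beta, float)), Xs, ts, es,
                                      want_derivs=False)
    return ll
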