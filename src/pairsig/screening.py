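"""Immune-related lncRNA screening and differential expression.

Two stages: (1) a co-expression screen keeping every lncRNA whose
expression correlates with at least one immune-annotated mRNA beyond
|r| > 0.4 at p < 0.001 (Pearson on log2(x+1), defaults configurable);
(2) a tumor-vs-normal moderated-t test on the retained lncRNAs, with
Benjamini-Hochberg adjustment within the tested family, keeping genes
with FDR < 0.05 and |log2FC| > 1.5.

The moderated t follows the empirical-Bayes variance shrinkage of
limma: gene-wise pooled variances are shrunk towards a scaled
inverse-chi-square prior whose scale and degrees of freedom are fitted
by moments of the log variances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson correlation via the exact t transform
    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom."""
    r = np.clip(np.asarray(r, float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return p


def screen_irlncrnas(
    expr: ExpressionMatrix,
    r_min: float = 0.4,
    p_max: float = 0.001,
    *,
    tumor_only: bool = True,
    method: str = "pearson",
    log2: bool = True,
) -> pd.DataFrame:
    """Identify immune-related lncRNAs by co-expression with immune mRNAs.

    A lncRNA is retained iff some immune gene has |r| > ``r_min`` and
    p < ``p_max``; its strongest-|r| partner is reported. Zero-variance
    genes are skipped (correlation undefined) with a logged warning.

    Returns a DataFrame with columns ``lncRNA``, ``best_partner``, ``r``,
    ``p`` — one row per retained lncRNA.
    """
    lnc_ids = expr.lncrna_ids
    imm_ids = expr.immune_gene_ids
    if not lnc_ids or not imm_ids:
        raise ValueError("need at least one lncRNA and one immune-flagged mRNA")
    samples = expr.tumor_samples if tumor_only else expr.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for the correlation screen")
    vals = expr.log2_values() if log2 else expr.values
    L = vals.loc[lnc_ids, samples].to_numpy(float)
    M = vals.loc[imm_ids, samples].to_numpy(float)
    if method == "spearman":
        L = stats.rankdata(L, axis=1)
        M = stats.rankdata(M, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    n = len(samples)
    L_ok = L.std(axis=1) > 0
    M_ok = M.std(axis=1) > 0
    for gid, ok in zip(lnc_ids, L_ok):
        if not ok:
            log.warning("screen_irlncrnas: constant lncRNA %s skipped", gid)
    for gid, ok in zip(imm_ids, M_ok):
        if not ok:
            log.warning("screen_irlncrnas: constant immune gene %s skipped", gid)
    if not L_ok.any() or not M_ok.any():
        return pd.DataFrame(columns=["lncRNA", "best_partner", "r", "p"])

    Lc = L[L_ok] - L[L_ok].mean(axis=1, keepdims=True)
    Mc = M[M_ok] - M[M_ok].mean(axis=1, keepdims=True)
    Lc /= np.linalg.norm(Lc, axis=1, keepdims=True)
    Mc /= np.linalg.norm(Mc, axis=1, keepdims=True)
    R = np.clip(Lc @ Mc.T, -1.0, 1.0)  # (lnc, immune)

    kept_lnc = [g for g, ok in zip(lnc_ids, L_ok) if ok]
    kept_imm = [g for g, ok in zip(imm_ids, M_ok) if ok]
    best = np.argmax(np.abs(R), axis=1)
    r_best = R[np.arange(len(kept_lnc)), best]
    p_best = pearson_pvalue(r_best, n)
    retain = (np.abs(r_best) > r_min) & (p_best < p_max)
    out = pd.DataFrame(
        {
            "lncRNA": np.asarray(kept_lnc, dtype=object)[retain],
            "best_partner": np.asarray(kept_imm, dtype=object)[best[retain]],
            "r": r_best[retain],
            "p": p_best[retain],
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# moderated t differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x, y > 0 (Smyth's scheme)
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0_sq): prior degrees of freedom and prior variance. A
    non-positive excess dispersion of log(s2) yields d0 = inf (complete
    shrinkage to a common variance).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2)) if len(s2) else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    excess = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        s0 = np.exp(np.mean(e))
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2 * half_d0
        s0 = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0)


def differential_expression(
    expr: ExpressionMatrix,
    lnc_subset,
    fdr_max: float = 0.05,
    lfc_min: float = 1.5,
    *,
    method: str = "moderated",
    return_all: bool = False,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on log2(x+1) values.

    ``method="moderated"`` uses the empirical-Bayes moderated t;
    ``"welch"`` is a plain Welch two-sample t. BH adjustment is applied
    within the tested subset only. Retained iff fdr < ``fdr_max`` and
    |log2FC| > ``lfc_min``.
    """
    genes = list(lnc_subset)
    if not genes:
        raise ValueError("empty gene subset for differential expression")
    tum, nor = expr.tumor_samples, expr.normal_samples
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError(
            f"both groups need >=2 samples (tumor={len(tum)}, normal={len(nor)})"
        )
    vals = expr.log2_values().loc[genes]
    T = vals[tum].to_numpy(float)
    N = vals[nor].to_numpy(float)
    n1, n2 = T.shape[1], N.shape[1]
    m1, m2 = T.mean(axis=1), N.mean(axis=1)
    lfc = m1 - m2

    if method == "moderated":
        v1 = T.var(axis=1, ddof=1)
        v2 = N.var(axis=1, ddof=1)
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        d0, s0 = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_total = np.inf
        else:
            s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = lfc / se
        if np.isinf(df_total):
            p = 2 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2 * stats.t.sf(np.abs(tstat), df=df_total)
    elif method == "welch":
        tstat, p = stats.ttest_ind(T, N, axis=1, equal_var=False)
    else:
        raise ValueError(f"unknown DE method {method!r}")

    p = np.where(np.isfinite(p), p, 1.0)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "lncRNA": genes,
            "log2FC": lfc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    )
    if return_all:
        return out.reset_index(drop=True)
    keep = (out["fdr"] < fdr_max) & (out["log2FC"].abs() > lfc_min)
    return out[keep].reset_index(drop=True)
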