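"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
textbook formulas) and share no code with the package, so they can
arbitrate correctness of the fast implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from pairsig import ExpressionMatrix, SimulationSpec


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """Compact synthetic cohort used by fast unit tests."""
    return SimulationSpec(
        n_tumor=150, n_normal=30, n_lncrna=40, n_mrna=30,
        n_immune_genes=10, n_irlnc=12, n_de=8, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    from pairsig import simulate_cohort

    return simulate_cohort(small_spec)


@pytest.fixture()
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 tumor + 2 normal."""
    values = pd.DataFrame(
        [[5.0, 1.0, 2.0, 3.0], [1.0, 5.0, 4.0, 2.0], [2.0, 2.0, 2.0, 2.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["tumor", "tumor", "normal", "normal"],
                       index=values.columns, name="group")
    meta = pd.DataFrame(
        {"biotype": ["lncRNA", "lncRNA", "mRNA"], "immune_flag": [False, False, True]},
        index=values.index,
    )
    return ExpressionMatrix(values=values, sample_group=groups, gene_meta=meta)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def bf_pair_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Exhaustive loop over all gene pairs and samples (ties -> 0)."""
    genes = list(values.index)
    arr = values.to_numpy()
    rows, ids = [], []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            row = [1 if arr[i, s] > arr[j, s] else 0 for s in range(arr.shape[1])]
            rows.append(row)
            ids.append(f"{genes[i]}|{genes[j]}")
    return pd.DataFrame(rows, index=ids, columns=values.columns)


def bf_bh(p):
    """Benjamini-Hochberg by the step-up definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def bf_km(time, event):
    """Product-limit estimator: list of (time, survival) at event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = []
    for t in sorted(set(time[event == 1])):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        out.append((t, s))
    return out


def bf_logrank(time, event, groups):
    """Two-group log-rank chi-square from the risk tables."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[0]
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def naive_efron_loglik(beta, x, time, event):
    """Loop-based Efron log partial likelihood, single covariate."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = np.where((time == t) & (event == 1))[0]
        R = np.where(time >= t)[0]
        d = len(D)
        s_r = theta[R].sum()
        s_d = theta[D].sum()
        ll += beta * x[D].sum()
        for r in range(d):
            ll -= np.log(s_r - (r / d) * s_d)
    return ll


def grid_max_loglik(x, time, event, lo=-15.0, hi=15.0, tol=1e-6):
    """Coarse-to-fine grid maximization of the naive Efron likelihood."""
    for _ in range(8):
        grid = np.linspace(lo, hi, 41)
        lls = [naive_efron_loglik(b, x, time, event) for b in grid]
        k = int(np.argmax(lls))
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        if hi - lo < tol:
            break
    return (lo + hi) / 2, naive_efron_loglik((lo + hi) / 2, x, time, event)


def exact_mannwhitney_p(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    stats_all = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats_all = np.asarray(stats_all)
    mean = stats_all.mean()
    p = np.mean(np.abs(stats_all - mean) >= np.abs(obs - mean) - 1e-12)
    return p


def exact_spearman_perm_p(x, y):
    """Exact permutation p for Spearman rho (small n, no ties)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)

    def rho(a, b):
        return np.corrcoef(a, b)[0, 1]

    obs = abs(rho(rx, ry))
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total
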