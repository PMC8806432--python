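"""Associations between risk groups and immune / treatment covariates.

Consumes precomputed tables — immune-cell infiltration fractions from
deconvolution tools (xCell, TIMER, QUANTISEQ, MCPcounter, EPIC,
CIBERSORT variants), drug IC50 predictions, checkpoint-gene expression,
qRT-PCR delta-Ct measurements — and applies the statistical layer:
Spearman correlation of fractions with the risk score, rank-sum
(Mann-Whitney) comparisons between high/low groups, and chi-square
tests of pair calls across tumor-stage groups.

Note on test choice: for two independent groups the correct rank test
is the rank-sum (Mann-Whitney) test, which is what ``compare_group_values``
and ``correlate_infiltration`` use; the signed-rank variant applies only
to paired data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

ASSOC_COLUMNS = ["feature", "test", "statistic", "p", "fdr", "direction"]


def _direction(high_vals: np.ndarray, low_vals: np.ndarray) -> str:
    d = np.median(high_vals) - np.median(low_vals)
    return "positive" if d > 0 else ("negative" if d < 0 else "none")


def _finish(rows: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=ASSOC_COLUMNS[:-2] + ["direction"])
    if out.empty:
        out["fdr"] = []
        return out[ASSOC_COLUMNS]
    # BH within each test family
    out["fdr"] = np.nan
    for test in out["test"].unique():
        m = out["test"] == test
        out.loc[m, "fdr"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    return out[ASSOC_COLUMNS]


def correlate_infiltration(
    scores: pd.Series, groups: pd.Series, infil: pd.DataFrame
) -> pd.DataFrame:
    """Associate infiltration fractions with the risk score and groups.

    ``infil`` is features x samples (feature = cell type, optionally
    tagged with the deconvolution method). Per feature: Spearman rho of
    score vs fraction (two-sided) and a rank-sum comparison between the
    high and low groups. Features with < 3 overlapping samples or zero
    variance are skipped with a warning. A BH-adjusted column is added
    per test family; the raw p is the headline value.
    """
    scores = pd.Series(scores)
    groups = pd.Series(groups)
    rows: list[dict] = []
    for feat, vals in infil.iterrows():
        common = vals.index.intersection(scores.index)
        if len(common) < 3:
            log.warning("correlate_infiltration: %s skipped (<3 overlapping samples)", feat)
            continue
        v = vals.loc[common].to_numpy(float)
        s = scores.loc[common].to_numpy(float)
        if np.ptp(v) == 0:
            log.warning("correlate_infiltration: %s skipped (constant fractions)", feat)
            continue
        rho, rho_p = stats.spearmanr(s, v)
        g = groups.loc[common].to_numpy()
        hi, lo = v[g == "high"], v[g == "low"]
        rows.append(
            {"feature": feat, "test": "spearman", "statistic": float(rho),
             "p": float(rho_p), "direction": "positive" if rho > 0 else "negative"}
        )
        if len(hi) and len(lo):
            u, wp = stats.mannwhitneyu(hi, lo, alternative="two-sided")
            rows.append(
                {"feature": feat, "test": "wilcoxon", "statistic": float(u),
                 "p": float(wp), "direction": _direction(hi, lo)}
            )
    return _finish(rows)


def compare_group_values(
    groups: pd.Series, value_table: pd.DataFrame, features=None
) -> pd.DataFrame:
    """Rank-sum comparison of per-feature values between risk groups.

    ``value_table`` is features x samples (drug IC50s, or expression of
    checkpoint genes such as PDCD1 / LAG3 / CTLA4). Direction is the
    sign of (median high - median low).
    """
    groups = pd.Series(groups)
    if features is None:
        features = list(value_table.index)
    missing = [f for f in features if f not in value_table.index]
    if missing:
        raise KeyError(f"feature(s) absent from value table: {', '.join(map(str, missing))}")
    rows: list[dict] = []
    for feat in features:
        vals = value_table.loc[feat]
        common = vals.index.intersection(groups.index)
        g = groups.loc[common].to_numpy()
        v = vals.loc[common].to_numpy(float)
        hi, lo = v[g == "high"], v[g == "low"]
        if len(hi) == 0 or len(lo) == 0:
            raise ValueError(f"feature {feat!r}: a risk group is empty")
        u, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
        rows.append(
            {"feature": feat, "test": "wilcoxon", "statistic": float(u),
             "p": float(p), "direction": _direction(hi, lo)}
        )
    return _finish(rows)


# ---------------------------------------------------------------------------
# qRT-PCR delta-Ct pair calls
# ---------------------------------------------------------------------------

def pcr_pair_call(delta_ct, pair: tuple[str, str]) -> int:
    """Binary pair call from delta-Ct values (gene Ct minus GAPDH Ct).

    Lower delta-Ct means higher expression, so the call is 1 iff
    dCt(former) < dCt(latter) — the qPCR analogue of the expression
    pair indicator; equality gives 0 (same tie rule as pairing).
    """
    former, latter = pair
    for g in (former, latter):
        if g not in delta_ct or pd.isna(delta_ct[g]):
            raise KeyError(f"missing delta-Ct for gene {g!r}")
    return int(float(delta_ct[former]) < float(delta_ct[latter]))


@dataclasses.dataclass
class StageTestResult:
    pair: tuple[str, str]
    table: pd.DataFrame  # calls (0/1) x stage groups
    chi2: float | None
    p: float | None
    testable: bool


def pcr_stage_test(
    records: pd.DataFrame,
    pair: tuple[str, str],
    *,
    stage_col: str = "stage_group",
    continuity_correction: bool = False,
) -> StageTestResult:
    """Chi-square test of pair calls across tumor-stage groups.

    ``records`` has one row per specimen with a stage-group column and
    one delta-Ct column per gene. A zero marginal (all calls identical,
    or an empty stage group) makes the 2x2 table degenerate; the result
    is then flagged not testable rather than erroring.
    """
    stage_groups = records[stage_col].unique()
    if len(stage_groups) < 2:
        raise ValueError("need at least two stage groups")
    calls = records.apply(lambda row: pcr_pair_call(row, pair), axis=1)
    table = pd.crosstab(calls, records[stage_col]).reindex(
        index=[0, 1], fill_value=0
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        log.warning("pcr_stage_test: degenerate 2x2 table for pair %s", pair)
        return StageTestResult(pair=pair, table=table, chi2=None, p=None, testable=False)
    chi2, p, _, _ = stats.chi2_contingency(
        table.to_numpy(), correction=continuity_correction
    )
    return StageTestResult(pair=pair, table=table, chi2=float(chi2), p=float(p),
                           testable=True)
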