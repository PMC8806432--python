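"""Time-dependent ROC, AIC cutoff, KM/log-rank, independence, strata."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from pairsig import (
    assign_risk_groups,
    compare_signatures,
    independence_analysis,
    km_logrank,
    optimal_cutoff_aic,
    stratified_analysis,
    time_dependent_roc,
)
from pairsig.evaluation import MAX_ABS_LOGHR, age_strata, stage_strata
from conftest import bf_km, bf_logrank, grid_max_loglik


def mann_whitney_auc(scores, labels):
    """Empirical AUC of scores for binary labels (probability a case
    outscores a control, ties counting half)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_no_censoring_reduces_to_mann_whitney(seed):
    rng = np.random.default_rng(seed)
    n = 300
    scores = rng.normal(size=n)
    time = rng.exponential(100 * np.exp(-scores), n)
    event = np.ones(n, int)
    horizon = float(np.median(time))
    roc = time_dependent_roc(scores, time, event, horizon)
    assert roc.auc == pytest.approx(
        mann_whitney_auc(scores, (time <= horizon).astype(int)), abs=1e-10
    )


def test_null_score_auc_near_half():
    rng = np.random.default_rng(10)
    n = 1000
    scores = rng.normal(size=n)
    time = rng.exponential(100, n)
    event = rng.integers(0, 2, n)
    event[:5] = 1
    roc = time_dependent_roc(scores, time, event, float(np.median(time)))
    assert 0.45 <= roc.auc <= 0.55


def test_perfect_separation_auc_one():
    time = np.array([10.0, 20, 30, 200, 300, 400])
    scores = np.array([6.0, 5, 4, 1, 2, 3])
    roc = time_dependent_roc(scores, time, np.ones(6, int), horizon=100.0)
    assert roc.auc == pytest.approx(1.0)


def test_roc_sweep_monotone_with_censoring():
    rng = np.random.default_rng(3)
    n = 200
    scores = rng.normal(size=n)
    T = rng.exponential(100 * np.exp(-0.7 * scores), n)
    C = rng.uniform(0, 250, n)
    time, event = np.minimum(T, C), (T <= C).astype(int)
    roc = time_dependent_roc(scores, time, event, 120.0)
    assert (np.diff(roc.sensitivity) <= 1e-12).all()
    assert (np.diff(1 - roc.specificity) <= 1e-12).all()


def test_auc_invariant_under_monotone_score_transform():
    rng = np.random.default_rng(4)
    n = 150
    scores = rng.normal(size=n)
    T = rng.exponential(100 * np.exp(-scores), n)
    C = rng.uniform(0, 300, n)
    time, event = np.minimum(T, C), (T <= C).astype(int)
    a1 = time_dependent_roc(scores, time, event, 100.0).auc
    a2 = time_dependent_roc(np.exp(2 * scores) + 5, time, event, 100.0).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_no_events_before_horizon_errors():
    with pytest.raises(ValueError, match="events"):
        time_dependent_roc([1.0, 2.0], [100.0, 200.0], [1, 1], horizon=50.0)


# ---------------------------------------------------------------------------
# AIC cutoff
# ---------------------------------------------------------------------------

def test_perfectly_separating_cutoff_found():
    scores = np.array([0.1, 0.2, 0.3, 2.1, 2.2, 2.3])
    time = np.array([500.0, 600, 550, 20, 30, 25])
    event = np.ones(6, int)
    res = optimal_cutoff_aic(scores, time, event)
    assert 0.3 < res.cutoff < 2.1


def test_cutoff_matches_bruteforce_oracle_12_patients():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=12)
    time = rng.exponential(100 * np.exp(-scores))
    event = rng.integers(0, 2, 12)
    event[:4] = 1
    res = optimal_cutoff_aic(scores, time, event)
    uniq = np.sort(np.unique(scores))
    mids = (uniq[:-1] + uniq[1:]) / 2
    oracle_aics = []
    for c in mids:
        x = (scores > c).astype(float)
        _, ll = grid_max_loglik(x, time, event, lo=-MAX_ABS_LOGHR, hi=MAX_ABS_LOGHR)
        oracle_aics.append(-2 * ll + 2)
    assert res.cutoff == pytest.approx(mids[int(np.argmin(oracle_aics))])
    assert np.allclose(res.aics, oracle_aics, atol=1e-3)


def test_constant_scores_error():
    with pytest.raises(ValueError, match="distinct"):
        optimal_cutoff_aic([1.0, 1.0, 1.0], [10.0, 20, 30], [1, 1, 1])


def test_group_assignment_rule():
    g = assign_risk_groups(pd.Series([0.2, 0.5, 0.5001], index=list("abc")), 0.5)
    assert list(g["group"]) == ["low", "low", "high"]


# ---------------------------------------------------------------------------
# KM + log-rank
# ---------------------------------------------------------------------------

def test_identical_groups_give_null_statistic():
    time = np.tile([50.0, 100, 150, 200], 2)
    event = np.tile([1, 0, 1, 1], 2)
    groups = np.repeat(["a", "b"], 4)
    res = km_logrank(groups, time, event)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_km_equals_empirical_survivor_without_censoring():
    time = np.array([10.0, 20, 30, 40, 50, 60])
    event = np.ones(6, int)
    res = km_logrank(np.array(["a"] * 3 + ["b"] * 3), time, event)
    curve = res.curves["a"].set_index("time")["survival"]
    assert curve.loc[10.0] == pytest.approx(2 / 3)
    assert curve.loc[30.0] == pytest.approx(0.0)


def test_km_matches_product_limit_oracle():
    time = np.array([5.0, 8, 8, 12, 15, 20, 21, 25])
    event = np.array([1, 1, 0, 1, 0, 1, 1, 0])
    km = KaplanMeierFitter().fit(time, event)
    for t, s in bf_km(time, event):
        assert float(km.predict(t)) == pytest.approx(s, abs=1e-12)


def test_logrank_matches_risk_table_oracle():
    rng = np.random.default_rng(8)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 40
        groups = rng.choice(["a", "b"], n)
        time = np.round(rng.exponential(50, n)) + 1
        event = rng.integers(0, 2, n)
        event[:5] = 1
        res = km_logrank(groups, time, event)
        assert res.chi2 == pytest.approx(bf_logrank(time, event, groups), rel=1e-9)


def test_single_group_errors():
    with pytest.raises(ValueError, match="2 nonempty groups"):
        km_logrank(np.array(["a", "a"]), np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# independence + strata
# ---------------------------------------------------------------------------

def _clin(n, seed, score_driven=True):
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    eta = score if score_driven else np.zeros(n)
    T = rng.exponential(1000 * np.exp(-eta))
    C = rng.uniform(0, 3000, n)
    surv = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "time": np.minimum(T, C) + 31,
            "event": (T <= C).astype(int),
            "age": rng.normal(60, 10, n).round(),
            "gender": rng.choice(["male", "female"], n),
            "grade": rng.choice(["G1", "G2", "G3"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
        }
    )
    scores = pd.Series(score, index=surv["patient_id"], name="score")
    return scores, surv


def test_score_driven_cohort_score_significant_clinicals_not():
    scores, surv = _clin(600, seed=1)
    res = independence_analysis(scores, surv)
    assert res.loc["risk_score", "multi_p"] < 0.01
    clin_p = res.drop(index="risk_score")["multi_p"].astype(float)
    assert (clin_p > 0.01).mean() >= 0.8  # null covariates rarely significant


def test_duplicated_covariate_rank_deficiency_named():
    scores, surv = _clin(100, seed=2)
    surv["age2"] = surv["age"]
    with pytest.raises(ValueError, match="aliased"):
        independence_analysis(scores, surv, covariates=("age", "age2"))


def test_shuffled_score_null_calibration():
    scores, surv = _clin(200, seed=3, score_driven=False)
    rng = np.random.default_rng(4)
    rejections = 0
    reps = 200
    for _ in range(reps):
        sh = pd.Series(rng.permutation(scores.to_numpy()), index=scores.index)
        res = independence_analysis(sh, surv, covariates=())
        rejections += res.loc["risk_score", "uni_p"] < 0.05
    assert 0.02 <= rejections / reps <= 0.09


def test_age_and_stage_split_rules():
    surv = pd.DataFrame({"age": [60, 65, 66, 70],
                         "stage": ["I", "II", "III", "IV"]})
    assert list(age_strata(surv)) == ["young", "young", "old", "old"]
    assert list(stage_strata(surv)) == ["early", "early", "late", "late"]


def test_stratified_analysis_flags_single_group_stratum():
    scores, surv = _clin(120, seed=5)
    groups = pd.Series(np.where(scores > 0, "high", "low"), index=scores.index)
    strata = pd.Series(np.where(np.arange(120) < 60, "s1", "s2"),
                       index=scores.index)
    groups.iloc[60:] = "high"  # s2 degenerate
    out = stratified_analysis(groups, surv, strata)
    assert out["s2"] is None
    assert out["s1"] is not None and out["s1"].p <= 1.0


# ---------------------------------------------------------------------------
# signature comparison
# ---------------------------------------------------------------------------

def test_compare_signatures_informative_beats_noise():
    rng = np.random.default_rng(9)
    n = 400
    good = rng.normal(size=n)
    T = rng.exponential(300 * np.exp(-good))
    C = rng.uniform(0, 800, n)
    time, event = np.minimum(T, C), (T <= C).astype(int)
    idx = pd.Index([f"p{i}" for i in range(n)])
    wins = 0
    for seed in range(20):
        noise = pd.Series(np.random.default_rng(1000 + seed).normal(size=n), index=idx)
        tab = compare_signatures(
            {"fitted": pd.Series(good, index=idx), "noise": noise},
            time, event, horizon=200.0,
        ).set_index("signature")
        if tab.loc["fitted", "auc"] > tab.loc["noise", "auc"]:
            wins += 1
        assert 0.3 <= tab.loc["noise", "auc"] <= 0.7
    assert wins >= 19
    # self-comparison is exact
    tab = compare_signatures(
        {"a": pd.Series(good, index=idx), "b": pd.Series(good.copy(), index=idx)},
        time, event, horizon=200.0,
    )
    assert tab["auc"].iloc[0] == tab["auc"].iloc[1]


def test_compare_signatures_patient_mismatch_errors():
    s1 = pd.Series([1.0, 2.0], index=["a", "b"])
    s2 = pd.Series([1.0, 2.0], index=["a", "c"])
    with pytest.raises(ValueError, match="different patients"):
        compare_signatures({"x": s1, "y": s2}, [1.0, 2.0], [1, 1], 1.5)
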