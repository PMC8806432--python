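"""End-to-end orchestration: simulate/load -> screen -> pair -> fit ->
evaluate, with a run manifest recording the selection funnel.

Every stage's inputs and outputs are plain TSV tables, so any stage can
be re-run in isolation; all randomness flows from the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .evaluation import (
    age_strata,
    assign_risk_groups,
    km_logrank,
    independence_analysis,
    optimal_cutoff_aic,
    stage_strata,
    stratified_analysis,
    time_dependent_roc,
)
from .io import ExpressionMatrix, filter_patients, validate_survival
from .pairing import build_pair_matrix, filter_valid_pairs
from .screening import differential_expression, screen_irlncrnas
from .signature import PairSignatureCox
from .simulate import SimulationSpec, simulate_cohort

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    counts: dict[str, int]
    digests: dict[str, str]
    timings: dict[str, float]

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def equivalent(self, other: "RunManifest") -> bool:
        """Equality of everything except wall-clock timings."""
        a, b = dataclasses.asdict(self), dataclasses.asdict(other)
        a.pop("timings"), b.pop("timings")
        return a == b


@dataclasses.dataclass
class PipelineResult:
    manifest: RunManifest
    expr: ExpressionMatrix
    surv: pd.DataFrame
    irlnc: pd.DataFrame
    de: pd.DataFrame
    pair_matrix: "pd.DataFrame"
    model: PairSignatureCox
    scores: pd.Series
    cutoff: float
    groups: pd.DataFrame
    km: object
    rocs: dict[float, object]
    independence: pd.DataFrame
    stratified: dict
    truth: dict | None = None


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(sep="\t").encode()).hexdigest()[:16]


def map_samples_to_patients(tumor_samples, patient_ids) -> dict[str, str]:
    """One tumor sample per patient; extra samples for the same patient
    are dropped, keeping the first in file order (logged)."""
    seen = {}
    pset = set(patient_ids)
    for s in tumor_samples:
        pid = s if s in pset else s.split(".")[0]
        if pid not in pset:
            continue
        if pid in seen.values():
            log.info("map_samples_to_patients: extra sample %s for %s dropped", s, pid)
            continue
        seen[s] = pid
    return seen


def run_all(
    config: AnalysisConfig,
    sim_spec: SimulationSpec | None = None,
    expr: ExpressionMatrix | None = None,
    surv: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis chain and return objects plus manifest.

    Either a :class:`SimulationSpec` (synthetic cohort) or an
    expression/survival pair must be provided. Deterministic given
    (config, spec/seed).
    """
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    digests: dict[str, str] = {}
    truth = None

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = _time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = _time.perf_counter() - self.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("input"):
        if sim_spec is not None:
            sim_spec = dataclasses.replace(sim_spec, seed=sim_spec.seed or config.seed)
            expr, surv, truth = simulate_cohort(sim_spec)
        if expr is None or surv is None:
            raise ValueError("provide either sim_spec or (expr, surv)")
        surv = validate_survival(surv)
        digests["expression"] = _digest(expr.values)
        digests["survival"] = _digest(surv)

    with stage("filter_patients"):
        surv = filter_patients(surv, config.min_followup_days)
        counts["patients"] = len(surv)

    with stage("screen"):
        irlnc = screen_irlncrnas(
            expr, config.corr_r, config.corr_p,
            tumor_only=config.corr_tumor_only, log2=config.log2_transform,
        )
        counts["irlncRNAs"] = len(irlnc)
        if irlnc.empty:
            raise ValueError("no immune-related lncRNAs passed the correlation screen")
        de = differential_expression(
            expr, list(irlnc["lncRNA"]), config.de_fdr, config.de_log2fc
        )
        counts["DEirlncRNAs"] = len(de)
        if len(de) < 2:
            raise ValueError(
                f"only {len(de)} DEirlncRNA(s) — need at least 2 to form pairs"
            )
        digests["de"] = _digest(de)

    with stage("pair"):
        sample_map = map_samples_to_patients(expr.tumor_samples, surv["patient_id"])
        tumor_samples = list(sample_map)
        pm = build_pair_matrix(expr.values.loc[list(de["lncRNA"])], tumor_samples)
        counts["pairs_unfiltered"] = len(pm.values)
        pm = filter_valid_pairs(pm, config.pair_low, config.pair_high)
        counts["pairs_valid"] = len(pm.values)
        if pm.values.empty:
            raise ValueError("no valid pairs after the frequency filter")
        # relabel columns sample -> patient and align survival
        P = pm.values.rename(columns=sample_map)
        surv = (
            surv.set_index("patient_id").loc[P.columns]
            .rename_axis("patient_id").reset_index()
        )
        digests["pairs"] = _digest(P)

    with stage("fit"):
        model = PairSignatureCox(
            p_uni=config.uni_cox_p, cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats, n_lambdas=config.n_lambdas,
            random_state=config.seed,
        )
        model.fit(P.T, (surv["time"], surv["event"]))
        counts["pairs_screened"] = len(model.screen_results_)
        counts["pairs_lasso"] = len(model.selected_pairs_)
        counts["signature_size"] = len(model.pair_ids_)
        scores = model.predict(P.T)
        digests["signature"] = _digest(model.signature_.terms)

    with stage("evaluate"):
        tvec = surv["time"].to_numpy(float)
        evec = surv["event"].to_numpy(int)
        rocs = {}
        for h in config.horizons_days:
            try:
                rocs[h] = time_dependent_roc(scores.to_numpy(), tvec, evec, h)
            except ValueError as exc:
                log.warning("ROC at horizon %.0f skipped: %s", h, exc)
        cut = optimal_cutoff_aic(scores.to_numpy(), tvec, evec)
        groups = assign_risk_groups(scores, cut.cutoff)
        km = km_logrank(groups["group"].to_numpy(), tvec, evec)
        indep = independence_analysis(scores, surv)
        strat = {}
        surv_idx = surv.set_index("patient_id").loc[scores.index].reset_index()
        strat["age"] = stratified_analysis(
            groups["group"], surv_idx, age_strata(surv_idx).set_axis(scores.index)
        )
        strat["stage"] = stratified_analysis(
            groups["group"], surv_idx, stage_strata(surv_idx).set_axis(scores.index)
        )

    manifest = RunManifest(
        config=dataclasses.asdict(config) | {"horizons_years": list(config.horizons_years)},
        seed=config.seed,
        counts=counts,
        digests=digests,
        timings=timings,
    )

    result = PipelineResult(
        manifest=manifest, expr=expr, surv=surv, irlnc=irlnc, de=de,
        pair_matrix=P, model=model, scores=scores, cutoff=cut.cutoff,
        groups=groups, km=km, rocs=rocs, independence=indep, stratified=strat,
        truth=truth,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.expr.write(outdir / "expression.tsv", outdir / "sample_groups.tsv",
                   outdir / "gene_meta.tsv")
    res.surv.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    res.irlnc.to_csv(outdir / "irlnc.tsv", sep="\t", index=False)
    res.de.to_csv(outdir / "de.tsv", sep="\t", index=False)
    res.pair_matrix.to_csv(outdir / "pairs.tsv", sep="\t", index_label="pair_id")
    res.model.signature_.terms.to_csv(outdir / "signature.tsv", sep="\t", index=False)
    scores_df = res.groups.copy()
    scores_df.to_csv(outdir / "scores.tsv", sep="\t", index_label="patient_id")
    res.independence.to_csv(outdir / "independence.tsv", sep="\t")
    res.manifest.to_json(outdir / "manifest.json")
    if res.truth is not None:
        (outdir / "truth.json").write_text(json.dumps(res.truth, indent=2))
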