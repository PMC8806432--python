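# pairsig

Rank-based gene-pair prognostic signatures for immune-related lncRNAs,
from expression and survival tables to a validated risk score.

## The problem

Bulk tumor transcriptomes (e.g. TCGA head-and-neck squamous cell
carcinoma) are measured on incompatible scales across platforms and
batches, which makes absolute-expression prognostic signatures fragile.
A *pair signature* sidesteps normalisation entirely: for an ordered
gene pair (a, b) and a sample s, the only information used is the
binary indicator

    P_i(s) = 1  if expr(a, s) > expr(b, s),  else 0,

which is invariant under any strictly increasing per-sample transform
of expression. The risk score of a patient is the coefficient-weighted
sum over the signature's pairs,

    score(patient) = Σ_i β_i · P_i(patient),

with β_i fitted by multivariate Cox regression. `pairsig` implements
the full analysis for immune-related long non-coding RNAs (lncRNAs):

1. **Screening** — lncRNAs co-expressed with immune-annotated mRNAs
   (Pearson |r| > 0.4, p < 0.001), then the tumor-vs-normal
   differentially expressed subset (empirical-Bayes moderated t,
   BH FDR < 0.05, |log2FC| > 1.5).
2. **Pairing** — the 0-or-1 matrix over all n(n−1)/2 pairs of the DE
   lncRNAs; pairs whose 1-frequency falls outside (0.20, 0.80) are
   near-constant and dropped.
3. **Signature fitting** — univariate Cox screen (Efron ties, Wald
   p < 0.01), cross-validated LASSO-Cox selection at the
   deviance-minimizing penalty, then backward elimination by AIC.
4. **Evaluation** — time-dependent ROC/AUC at 1/2/3 years
   (KM-weighted cumulative/dynamic estimator), an AIC-minimizing
   dichotomization cutoff, Kaplan–Meier curves with the log-rank test,
   Cox independence from age/gender/grade/stage, and stratified
   (age ≤65 vs >65, stage I–II vs III–IV) analyses.
5. **Association** — Spearman/rank-sum statistics linking risk groups
   to immune-infiltration fractions, checkpoint-gene expression, drug
   IC₅₀ tables, and qRT-PCR ΔCt pair calls.

A synthetic-cohort generator with planted immune co-expression, DE
shifts and proportional-hazards pair effects provides ground truth for
every stage.

## Worked example

The two core objects are sklearn-style estimators: a transformer from
expression to pair indicators and a fit/predict signature model.

```python
from pairsig import AnalysisConfig, SimulationSpec, run_all

res = run_all(AnalysisConfig(seed=1), sim_spec=SimulationSpec(seed=1))
print(res.manifest.counts)
print(f"cutoff {res.cutoff:.3f}  log-rank p {res.km.p:.2e}")
print({round(h): round(r.auc, 3) for h, r in res.rocs.items()})
print(res.model.signature_.terms.head(3))
```

prints

```
{'patients': 477, 'irlncRNAs': 40, 'DEirlncRNAs': 20,
 'pairs_unfiltered': 190, 'pairs_valid': 139, 'pairs_screened': 36,
 'pairs_lasso': 14, 'signature_size': 9}
cutoff 0.247  log-rank p 1.04e-31
{365: 0.74, 730: 0.788, 1096: 0.777}
           pair_id      beta        hr    ci_low   ci_high             p
0  LNC0001|LNC0002  1.089484  2.972739  2.278705  3.878159  9.640309e-16
1  LNC0001|LNC0013  0.259426  1.296185  1.030028  1.631118  2.694881e-02
2  LNC0002|LNC0014 -0.391797  0.675842  0.523756  0.872089  2.593683e-03
```

Reading: of 477 patients surviving the 30-day follow-up filter, 40
lncRNAs pass the immune-correlation screen and 20 are differentially
expressed, giving 190 candidate pairs, 139 of them valid. The funnel
(univariate Cox → LASSO → backward AIC) ends in a 9-pair signature
whose score splits the cohort into risk groups with strongly different
survival (log-rank p ≈ 1e-31) and 3-year AUC ≈ 0.78. The three planted
pairs (`LNC0001|LNC0002`, `LNC0003|LNC0004`, `LNC0005|LNC0006`) are all
recovered with coefficients near their true values (1.2, 0.9, −0.8).

The same chain is scriptable from the shell:

```bash
pairsig simulate --outdir cohort --seed 1
pairsig screen --expr cohort/expression.tsv --groups cohort/sample_groups.tsv \
               --genes cohort/gene_meta.tsv --out-irlnc irlnc.tsv --out-de de.tsv
pairsig pair --expr cohort/expression.tsv --groups cohort/sample_groups.tsv \
             --genes cohort/gene_meta.tsv --de de.tsv --out pairs.tsv
pairsig fit --pairs pairs.tsv --surv cohort/clinical.tsv
pairsig evaluate --scores scores.tsv --surv cohort/clinical.tsv
pairsig run --seed 1 --outdir full_run     # everything at once
```

## Layout

- `src/pairsig/pairing.py`, `signature.py` — the method's core
  (`PairMatrixTransformer`, `PairSignatureCox`).
- `src/pairsig/screening.py`, `evaluation.py`, `association.py` —
  screening, validation and downstream-association layers.
- `src/pairsig/simulate.py` — synthetic cohorts with ground truth.
- `src/pairsig/pipeline.py`, `cli.py` — orchestration and CLI.
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations.
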