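# Methods

This note documents the statistical procedures implemented in
`pairsig`, the choices made where the protocol is genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Cohort filtering

Patients with follow-up time ≤ 30 days (inclusive bound) are excluded
and duplicated patient ids are collapsed to the first occurrence in
file order; both rules are deterministic and order-stable, and the
filter is idempotent. Expression is analysed on the log2(x+1) scale for
correlation and differential expression; the pair matrix always uses
the raw scale, which is immaterial because the pair indicator is
rank-based within each sample.

## Immune-related lncRNA screening

A lncRNA counts as immune-related if some immune-annotated mRNA has
Pearson |r| > 0.4 with two-sided p < 0.001 (exact t transform,
t = r√(n−2)/√(1−r²)). Pearson on log2 values is the co-expression
convention; Spearman is available by configuration. Correlations use
tumor samples only by default — the prognostic model lives in tumors —
with an all-samples switch. Zero-variance genes have undefined
correlations and are skipped with a warning. Because a larger |r| at a
fixed sample size always gives a smaller p, the reported best partner
(strongest |r|) is also the partner that decides retention.

Differential expression between tumor and normal uses a two-sample
moderated t: gene-wise pooled variances are shrunk towards a scaled
inverse-chi-square prior whose degrees of freedom d0 and scale s0² are
fitted by moments of the log variances (trigamma inversion by Newton
iteration); the statistic has d0 + (n1+n2−2) degrees of freedom. This
reproduces the behaviour of the standard empirical-Bayes linear-model
pipeline for a two-group design (cross-checked against Bioconductor
limma in the test suite); a plain Welch t is available as a fallback.
log2FC is the difference of group means of log2(x+1). BH adjustment is
applied within the tested lncRNA family only, and genes are retained at
FDR < 0.05 with |log2FC| > 1.5.

## Pair matrix

Pairs are the i < j upper triangle of the canonical (input-order) gene
list, so n genes yield exactly n(n−1)/2 rows and each unordered pair
appears once with a fixed orientation. Ties in expression give
indicator 0, so results are reproducible on quantized data. The
validity filter keeps pairs with 1-frequency strictly inside
(0.20, 0.80): a pair that is almost always 0 or almost always 1 carries
no ordering information. Strict conjunctive bounds are used; the
boundary cases (exactly 0.20 or 0.80) are removed.

Rank invariance — bit-identical pair matrices and risk scores under
any strictly increasing per-sample transform — is the defining
robustness property and is enforced by dedicated tests with random
monotone transforms.

## Signature fitting

*Univariate screen.* One Cox PH model per pair (single binary
covariate), Efron tie handling, Wald p; pairs with p < 0.01 survive.
Constant indicators and monotone-likelihood (diverging) fits are
skipped with warnings. The Newton solver is implemented in
`pairsig._cox` and is validated against lifelines and against grid
maximization of an independently coded Efron partial likelihood.

*LASSO-Cox.* The L1 path is computed by `scikit-survival`'s coxnet
(a glmnet port) on a descending 100-point penalty grid. K-fold
cross-validation scores each penalty by held-out partial-likelihood
deviance, 2·(ll_null − ll_fit) on the validation fold; the selected
set is the nonzero support at the deviance-minimizing penalty
(lambda_min, matching a minimum-error selection rule). The protocol
phrase "1000 cross-validations" is interpreted as repeated k-fold CV;
the package default is 10-fold with a single repeat, and
`cv_repeats` raises the number of repeated random fold assignments
(100 repeats reproduces the 1000-fold-fit reading) when the extra
stability is worth the compute.

*Backward elimination.* From the full multivariate Cox model on the
selected pairs, the term whose removal most decreases AIC
(−2 log PL + 2k) is dropped until no removal decreases AIC. Perfectly
collinear candidates are resolved naturally: removing a redundant term
leaves the likelihood unchanged and saves 2 AIC units. If the full
model does not converge, a ridge-stabilised fit provides the starting
point. The surviving terms with their multivariate coefficients are
the signature.

## Evaluation

*Time-dependent ROC.* Cumulative/dynamic sensitivity and specificity
at a horizon t are estimated with Kaplan–Meier weighting of censored
observations: each subject receives a case weight P(T ≤ t | observed
data) — 1 for events by t, 0 for subjects under observation past t,
and 1 − S(t)/S(c) for subjects censored at c < t, with S the overall
KM curve — and the complement as control weight. With no censoring
this reduces exactly to the empirical ROC of the binary outcome
1{T ≤ t}, and the sweep is monotone by construction, so the
trapezoidal AUC is well defined. Integration follows the
descending-cutoff sweep, which credits tied scores with half weight
(Mann–Whitney convention). Horizons use 365.25 days/year.

*Cutoff.* The "inflection point" dichotomization is operationalized as
the AIC-minimizing cutoff: candidates are midpoints between
consecutive sorted unique scores; each candidate's one-covariate Cox
model (indicator score > cutoff) is scored by AIC = −2 log PL + 2;
ties resolve to the lower cutoff. The log partial likelihood is
profiled over |log HR| ≤ 15 so perfectly separating cutoffs remain
finite. AIC is only defined relative to a model, and the group-
indicator Cox model is exactly the model the cutoff feeds.

*KM / log-rank / independence.* Kaplan–Meier curves and the log-rank
test come from lifelines; the test statistic is verified against a
hand-coded risk-table computation. The independence analysis fits
univariate Cox per covariate and one multivariate Cox with risk score,
age, gender, grade and stage; categorical covariates are dummy-coded
against the first sorted level, missing rows are dropped per analysis
(complete case, logged), and rank-deficient designs raise an error
naming the aliased columns. Stratified analyses split at age 65
(young ≤ 65 < old) and stage (early = I–II, late = III–IV) and re-run
the log-rank test within each stratum using the global cutoff; strata
with a single risk group are reported as not testable.

## Association layer

Infiltration fractions, IC₅₀ and biomarker tables are inputs, never
computed: deconvolution and drug-response modelling are out of scope.
Per feature the package reports Spearman rho against the risk score
and a two-sample rank-sum (Mann–Whitney) comparison between risk
groups — the correct independent-samples analogue of a signed-rank
test, which would require paired data. Raw p-values are the headline
numbers, with a BH-adjusted column per test family.

qRT-PCR ΔCt pair calls use the difference criterion ΔCt(former) <
ΔCt(latter), equivalent to the higher-expression rule because ΔCt is
inversely related to expression but robust when ΔCt values cross zero
(a ratio criterion is not); equality gives 0, matching the pairing tie
rule, and the equivalence ΔCt = −log2(expression) + c is enforced by
an exact consistency test. Calls are compared across stage groups with
a Pearson chi-square (continuity correction off by default,
switchable); degenerate 2×2 tables are flagged not testable.

## Synthetic cohorts

The generator draws gene expression on the log2 scale from a
latent-factor Gaussian model: factor i (standard normal per sample) is
shared between immune-related lncRNA i and one immune mRNA with
loading 1.0 over residual noise sd 0.6, giving expected correlation
≈ 0.74, comfortably past the 0.4 screen. Differentially expressed
lncRNAs get a tumor mean shift of ±3.0 log2 units (twice the
|log2FC| > 1.5 threshold; 85% up, echoing the predominance of
upregulated lncRNAs in tumor cohorts). Raw expression is 2^z − 1
(clipped at 0), so the analysis scale log2(x+1) recovers the latent
values. Planted pair members share a baseline mean, putting their
indicator frequency near 0.5, inside the validity window; explicitly
specified pairs are checked for theoretical feasibility and refused
when their expected 1-frequency leaves (0.20, 0.80).

Survival times follow a proportional-hazards model whose linear
predictor is the true weighted sum of planted pair indicators computed
from the generated expression itself — exponential baseline with rate
ln 2 / 1000 days⁻¹ (median ≈ 2.7 years, typical of an advanced-cancer
cohort) by default, Weibull optional. Censoring is uniform on [0, τ]
with τ calibrated by bisection so the expected censoring fraction hits
the target (default 30%). Times are continuous days, so Cox fits face
no ties. Clinical covariates (age ~ N(61, 10²), gender 70/30,
grade G1–G3, stage with a late-stage-heavy distribution) are generated
independently of the score so the independence analysis has a known
answer. Default cohort size is 500 tumors + 50 normals with 300
lncRNAs, 200 mRNAs (60 immune), 40 immune-related and 20 DE lncRNAs,
and three planted pairs with coefficients (1.2, 0.9, −0.8).

What the generator does **not** emulate: negative-binomial read-count
noise, library-size artefacts, batch effects, correlated clinical
confounding, or informative censoring. Passing the recovery tests
therefore shows the estimator chain is correct and calibrated under
its own assumptions, not that the signature would validate on real
cohorts.

## Numerical choices and problem sizes

Newton iteration for Cox fits stops at step changes < 1e-9 or gradient
< 1e-7, with step halving; information matrices are inverted exactly
(p is at most a few dozen). Coefficients beyond |β| > 50 are treated
as monotone-likelihood divergence. The tie-free fast path of the
partial likelihood (vectorized suffix sums) is exact because Efron and
Breslow coincide without ties. Coxnet runs at tolerance 1e-7 (1e-9 in
the KKT test, which verifies the subgradient conditions of the
unstandardized objective at 1e-4). Monte-Carlo tests use 200–2000
replicates with fixed seeds and binomial-width acceptance bands; the
end-to-end recovery experiment uses 20 seeds of the default cohort
with an independently simulated test cohort per seed, sizes chosen so
the full suite runs in a few minutes on one CPU.

## Known limitations

- The univariate screen treats each pair independently; correlated
  pairs sharing a gene inflate the screened set, and backward AIC
  only partially prunes them — extra correlated pairs can absorb part
  of a planted coefficient.
- The AIC cutoff is a global dichotomization; no honest inference is
  attached to the resulting group difference (the log-rank p after
  cutoff optimization is optimistic, as in the original protocol).
- The KM-weighted ROC estimator assumes censoring independent of the
  score; heavy dependent censoring would bias AUC.
- Pair indicators discard effect magnitude by design; margins near
  zero are as informative as large ones to the model.
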