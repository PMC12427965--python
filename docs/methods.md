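# Methods

`daplex` implements a three-phase stacked-generalization framework for
binary diagnostic classification on tabular clinical data, developed
around the task of differentiating pediatric pneumonia (label 1) from
acute bronchitis (label 0). This note records the model, its
assumptions, the tunable parameters, and the design choices made where
the design was genuinely open.

## The classification framework

**Phase I — diversity-aware pool.** Six base classifiers from distinct
learning paradigms are tuned independently: a random forest (bagging),
XGBoost (boosting), RBF- and polynomial-kernel SVMs (margin-based),
k-nearest neighbours (instance-based) and Gaussian naive Bayes
(probabilistic). Each is tuned by exhaustive grid search with
stratified 5-fold cross-validation on the training partition only,
optimizing mean validation *balanced accuracy*
BA = (sensitivity + specificity)/2, which is robust to the moderate
class imbalance of the cohort (54.6% pneumonia). All learners share
one fold partition, which is a prerequisite for the rank test and the
out-of-fold alignment in Phase III. For every configuration the seven
tracked metrics (BA, sensitivity, specificity, precision, F1, ROC-AUC,
Brier score) are recorded per fold on both the in-sample training
folds and the held-out validation fold. SVMs expose probabilities via
Platt-style sigmoid calibration of their decision values
(`CalibratedClassifierCV(SVC(), ensemble=False)`); hard predictions
everywhere are the positive-class probability thresholded at 0.5, so
threshold metrics and probability metrics always describe the same
classifier.

**Phase II — stability pruning.** For each tuned learner the stability
gap Δ_metric = mean score on training folds − mean score on validation
folds is computed for all seven metrics (the Brier gap is reversed,
validation − train, so a positive gap always means worse
generalization). A learner is pruned iff its BA gap strictly exceeds
the threshold (default Δ_BA > 0.05); a gap exactly at the threshold is
retained. Only the anchor metric decides; the other gaps are reported
for context. An empty retained set raises an explicit error advising
threshold review rather than silently proceeding.

**Phase III — complementarity-driven fusion.** Complementarity of the
retained learners is quantified two ways. A Friedman rank test on the
folds × models matrix of validation BA (midrank ties, tie-corrected
chi-square, df = models − 1) asks whether the learners behave
distinctly across folds. Pairwise Jensen–Shannon divergence — base-2,
computed per patient between the two models' binary outcome
distributions (p, 1−p) and averaged over patients — measures how
differently the models reason probabilistically; base-2 logs bound it
in [0, 1].

The meta-learner input fuses two streams:

1. *Prediction stream*: each retained learner's out-of-fold (OOF)
   positive-class probability, produced by refitting that learner's
   selected configuration on k−1 folds of the same Phase-I partition —
   no patient is ever scored by a model that saw it.
2. *Feature stream*: the values of the top-k (default 5) consensus
   features. Per retained learner, grouped permutation importance is
   computed fold-wise: the fold model's validation BA drop when all
   emitted columns of a source clinical variable (e.g. every one-hot
   indicator) are permuted jointly, averaged over `n_repeats = 10`
   repeats and then over folds. Using held-out folds avoids the
   optimistic bias of in-sample importance. Per-model rankings
   (descending importance, name-ordered ties) are aggregated by the
   rank-sum Borda variant: a variable's consensus score is the sum of
   its ranks across models, smaller = more important; ties break by
   mean raw importance, then name.

The assembled meta-matrix (retained-count + k columns) is z-scored
with stored parameters, and an MLP is tuned on it with the same
grid-search machinery and folds as Phase I. At prediction time base
probabilities come from the learners refit on the full training set
(standard stacking practice; OOF probabilities exist only for
meta-training), pass through the stored standardization, and the MLP's
positive probability is thresholded at 0.5.

**Meta-feature representative columns.** The framework fixes the
meta-input width at retained + k, but a one-hot encoded consensus
variable emits several columns. Each consensus variable therefore
contributes one representative column: a continuous variable is its
own z-scored column; a categorical variable contributes the indicator
with the largest |Pearson correlation| with the training label (ties
by column name). This keeps the meta-input compact, deterministic and
clinically interpretable (for the 3-level radiology variable it
selects the infiltration indicator).

## Evaluation

The cohort is split once, stratified by diagnosis, into 80% training
and 20% holdout using largest-remainder per-class allocation (694/174
for the 474/394 cohort); a SHA-256 hash of the holdout rows is
recorded before any fitting and verified before evaluation. The fused
model is benchmarked on the holdout against all six base learners;
improvements are *relative* percentages, 100·(DAPLEX − base)/base for
score metrics and 100·(base − DAPLEX)/base for the Brier loss.
Subgroup analysis stratifies the holdout by sex and WHO-style age
bands — half-open intervals [0, 12), [12, 60), [60, ∞) months — and
reports the seven metrics per stratum; metrics undefined in a
single-class stratum stay NaN (flagged), never zero.

## Synthetic cohort generator

The generator emulates the structure of the study population: n = 868
children, prevalence 0.546 (474 pneumonia / 394 bronchitis), and 28
predictors in five clinical domains. Hallmark per-class marginals use
the published group summaries: age 53.2 vs 35.9 months, CRP 40.4 vs
14.2 mg/L, fever 77.2% vs 38.1%, myalgia 22.4% vs 16.5%, crackles
91.4% vs 17.8%, rhonchus 18.6% vs 98.7%, prolonged expiration 14.8%
vs 96.7%, hyperpnea 65.2% vs 85.8%, and a 3-level radiology variable
(infiltration 85.7% vs 0.8%, increased aeration 12.7% vs 92.1%,
remainder normal). Printed ± values for continuous summaries are
standard errors of the mean and are converted to SDs via
SD = SEM·√n_group (an SD of 2.4 months for a pediatric age
distribution would be implausible). The remaining predictors needed to
reach 28 — additional symptoms, work-of-breathing signs and routine
hematology — carry weakly informative, clinically plausible values
chosen once and documented in `default_lrti_config`.

Variables are tied by a latent Gaussian copula: within each clinical
domain the latent normals share an equicorrelation (default ρ = 0.3),
with independence across domains, producing the predictor redundancy
the pruning and complementarity stages need. Marginals are inverted
per variable: continuous normals directly, right-skewed non-negative
quantities (age, CRP, ESR) as lognormals parameterised to match the
target mean and SD, binaries by thresholding the latent CDF at the
event probability, and categoricals by cumulative-probability cut
points. Generation is a pure function of (config, seed).

**What the generator does not emulate.** Only the published marginals
are matched; the real cohort's joint distribution, cross-domain
dependence (e.g. severity linking auscultation, labs and radiology),
measurement noise and any missing-data mechanism are not modelled. The
configured marginals are strongly separating, so the synthetic task is
easier than the clinical one: all tuned learners reach holdout BA near
0.98–1.00 rather than the 0.90–0.95 range typical of real data.
Passing tests therefore demonstrate the correctness and anti-leakage
properties of the machinery, not clinical-grade discrimination on real
patients.

The baseline group-comparison table uses Welch's t-test (unpooled
variances, Welch–Satterthwaite df) for continuous variables and the
Pearson chi-square test without continuity correction for
binary/categorical variables — the common default at this sample size.

## Defaults and numerical choices

| Parameter | Default | Notes |
|---|---|---|
| folds (cv) | 5 | shared across all phases |
| prune threshold | 0.05 | strict `>` on Δ_BA |
| anchor metric | balanced accuracy | other gaps reported only |
| consensus features k | 5 | meta-input width = retained + k |
| permutation repeats | 10 | per variable per fold |
| latent correlation ρ | 0.3 | within clinical domains |
| MLP grid | (16,), (32,), (32,16) × L2 1e-4/1e-3 | adam, max 2000 epochs |
| split fraction | 0.8 | largest-remainder stratified |

- Grid enumeration order is deterministic (sorted parameter names);
  BA ties keep the first configuration, so selection is reproducible.
- z-scores use the training sample SD (ddof = 1); a zero-variance
  feature is scaled by 1 and flagged so the column layout is stable.
- One-hot encoding keeps the full indicator set (no reference-level
  drop) because grouped permutation importance needs every level;
  unseen test categories map to all-zero indicators.
- Undefined metric denominators yield NaN, propagated and flagged,
  never silently 0. ROC-AUC uses midrank tie handling (equivalent to
  the trapezoidal empirical ROC area).
- The Friedman statistic is computed from the explicit tie-corrected
  rank formula rather than a library call so that the two-model case
  is supported and degenerate all-tied matrices return (0, df, 1).
- One seed drives the cohort draw, split, folds and every learner.

## Problem sizes used by the test suite

The deeper simulation-based tests run at the cohort's native scale
(n = 868, 5 folds). Marginal-fidelity checks use n = 50 000 draws.
The multi-seed end-to-end property (median holdout BA of the fused
model vs every base learner) and the label-noise pruning property each
use 20 seeds; the multi-seed sweep runs with the single-configuration
`COMPACT_GRIDS` profile — the package's desk-scale default for
repeated experiments — while a single full default-grid run is also
exercised end to end.

## Known limitations

- The synthetic cohort's independence across domains makes the task
  close to separable; absolute performance numbers are optimistic and
  only relative/structural claims should be read from them. At that
  ceiling every learner makes only a handful of holdout errors, and
  the multi-seed sweep in the test suite shows the strongest single
  learner (the random forest) can edge the fused model by about one
  patient at the median: fusion gains materialize on harder problems
  where base learners err more and differently, not on a
  near-separable one.
- Per-patient averaged binary JSD between well-calibrated, accurate
  models is small by construction (both models are confident and
  agree); divergences near 1 arise only between anti-correlated
  confident models.
- The MLP meta-learner can converge to slightly different optima
  across platforms despite fixed seeds if BLAS threading differs;
  fold-level metrics are deterministic on a given machine.
- No confidence intervals or significance tests are attached to
  holdout comparisons; subgroup strata can be small (< 30 patients).
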