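# Methods

## Problem setting

Preoperative aortic rupture complicates roughly 6% of acute type A aortic
dissection (ATAAD) admissions and is the dominant cause of death before
surgery. The package implements a risk-stratification pipeline for this
rare-event prediction problem: a synthetic cohort generator calibrated to
published group-wise summary statistics (the source cohort of 774 patients,
47 ruptures, is not publicly deposited), a leakage-guarded preprocessing
chain, a Salp Swarm Algorithm (SSA) hyperparameter optimizer for random
forest and XGBoost classifiers, a baseline zoo of eight classifier families,
a full evaluation surface (threshold metrics, ROC/PR areas, calibration,
decision-curve net benefit), and exact additive feature attributions.

## Synthetic cohort generator

The generator treats each clinical variable as an independent draw per
outcome group, described only by what a baseline-characteristics table
prints.

**Continuous variables** are sampled from a *two-piece log-normal*: with
printed quartiles (p25, m, p75), a standard normal Z is mapped through

    X = m * exp(sigma_lo * Z)  if Z < 0
    X = m * exp(sigma_hi * Z)  otherwise,

with `sigma_lo = (ln m - ln p25) / z75` and `sigma_hi = (ln p75 - ln m) / z75`
(`z75 ≈ 0.6745`). By construction the population 25th/50th/75th percentiles
equal the printed values exactly, and the unequal tails reproduce the right
skew typical of laboratory values. A simpler alternative — a single
log-normal fitted to (p25, p75) with a multiplicative shift onto the median —
was rejected because the shift displaces the outer quartiles by up to ~7%
for strongly asymmetric variables (e.g. the rupture-group eGFR), breaking
the generator's 5% quantile-recovery contract. Variables whose support can
include non-positive values fall back to a two-piece normal on the raw
scale; all default variables happen to be positive, so the log route is
used throughout.

**Binary variables** are allocated exactly: within each outcome group the
printed count of positive cells is assigned to a uniformly random subset of
rows. Group prevalences therefore match the table exactly (605/774 male,
4/47 cold extremities, …) rather than in expectation.

**Group sizes.** The non-rupture group is 727 (so 727 + 47 = 774); the
source text is internally inconsistent (727 vs 728) and the table's own
arithmetic is the self-consistent reading.

**Missingness.** Laboratory variables (the 15 admission labs) carry a 10%
missing-completely-at-random rate by default — a realistic single-centre
figure, comfortably inside the stated <30% bound; bedside and demographic
variables are complete. Exactly `round(rate * n)` cells per variable are
masked; the outcome is never masked.

**Correlation.** Variables are independent by default (no covariance
information is published). An optional Gaussian copula accepts a
rank-correlation matrix over continuous variables for sensitivity analyses.

**What the generator does not emulate:** real biological covariance between
labs (e.g. creatinine–eGFR coupling), measurement rounding, informative
missingness, or time-to-event structure. Model performance measured on these
cohorts therefore characterises the *pipeline mechanics* (optimization,
rebalancing, leakage control, calibration of the evaluation code), not the
clinical attainability of any particular accuracy. In particular, with
independent features the synthetic classification task is easier than the
real one at the same marginals.

## Preprocessing

- **Split:** stratified 64/16/20 train/validation/test with
  largest-remainder size allocation (774 → 495/124/155 exactly). Events and
  non-events are allocated separately, keeping per-split prevalence within
  one case of the global 6.1%.
- **Imputation:** chained-equation regression imputation (linear for
  continuous, logistic for binary targets), 10 sweeps, single completed
  dataset — the downstream consumer is one fitted model, not a pooled
  inference, so multiple completed datasets would be unused. Each partition
  is imputed self-contained so no imputation model ever sees another
  partition's rows. The imputation is deterministic (no posterior noise);
  the seed fixes only the sweep order.
- **Screening:** per-variable two-group tests on the training partition
  only — Shapiro-Wilk normality gate per group, then t-test (both normal)
  or Mann-Whitney U; chi-square for binary variables with Fisher's exact
  fallback when any expected cell count is below 5. Variables with p < 0.05
  are retained; `top_k = 9` (the default) additionally keeps the nine
  smallest p-values, matching the reported model input dimensionality. The
  literal p < 0.05 reading (about 20 variables on default cohorts) is
  available with `top_k=None`.
- **SMOTE:** authored in-package. Synthetic minority rows are convex
  combinations `x + u (x_nn - x)` between a minority row and one of its
  k = 5 nearest minority neighbours; binary coordinates take the nearer
  parent's value (threshold 0.5 on the interpolated coordinate). Oversampling
  runs to exact class balance.
- **Standardization:** z-scores with centre/scale fitted on the training
  partition only; zero-variance columns pass through with scale 1 and a
  warning.

Pipeline order: impute → screen → standardize → SMOTE → fit. SMOTE operates
on standardized features so its Euclidean neighbourhoods are not dominated
by large-unit variables.

## Salp Swarm Algorithm

Positions are hyperparameter vectors in a box; fitness is minimized.

- Leader update, per dimension j with fresh c2, c3 ~ U(0,1):
  `x_j = F_j ± c1 ((ub_j - lb_j) c2 + lb_j)` (+ when c3 < 0.5), where F is
  the best-so-far position (food source).
- Schedule: `c1 = 2 exp(-(4 t / T)^2)` — equals 2 at t = 0 and decays to
  2e-16 at t = T, moving from exploration to exploitation.
- Followers: sequential sweep `x_i ← (x_i + x_{i-1}) / 2` using the
  already-updated predecessor (a simultaneous variant is available behind
  `sequential_followers=False`).
- Boundary handling by clamping; the food source is elitist (best over all
  evaluations, not best of the iteration); the trace records best-so-far
  fitness per iteration and is non-increasing by construction.
- Integer dimensions decode by rounding half-away-from-zero, then clamping.

Defaults are 20 salps and 50 iterations; the source study does not print its
budget, and the 2-D sphere benchmark reaches <1e-3 within 100 iterations at
20 salps for every tested seed, so these defaults are comfortably
convergent for the 4- and 5-dimensional search boxes used here. Uniform
initialisation within bounds, with an optional warm-start leader pinned at
the library-default hyperparameters; with warm start enabled, elitism
guarantees the tuned cross-validation fitness never exceeds the default
configuration's fitness on the same folds.

## Cross-validated fitness

`fitness = 1 - mean(fold accuracies)` over a stratified 5-fold split of the
training partition. SMOTE is applied *inside* each fold to the fold-train
rows only: fold-validation rows never enter the oversampling neighbour pool,
so the fold accuracies are leakage-free. (A `smote_in_folds=False` switch
reproduces the laxer pre-balanced reading.) Accuracy is computed at
threshold 0.5 on the balanced fold fit. Search boxes: random forest —
n_estimators ∈ [50, 500], max_depth ∈ [3, 30], min_samples_split ∈ [2, 20],
min_samples_leaf ∈ [1, 10], all integer; XGBoost — n_estimators ∈ [50, 500],
max_depth ∈ [3, 15], min_child_weight ∈ [1, 10] integer, learning_rate ∈
[0.01, 0.3], gamma ∈ [0, 1] continuous. Non-searched hyperparameters stay at
library defaults and are recorded in the run manifest.

The baseline zoo fits eight families (random forest, XGBoost, logistic
regression, SVM with Platt-calibrated probabilities, k-NN, decision tree,
MLP, Gaussian naive Bayes) at library defaults with the run's seed. The
eight-family set is the union of the two slightly different model lists the
source reports.

## Evaluation

Positives are called at score ≥ threshold (default 0.5). Ratios with a zero
denominator are NaN, never coerced to 0. ROC area groups tied scores into
single threshold steps, so it equals the Mann-Whitney U statistic divided by
n1·n0 (tested exhaustively at small n). PR area is a trapezoid over the
precision-recall curve; for random scores it converges to the prevalence.
Calibration uses equal-width probability bins with empty bins omitted.
Decision-curve net benefit is `TP/n - (FP/n) p_t/(1 - p_t)` with confusion
counts taken at threshold p_t; treat-all and treat-none references are
emitted with every curve. All surfaces are written as tidy CSV; no figure
rendering is performed.

## Attributions

Exact interventional Shapley values by subset enumeration: the value of a
coalition S for sample x is the mean model probability over a fixed
background sample with the S features set to x's values. Exact enumeration
(2^d coalitions) is feasible at the post-screening dimensionality (d = 9 by
default; hard limit d = 14) and makes the additivity identity — base value
plus the sum of a sample's attributions equals the model's output — hold to
floating-point precision, with no sampling noise. The background is a
seed-fixed 100-row subsample of the training partition; global importance is
the mean absolute attribution over the explained rows, descending.

## Determinism and problem sizes

All randomness flows from one configuration seed via spawned per-stage child
seeds; identical configurations produce byte-identical CSV/JSON artifacts
(tested). The test suite and the pipeline determinism checks run the swarm
at reduced budgets (3–4 salps, 2–3 iterations) and explain small row
subsets — the orchestration logic is budget-independent, and the convergence
properties are tested separately on analytic benchmarks at full budget. The
analysis drivers default to 10 salps × 15 iterations, which converges on the
default synthetic cohorts in a few minutes on one CPU. Generator conditions
(774/47 cohort, published quartiles and counts, 10% laboratory missingness)
are never scaled.

## Known limitations

- Independent features make the synthetic task optimistic; absolute metric
  values on synthetic cohorts are not clinical performance estimates.
- The two-piece log-normal matches three quantiles only; tail behaviour
  beyond the quartiles is an assumption, not data.
- Single completed imputation understates imputation uncertainty.
- SSA provides no convergence guarantee; elitism only guarantees
  monotonicity of the incumbent.
- Decision-curve and calibration outputs are point estimates without
  confidence bands.
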