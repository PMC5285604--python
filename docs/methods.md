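# Methods

## The similarity metric

The PSM is built from an unsupervised random forest. Given a cohort of n
patients, a two-class contrast set is formed: the n real rows, plus n
synthetic rows in which each feature column is resampled independently (with
replacement) from its own empirical values. The synthetic class preserves
every marginal distribution but destroys the joint dependence structure, so
a forest trained to separate the classes must split on the cohort's real
covariance/interaction geometry. Forest parameters: 500 trees, candidate
features per split (mtry) equal to the full encoded predictor count,
minimum terminal node size 5. The out-of-bag contrast error is reported as
a diagnostic; values well below 0.5 indicate learnable structure.

For patients i (index) and j (training), Prox_ij counts the trees in which
both reach the same terminal node, so 0 <= Prox_ij <= T, Prox_ii = T, and
the self-proximity matrix is symmetric. One index patient's PSM vector is
its proximity row normalized by the row sum, giving nonnegative weights
summing to 1. Division by T instead is exposed as an option
(`denominator="trees"`); the two differ by a positive per-row scalar and
therefore induce identical neighbor rankings (property-tested). The row-sum
form is the default because CSRF consumes the weights as a sampling
distribution. Proximity is counted over all trees, matching the default
behavior of the classic R forest implementation. An all-zero proximity row
(possible in principle for an extreme outlier under few trees) falls back
to uniform weights with a logged warning rather than failing.

Neighbor selection (`rank_similar`) orders weights descending with ties
broken by ascending patient index, so results are reproducible bit-for-bit.
A cosine-similarity PSM over z-scaled one-hot features is included as a
comparator with the same interface (raw cosines shifted by +1 and
normalized).

### Forest scope under cross-validation

By default the proximity forest is grown *within each fold* on the union of
that fold's training and test features. Outcome labels are never used by
the unsupervised forest, so no label leakage is possible; sharing test
*features* at similarity-learning time mirrors the deployment situation in
which the index patient's covariates are available when similarity is
computed. A `scope="global"` mode grows one forest on the whole cohort
before CV instead; both are available because either reading of
"grown on all data" is defensible, and the per-fold default is the more
conservative one.

## Personalized models

Four families share one contract — fit on the index patient's M nearest
training patients, emit P(death within 30 days):

- **DC**: the neighborhood death fraction; exactly k/M (tested in rational
  arithmetic). With M = n_train it degenerates to the overall training
  mortality rate — a constant score whose AUROC is 0.5 by the tie
  convention. This is the correct reference point for "no personalization".
- **LR**: maximum-likelihood logistic regression, no regularization
  (`C=inf`), lbfgs, max 500 iterations. Perfect separation or a failed fit
  (non-finite coefficients) falls back to a constant risk equal to the
  neighborhood death rate, logged. (The R `glm` analogue warns and returns
  an arbitrary-large-coefficient fit; a deterministic fallback is easier to
  reason about in a sweep that fits thousands of local models.)
- **DT**: CART-style classification tree with conservative stopping in the
  spirit of classic recursive-partitioning defaults: minimum 20 cases to
  split, 7 per leaf. No cost-complexity pruning (scikit-learn's `ccp_alpha`
  scale is not commensurable with the classic relative-complexity
  parameter, so stopping rules carry the regularization).
- **RF**: the shared bootstrap-forest machinery (below) at 500 trees,
  nodesize 1, mtry = floor(sqrt(p)); risk = fraction of trees voting death.

Small homogeneous neighborhoods are routine, not exceptional. Predictors
constant across the M rows (e.g. gender in an all-male neighborhood,
single-level categoricals) are dropped before fitting and ignored at
prediction; single-class outcome neighborhoods short-circuit to a constant
risk of 0 or 1 without fitting. Encoding is schema-driven one-hot with the
first declared level as reference, applied uniformly to all families, and
the column layout depends only on the schema — never on which levels happen
to appear in a neighborhood — so any local model can score any conforming
row.

## CSRF

The case-specific random forest keeps the whole training fold and
personalizes through the bootstrap: each of T=500 trees grows on n_train
draws with replacement where training patient j is drawn with probability
w_ij, the index patient's PSM weight. nodesize 1, mtry = floor(sqrt(p)),
bootstrap sample size n_train per tree (the standard forest convention; the
weighted analogue keeps it). Per-tree RNG streams are spawned from
(seed, tree index), so any tree is reproducible independently.

One `BootstrapForest` implements both this and the personalized RF family,
and it always draws with an explicit probability vector (uniform when no
weights are given). Consequently a uniform-weight CSRF is *bit-identical*
to the standard forest under a shared seed — the equivalence is tested
exactly, plus distributionally against scikit-learn's
`RandomForestClassifier` at matched hyperparameters with majority-vote
aggregation on both sides (vote vs leaf-probability aggregation is a real
protocol difference and is held fixed in the comparison).

## Evaluation harness

10-fold cross-validation, unstratified by default (stratified folds
available). Per fold, each family is trained per test patient at each M on
its grid plus an all-training-data condition, and the fold's scored
patients yield one AUROC and one AUPRC per (family, M, fold). CSRF takes no
M grid (soft thresholding) and runs once per fold.

- AUROC: Mann–Whitney rank form, tied scores credited 0.5. AUPRC: average
  precision with tie blocks collapsed to a single threshold (delegated to
  scikit-learn's `average_precision_score`). Both are cross-checked against
  brute-force pair-count and threshold-enumeration oracles on ~1,000 random
  small instances.
- Summaries: mean ± t_{0.975,k−1}·sd/√k per (family, M).
- Best-vs-all: "best" is the grid point with maximum mean metric; the
  comparison with the all-data condition is a two-sided t test, paired by
  fold (both conditions share folds; the unpaired variant is also
  reported). All-zero differences give p = 1; constant nonzero differences
  fall back to an exact sign test. The type-I error of the paired test is
  verified at ~5% by null simulation.

The M grids scale the reference geometry — DC from 10 upward in steps of
10; LR/RF from ~26% of the training size in steps of ~6.5%; DT from ~32% —
proportionally to the actual training-fold size, because the reference
ranges were defined for a training fold of ~15,500 patients. With a
2,000-patient cohort this gives DC 10..1800 step 10 and LR/RF 400..1800
step 100, DT 500..1800 step 100. Full-scale grids are available by passing
explicit `M_values`.

`max_test_per_fold` caps how many test patients are scored per fold for the
expensive per-patient-forest families (an outcome-stratified deterministic
subsample); metrics are then computed on that subset. This is a variance
knob only — it does not bias the best-vs-all comparison because all
conditions share the same scored subset.

## The synthetic cohort generator

The generator emulates the marginal structure of a large adult ICU cohort:
75 first-24-hour predictors (age truncated-normal on [18,100], mean 64.5,
sd 17; six vitals as sorted min/max pairs per 6-hour window around a
patient-level center; eight labs as right-skewed lognormal min/max pairs;
integer worst GCS in 3..15; nonnegative per-window urinary output;
admission type at 18.0/3.7/78.3% elective/urgent/emergency; male fraction
0.567), and a 30-day mortality outcome with target prevalence 15.10%.

Heterogeneity — the property personalization exploits — enters twice, per
latent cluster c (default C = 4, equal weights):

1. **Feature shifts**: each cluster shifts each signal's mean by a draw of
   sd ~0.6·`cluster_sep` (in units of that signal's between-patient sd;
   default `cluster_sep` = 1), plus tilted intervention rates and ICU
   service mixes. This is what makes cluster membership recoverable from
   features, hence by the RF proximity.
2. **Risk models**: outcome ~ Bernoulli(logistic(a_c + x·β_c)) on the
   standardized encoded features, with β_c drawn N(0, effect_scale²/d) per
   cluster and cluster intercepts spread with sd 0.9·effect_scale. A single
   shared intercept shift is then calibrated by bisection on the realized
   linear predictors until the cohort mean risk is within 0.002 of the
   target prevalence (the public `calibrate_intercepts` does the same by
   Monte Carlo against a supplied feature sampler). Default
   `effect_scale` = 1.4, fixed once so that the AUROC of the true risk
   against the simulated outcomes is ≈0.85 on the default cohort — the
   performance regime of a strong first-day ICU mortality model.

With `effect_scale = 0` all β_c vanish and every patient shares one
constant risk: the homogeneous negative control, under which
personalization can have nothing to exploit.

What the generator does **not** emulate: real ICU feature correlation
structure beyond the cluster mechanism (within a cluster, signals are
independent given the patient center), unit pathologies, missingness (the
complete-case rule is exercised only via hand-made fixtures), repeated
admissions of one patient, or time-series dynamics beyond windowed min/max
summaries. Passing tests therefore demonstrate that the machinery behaves
as specified under controlled heterogeneity — not that any particular
performance level transfers to real ICU data, whose headline metrics
require the original access-restricted database.

## Problem sizes used by the test and acceptance suites

The qualitative reproduction runs at a deliberately reduced scale chosen as
this package's standard desk-scale experiment: 2,000-patient cohorts
(4 clusters), 10-fold CV, 60-tree per-fold proximity forests, the full
scaled DC grid, an RF grid of {400, 900, 1400} with 20-tree per-patient
forests on a 40-patient stratified scored subset per fold. At these sizes
the expected pattern is unambiguous: DC best-M ≈ 0.65 AUROC vs 0.5 all-data
(paired p ~ 1e-6), RF flat in M (p ≈ 0.7), homogeneous control flat
(best ≈ 0.53, p ≈ 0.2). Calibration checks run at n = 50,000.

## Known limitations

- Tree growing is delegated to scikit-learn's CART; exact R
  `randomForest`/`rpart` split semantics (factor-level subset splits,
  surrogate splits) are not reproduced. Categorical predictors are one-hot
  encoded for all families.
- The LR separation fallback (constant risk) is more conservative than R's
  warn-and-fit behavior; at very small M this can flatten the LR curve.
- PSM computation is exact (no approximate nearest neighbors); the
  all-pairs proximity is blocked, not sparse, so very large cohorts pay
  O(n²) memory per block row.
- Absolute-PSM-threshold neighbor selection (as opposed to top-M) and
  per-patient optimal-M selection are deliberately out of scope.
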