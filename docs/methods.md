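# Methods

This note records the statistical procedures implemented in `survselect`,
the defaults that matter, and the design choices made where more than one
reasonable reading existed.

## Cox partial-likelihood core

All learners share the Cox proportional-hazards loss: the negative log
partial likelihood of per-sample risk scores, with the **Breslow**
treatment of tied event times (tied events share the full risk-set
denominator). Breslow is the convention of gradient-boosting survival
objectives and keeps the per-sample derivatives simple:

    g_i = −δ_i + exp(η_i) Σ_{g: t_g ≤ t_i} d_g / D_g
    s_i = exp(η_i) Σ_g d_g / D_g − exp(2η_i) Σ_g d_g / D_g²

where d_g and D_g are the event count and risk-set denominator at the g-th
distinct event time. The gradient sums to zero (the partial likelihood is
invariant to score translation — scores are mean-centered before
exponentiation for numerical stability) and the curvature is nonnegative.
Before forming boosting targets −g/s, the curvature is floored at 1e−12 to
avoid division blow-ups on samples with vanishing curvature. All-censored
input yields a constant likelihood; the loss returns 0 with a warning
rather than failing, so that degenerate resamples surface loudly but not
fatally.

Absolute survival prediction uses the Breslow baseline estimator
S₀(t) = exp(−Ĥ₀(t)) computed from the training scores; a subject's curve is
S₀(t)^exp(η). This supplies IBS evaluation for every learner, including
tree ensembles that natively produce only risk scores.

## Learners

* `penalized_cox` — elastic-net penalized Cox regression
  (scikit-survival's coxnet). The penalty is
  λ Σ_j {α|β_j| + ½(1−α)β_j²}; `l1_ratio` = α = 1 is the lasso.
  Importance is |β̂_j|. Recommended λ range 0.01–0.1, α range 0.05–0.5.
  coxnet internally rescales per-feature penalty factors to mean one; the
  adapter compensates the global penalty so a factor of w means "feature
  penalized at exactly λ·w".
* `xgb_cox`, `lgb_cox` — XGBoost / LightGBM with the package's exact Cox
  gradient/curvature as custom objective. Defaults: learning rate 0.05
  (the largest of the conventional search set {0.001, 0.005, 0.01, 0.05},
  appropriate for the default 100 rounds), subsample fraction 0.5, L1/L2
  regularization 0.05, max depth 3 (XGB) / 15 leaves (LGB). Importance is
  total split gain; a feature never split on scores exactly zero.
  The training partial likelihood is recorded per round; with learning
  rates ≤ 0.05 it is nonincreasing (verified in tests).
* `rsf` — random survival forest (scikit-survival, log-rank splitting).
  Importance is permutation importance on the training data with negative
  values clipped to zero, which is considerably more expensive than split
  gain; the repeat count (default 3) is a speed/stability knob.

Risk scores are always oriented "larger = higher hazard". New learners
register a fit function in `survselect.learners.REGISTRY` and inherit the
whole selection/benchmark machinery. A deep-learning Cox adapter would slot
in the same way; none is shipped.

## PROMISE-Cox

1. **Penalty tuning.** (λ, α) are searched on a grid by event-stratified
   k-fold CV (default 5). The validation criterion is the **partial
   likelihood** (deviance), the convention of `cv.glmnet`, combined with
   the **one-standard-error rule**: among grid points within one SE of the
   best mean validation score, the sparsest (largest λ, then largest α)
   wins. Validation C-index is available as an option, but it is a poor
   tuning surface here: a null fit's C-index is pinned at exactly 1/2, so
   on data without signal some overfit penalty always beats it by chance,
   whereas the validation partial likelihood genuinely decreases with
   overfitting.
2. **Stability selection.** 100 event-stratified bootstrap resamples of
   size n are drawn (events and censored subjects resampled separately so
   every resample is fittable); the model is refit on each at (λ*, α*),
   and feature j's selection frequency f_j is the fraction of resamples
   with β̂_j ≠ 0. The panel is {j : f_j ≥ π}, π ∈ [0.6, 0.8], default 0.6.
3. **Randomized penalty.** Within each resample every feature's penalty is
   multiplied by 1 or 1/w with equal probability (two-point randomized
   lasso; weakness w, default 0.2; w = 1 disables it). Without this, a
   feature that is spuriously correlated with survival *in the observed
   cohort* re-enters nearly every bootstrap fit whenever the tuned penalty
   is weak, and no frequency threshold can screen it out: on pure-noise
   data (n = 200, p = 50) the plain bootstrap frequencies put 10–50
   features above π = 0.6. With the randomization, true signals (which
   survive a 5× penalty) keep frequency ≈ 1 while sample-specific noise is
   broken apart; measured on the same null datasets the selector returns
   essentially nothing, and on the linear scenario it keeps TPR = 1 with
   FPR ≈ 0 even at the weakest grid penalty.

Thresholding is monotone by construction (the frequencies do not depend on
π), and the entire procedure is a deterministic function of the seed.

## CV + top-k selection

For a nonlinear learner: per CV fold, fit on the training portion with all
features, rank by importance, refit on the top-k panel for each k in the
grid, and record the validation C-index. The panel size k* maximizes the
mean validation C-index (smallest k on ties, favoring parsimony). The final
panel is the top-k* of a full-data fit (option: mean rank across folds);
features with zero full-data importance are never selected even when
k* exceeds the number of used features. The default grid doubles from 5
(5, 10, 20, 40, …) capped at min(p, n/5).

The C-index is an appropriate tuning surface in this stage — unlike the
penalized path, the compared objects are discrete panels refit from
scratch, and the degenerate null-fit case does not arise.

`refit_on_selected` trains the final prediction model on the selected
columns; an empty selection falls back to the full feature set with a
warning rather than failing, so benchmark replicates always produce a
prediction record.

## Evaluation metrics

* **C-index** (Harrell): orderable pairs are {(i, j): t_i < t_j, δ_i = 1};
  a pair is concordant when the earlier-failing subject has the strictly
  higher risk score; score ties count 1/2 by default (a `strict` policy
  counts them 0). Writing the concordance indicator as
  1{H(x_i) < H(x_j)} would invert the orientation under the
  "larger score = larger hazard" convention used throughout; the package
  uses the standard orientation, under which larger C means better
  ranking.
* **IPCW Brier score** at time t: subjects who failed before t contribute
  Ŝ(t|x)²/Ĝ(t_i−), subjects still under observation after t contribute
  (1−Ŝ(t|x))²/Ĝ(t), subjects censored by t contribute nothing. Ĝ is the
  Kaplan–Meier estimate of the censoring survival (indicator 1−δ),
  evaluated left-continuously at event times. A subject observed exactly
  at t is excluded by the strict inequalities (documented boundary; tested).
  A zero Ĝ at a needed point raises an error naming the time.
* **IBS**: (1/t_max) ∫₀^{t_max} BS(t) dt via the trapezoidal rule on the
  grid of unique observed times up to t_max (default: the largest observed
  time). BS(t) is a step-like function with jumps at event times, so the
  trapezoidal value carries an O(grid spacing) boundary error; the metric
  tests quantify this and the closed-form cases (constant-½ predictor
  → 0.25, perfect predictor → 0).
* **Selection TPR/FPR**: |selected ∩ true|/|true| and
  |selected \ true|/(p − |true|).

## Synthetic scenarios

Covariates are i.i.d. standard normal except in the risk-group cohort. The
first q features carry signal; the rest are noise. The printed conditional
expressions exp(η) act on the **hazard** (T ~ Exponential(rate = exp(η)),
the Cox convention "hazard ∝ exp{H(x)}"), not on the mean of T. The mean
reading is available (`hazard_scale=False`) but produces ~100% censoring in
scenario 3, where the mixture censoring law (0.02 with probability 1/3,
Uniform(0, 0.02) otherwise) pins censoring times below 0.02; under the
hazard reading the empirical censoring rate is ~33%, matching the intended
~30% regime. The same flag governs every scenario.

1. **linear** — η = X₁ + ⋯ + X_q; censoring Exponential(mean q).
2. **quadratic** — η = (X₁² + ⋯ + X_q²)/2; censoring as scenario 1
   (no separate law is specified for this scenario; adjacent scenarios
   share the design). Under the hazard reading the failure times are far
   shorter than the censoring times, so this scenario is effectively
   uncensored.
3. **nonlinear** — η = 2[Φ(1{X₁>0.5}+X₂²−1) + Φ(0.5X₃+X₄²−1)
   + Φ(0.5X₅+X₆²−1) + Φ(sin X₇+X₈²−1) + Φ(cos X₉+X₁₀²−1)] + X₁₁+⋯+X_q,
   Φ the standard normal CDF; mixture censoring as above; requires q ≥ 10.
4. **interaction** — η = 4[Φ(1{X₁>0.4}·X₂²−1) + Φ(0.6X₃+X₄²−1)
   + Φ(0.5X₅·sin X₆²−1) + Φ(cos X₇+X₈²−1) + Φ(sin X₉·X₁₀²−1)] + X₁₁+⋯+X_q;
   failure times Weibull with shape 2 (configurable) and conditional mean
   exp(−η); censoring as scenario 3.
5. **risk_groups** — 2000 features, three populations of 400 samples with
   means 5/10/15 (unit SD); the latent scale
   υ = 3[Φ(1{X₁>10}+X₂−1) + Φ(0.5X₃+1{X₄>5}−1) + Φ(1{X₅>10}+1{X₆>15})
   + Φ(1{X₇>20}+X₈²−1) + Φ(1{X₉>20}+X₁₀²−1)] enters the Weibull survival
   as S(t) = exp(−υ t²), so a larger υ means worse survival, consistent
   with the high/low-risk labels (υ above/below the cohort median; the
   label threshold is a package choice — balanced classes). Reading υ
   literally as the Weibull scale would *lengthen* survival with larger υ
   and contradict the label semantics, so the proportional-hazards reading
   is the default. No censoring is applied (all events observed).

All randomness flows through one seeded generator per dataset; identical
configurations are bit-reproducible. Latent failure/censoring times and υ
are retained on the dataset object for testing.

What the generators do **not** emulate: correlated features (real omics
blocks are strongly collinear), heavy-tailed or batch-affected
measurements, informative censoring, and competing risks. Passing the
benchmark therefore demonstrates correct behavior of the selectors under
clean, independent features — it does not certify performance on real
multi-omic cohorts, where correlated signals make "the" true panel
ill-defined.

## Benchmark harness

Each (scenario, method, replicate) triple simulates a fresh cohort, splits
it 80/20, runs selection on the training part only, refits the method's
prediction learner on the selected panel (the evaluated model is the
refit-on-panel model, not the full-feature model — switchable by passing
the full index set), and scores the held-out test part: C-index, IBS (via
the training Breslow baseline), and TPR/FPR against the known signals.
Seeds for simulation, splitting and methods derive deterministically from
(base seed, scenario, method, replicate); a repeated run is byte-identical.
Replicate failures are logged and dropped, never imputed. Method ranking
averages within-replicate ranks by test C-index (ties get the average
rank). The full-scale design uses 100 replicates; the default profile is a
scaled-down 10, which is the size used throughout the test suite.

The risk-group experiment trains each learner on 1000 random samples of
the risk-group cohort, dichotomizes predicted risk on the remaining 200 at
the *training* median predicted score, and reports misclassification
against the latent labels plus tidy Kaplan–Meier curve data for true and
predicted groups.

## Numerical and interface choices

* Times must be strictly positive and finite; events coded {0, 1}. Missing
  feature values are rejected at the I/O layer (the penalized model cannot
  handle them; passing them through to the tree learners is a possible
  extension, not enabled).
* TSV/CSV round-trips are bit-exact (17-significant-digit output,
  round-trip float parsing).
* Tie-breaks are deterministic everywhere: feature ranking breaks
  importance ties by ascending index; k ties prefer the smallest k;
  penalty-grid ties prefer the sparsest fit.
* Test-suite problem sizes: unit tests run on cohorts of 100–600 samples;
  the replicated experiments use n = 1000, p = 100, q = 10 with 10
  replicates, and n = 5000 for the scenario-3 censoring check.

## Known limitations

* The boosted learners' hyperparameters are taken from the recommended
  ranges rather than tuned per dataset; only the panel size k is tuned
  inside the selection loop.
* RSF permutation importance is slow (n_repeats × p scoring passes) and is
  the practical bottleneck for RSF-based top-k selection on wide matrices.
* The IBS depends on the integration grid near its upper limit when the
  censoring KM reaches zero; the default t_max (largest observed time) is
  safe for the shipped scenarios but a quantile cutoff may be preferable
  for heavily censored real data.
* No deep-learning survival adapter, no accelerated-failure-time variants,
  no competing risks, no time-varying covariates.
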