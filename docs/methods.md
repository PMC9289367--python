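# Methods

This note documents the models, defaults, and numerical choices behind
`rsbi_traj`, and what the synthetic-cohort tests do and do not establish.

## The analysis model

**Featurization.** Subject *i*'s weekly RSBI series is reduced to the
ordinary-least-squares fit `RSBI_i(w) ≈ β0_i + β1_i · w` (week 0 = RCC
arrival).  Subjects with fewer than two distinct measurement weeks are not
featurizable and are routed to an explicit "unclusterable" report — the
analysis-population analogue of excluding records with missing ventilator
data.  All subjects contribute equally regardless of their number of
observations; the regression degree is fixed at 1 (a recovery/deterioration
*trend* is the clinical object of interest, and two coefficients keep the
cluster space interpretable).

**Clustering.** (β0, β1) pairs are z-scored per dimension before k-means:
intercepts (~50–120 breaths/min/L) and slopes (~±8 per week) are on
incommensurate scales, and unstandardized Euclidean distance would ignore
the slope entirely.  k-means is Lloyd's algorithm with k-means++ seeding,
best of `n_init=50` restarts by WSS, convergence at relative WSS change
`tol=1e-6` or 300 iterations.  The WSS is asserted non-increasing at every
Lloyd iteration; an empty cluster is re-seeded at the worst-fit point.

**Choosing K.** k-means has no likelihood, so information criteria require
a model. Two hard-assignment spherical-Gaussian families are implemented:

* `pooled` — one pooled variance σ² = WSS/(nd),
  LL = −(nd/2)(ln 2πσ² + 1), p = Kd + 1.  This is the minimal model whose
  ML hard assignment is the k-means partition, but its BIC is *not* usable
  for selecting K at cohort scale: splitting a genuinely Gaussian cluster
  always buys ~8% of WSS against a penalty of only d·ln(n), so BIC
  decreases monotonically in K (the classic over-splitting behaviour of
  x-means-style criteria).  It is retained for formula-level checks and
  diagnostics.
* `classification` (default) — mixing proportions plus per-cluster
  variances: LL = Σ_c [ n_c ln(n_c/n) − (n_c d/2)(ln 2πσ̂_c² + 1) ],
  p = (K−1) + Kd + K.  The entropy term charges ln 2 per point for an even
  split while the fit gain for splitting a single spherical Gaussian is
  only ≈ (d/2)·ln(1/0.68) ≈ 0.39 per point, so min-BIC stops at the number
  of genuinely separated components.  On the default synthetic world this
  selects K = 4 for every seed tried.

Degenerate zero variances (perfect fits) are floored at 1e-12 with a
warning.  Metrics are computed on the **post-merge** model, and the chosen
K is the min-BIC row of the emitted table; the full table is always written
so a human can override the automatic choice, mirroring how the original
protocol combined statistical metrics with domain expertise.

**Small-cluster merging.** Clusters with fewer than 20 subjects are
iteratively dissolved — smallest first — into the nearest remaining
centroid (standardized space), with centroids recomputed after each
dissolution.  Subject count is conserved by construction.

**Canonical labels.** On de-standardized centroids: |slope| < 2
breaths/min/L/week counts as flat; flats are labelled A (higher intercept)
then B; positive slopes C; negative slopes D; leftovers continue E, F, …
in descending-intercept order.  The threshold 2 sits midway between the
archetype slopes (0 and ±8) on the between-subject slope SD scale.

**Profiles.** The per-cluster band is the cross-sectional mean over
subjects observed in a given week with a 90% t-interval
(mean ± t(0.95, n−1)·SD/√n).  This deliberately assumes no longitudinal
model; weeks with n < 2 report a mean but no band rather than a fabricated
one.  Percentages in outcome tables are half-up integers, matching the
"n (%)" table style; missing outcome values get an explicit `missing` row.

**Group comparison.** Categorical variables: Pearson χ² without continuity
correction (standard for r×c tables); a zero marginal is a named error.
Numeric variables: Shapiro–Wilk per group at α = 0.05; ANOVA with
mean ± SD summaries only when every group passes, otherwise tie-corrected
Kruskal–Wallis with median (Q1, Q3) summaries (quartiles by linear
interpolation).  A `route` argument can force either branch.  P-values
render as three decimals with "<0.001" below; no multiplicity adjustment
is applied (none is applied in the protocol being replicated).

**Membership prediction.** Gradient-boosted trees (multinomial
cross-entropy), exhaustive 60-point grid: trees 1..15 × depth
{10, 15, 20, 25}, learning rate 0.1, ≥ 30 observations per terminal node,
scored by mean accuracy under stratified 10-fold CV; ties break toward
fewer trees then shallower depth (prefer the simpler model).  Because
boosting is stagewise and deterministic here, the accuracies for all tree
counts at one depth are read from `staged_predict_proba` of a single
15-stage fit per fold — an exact shortcut, asserted against separately
fitted models in the tests.  Relative influence is the per-feature total
split squared-error improvement over all trees, normalized to 100.
`compare_models` uses 5×10-fold repeated stratified CV with shared folds
across GBM, random forest, and L1 multinomial regression, reporting
accuracy and Cohen's kappa per resample.

**Explanations.**
*Breakdown*: features are fixed to the instance's values one at a time in
descending order of single-feature effect; the contribution of a feature is
the change in the background-averaged prediction when it is fixed after all
earlier ones.  Contributions telescope, so baseline + Σ contributions
equals the predicted probability exactly.  Pairs among the top-5 single
effects whose joint effect deviates from additivity by > 0.01 (probability
scale) are flagged as interactions; uncertainty intervals are 10th–90th
percentiles of per-feature contributions across 25 random fixing orders.
The background is a seeded subsample of ≤ 200 training rows (conservation
holds for any background).
*Local surrogate*: Gaussian perturbations scaled by per-feature training
SDs, proximity kernel exp(−d²/w²) on standardized distance with default
width 0.75·√d, weighted least squares on the explained class probability,
top-|coefficient| refit for sparsity; signs are reported as
supporting/contradicting.  With infinite kernel width and no sparsity the
result is exactly the global WLS fit, which the tests verify in closed form
on a linear model.  Binary (one-hot) columns are perturbed like numeric
ones — a simplification that keeps the surrogate linear-algebraic.

## The synthetic world

The generator emulates the *statistical structure* the analysis assumes,
not ventilator physiology:

* **Trajectories.** Four archetypes with per-subject random lines:
  A (115, 0), B (55, 0), C (70, +8), D (110, −8) breaths/min/L (/week),
  between-subject SDs 15 (intercept) and 2 (slope), within-subject noise SD
  10, RSBI floored at 5 for positivity.  Archetype means are invented
  (chosen so the clinical RSBI ≈ 105 weaning threshold separates "high"
  from "low"); the published source shows shapes, not numbers.  Observed
  RR/MV are back-solved from simulated RSBI through a lognormal tidal
  volume around 0.3 L, so derived indices reproduce the latent RSBI
  exactly.  The weekly schedule runs to week min(9, 7 + Geom(0.35)) with
  10% independent missingness after week 0 (week 0 never missed), giving a
  median of ~9 visits — consistent with a ~65-day median hospital stay.
* **Covariates.** Ten labs/scores with cluster-conditional *medians* equal
  to the published per-cluster medians (e.g. magnesium 1.99/1.88/1.87/1.92
  for A–D), normal for symmetric variables and lognormal for right-skewed
  labs (TSH, cortisol, BUN).  Scales are the published-IQR-implied SDs
  divided by `covariate_signal`.  The default signal (20) is the
  **strong-signal world**: cluster membership is recoverable from baselines
  by construction (mixture Bayes error < 1%), which is what the prediction
  protocol's high published accuracy requires.  `covariate_signal=1`
  restores published-IQR spreads — the **weak-signal world**, in which
  4-class prediction from baselines is realistically hard.  Medians are
  invariant to the signal setting, so table-one checks hold in both.
* **Outcomes.** Last-follow-up status, weaning, in-hospital death,
  tracheostomy and sex are categorical draws from the published per-cluster
  rates, independent of one another given the cluster (only marginal rates
  are targeted; no within-subject outcome correlation is modelled).
* **Screening.** 349 of 1,720 admissions excluded; the per-reason split
  (120/60/45/40/34/50) is invented but sums exactly, and
  included + excluded = screened is enforced.

A green test on this world establishes that the *pipeline machinery* is
correct under its stated assumptions.  It does not establish anything
about real PMV cohorts: real trajectories are not linear-plus-noise, real
covariate effects are far weaker (Table-scale median gaps of ~0.1 SD), and
real outcomes are correlated within subjects.

## Known limitations

* **Cluster-recovery ceiling.** Under the stated archetype dispersions,
  archetypes A (115, 0) vs D (110, −8) and B (55, 0) vs C (70, +8) overlap:
  clustering even the *true* per-subject coefficients yields ARI ≈ 0.88
  (agreement ≈ 0.96), and clustering OLS estimates yields ARI 0.81–0.86
  across seeds.  A 0.90 ARI bar is therefore unreachable in this world
  without changing the stated dispersions, which we deliberately do not do.
* **CV-accuracy ceiling.** The classifier is scored against the *clustered*
  labels while covariates are generated from the *true* archetype, so its
  accuracy is bounded by the clustering agreement (~0.93–0.94 measured;
  the classifier recovers the true archetype at ~0.99).  The best grid
  accuracy lands at ~0.93, short of the 0.95 that would hold if clustering
  were error-free.
* The pooled-variance information criterion must not be used for selecting
  K (see above); it is exposed for diagnostics only.
* Subjects observed in exactly one week are readable and profiled but not
  clusterable; they appear only in the unclusterable report.
* The explainers operate on probabilities of a softmax ensemble; breakdown
  contributions are exact by construction, but LIME-style weights are local
  approximations whose quality degrades with kernel width.
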