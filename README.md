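# rsbi-traj

Trajectory clustering of the **rapid shallow breathing index (RSBI)** in
patients on prolonged mechanical ventilation (PMV, ≥ 21 days of ventilator
support), with prediction of cluster membership from variables available on
arrival at a respiratory care center (RCC).

PMV patients are clinically heterogeneous; their weekly weaning indices
trace out distinct recovery and deterioration patterns.  This package
implements a complete, tested version of a published analysis protocol for
that problem:

1. **Weaning indices.** From respiratory rate RR (breaths/min) and minute
   ventilation MV (L/min) measured off the ventilator:
   `TV = MV / RR` (L) and `RSBI = RR / TV = RR² / MV` (breaths/min/L).
   High RSBI (rapid shallow breathing) predicts weaning failure.
2. **Two-step trajectory clustering.** Each subject's weekly RSBI series is
   summarized by the OLS intercept β₀ and slope β₁ of RSBI on week; k-means
   (Lloyd's algorithm, k-means++ seeding, best of 50 restarts) partitions
   subjects in z-scored (β₀, β₁) space.  The number of clusters is chosen by
   minimum BIC of a hard-assignment Gaussian classification likelihood over
   K = 1..8, after dissolving clusters with fewer than 20 subjects into
   their nearest neighbours.  Surviving clusters receive canonical labels:
   **A** persistently high RSBI, **B** constantly low, **C** increasing,
   **D** declining.
3. **Profiles and table-one statistics.** Per-cluster weekly means with 90%
   t-intervals for every ventilator parameter; per-cluster outcome rates;
   χ² tests for categorical variables and normality-routed ANOVA /
   Kruskal–Wallis for numeric ones.
4. **Membership prediction.** A gradient-boosted tree classifier
   (multinomial cross-entropy) tuned by exhaustive grid search — trees
   1–15, depth {10, 15, 20, 25}, learning rate 0.1, ≥ 30 observations per
   terminal node — scored by stratified 10-fold CV accuracy; relative-influence
   variable importance; repeated-CV comparison against a random forest and
   L1 multinomial regression; LIME-style and additive-breakdown
   instance-level explanations.

Because the underlying clinical registry is not redistributable, the
package ships a **synthetic cohort generator** whose defaults encode the
published cohort's structure (cluster mix 349/461/323/238 of 1,371;
screening flow 1,720 → −349 → 1,371; per-cluster outcome rates such as
last-follow-up mortality 72/61/62/63%; cluster-conditional lab medians such
as magnesium 1.99 mg/dl in A vs 1.87 in C).  Every stage of the pipeline is
tested against that stated world.  See `docs/methods.md` for what the
generator does and does not emulate.

## Worked example

```python
import pandas as pd
from rsbi_traj import synthetic_cohort as sc, trajectory_clustering as tc
from rsbi_traj import cluster_profiles as cp, membership_prediction as mp

spec = sc.ScreeningSpec()
cfg = sc.default_config(
    n_subjects=1200, seed=7,
    screening=sc.ScreeningSpec(n_screened=1200 + spec.n_excluded),
)
records, log = sc.generate_cohort(cfg)

features, _ = tc.featurize(r.trajectory for r in records)
model, metrics, _ = tc.select_K(features, k_range=range(1, 9), seed=8)
labels = model.labelled_assignments()

cov = sc.covariates_frame(records)
X, _ = mp.encode_features(cov.loc[labels.index])
bundle = mp.tune_and_fit(X, labels, seed=9)
```

This run prints (`metrics`, truncated):

```
K_requested  K_effective     WSS      LL     BIC
1                      1  2400.0 -3405.5  6832.2
2                      2  1110.4 -3292.0  6633.6
3                      3   711.7 -3162.2  6402.5
4                      4   469.2 -3083.7  6273.7   <- min BIC
5                      5   397.2 -3143.9  6422.6
...
```

so K = 4 is selected, with de-standardized centroids recovering the four
archetypes (intercept, slope per week):

```
A  118.1  +0.7      persistently high
B   52.7  +0.1      constantly low
C   70.6  +8.1      increasing
D  110.3  -7.0      declining
```

cluster sizes A 258 / B 403 / C 300 / D 239, and last-follow-up mortality
of 68/62/59/66% across A–D in this synthetic draw.  The tuned classifier
reports

```
best params: {'n_trees': 15, 'depth': 10, 'learning_rate': 0.1, 'min_obs_in_node': 30}
best mean CV accuracy: 0.932
```

with relative influence led by the covariates given the strongest
cluster-conditional separation (prealbumin 43.8, magnesium 25.8, cortisol
22.8 of 100).  The CV accuracy is capped near 0.93 by design: the
classifier is scored against the *clustered* labels, and the clustering
itself agrees with the generating archetypes at ≈ 0.94 under the default
trajectory-noise settings (`docs/methods.md`, "Known limitations").

The same pipeline is available from the shell:

```sh
rsbi-traj simulate --n-subjects 1200 --seed 7 --out out/data
rsbi-traj cluster  --traj out/data/trajectories.csv --seed 8 --out out/clust
rsbi-traj predict  --covariates out/data/covariates.csv \
                   --assignments out/clust/assignments.csv --seed 9 --out out/pred
rsbi-traj run      --config examples/demo.yaml       # or everything at once
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic cohort, reruns
the two-step clustering and the full tuning grid from scratch, and writes
the best mean 10-fold CV accuracy as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness is derived from `--seed`; the run takes well under a minute
on one CPU.
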