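"""Shared fixtures: synthetic cohorts at two scales and a tuned classifier.

The 1,200-subject cohort, its clustering and the tuned boosted-tree bundle
are session-scoped because the grid search is the expensive step (~15 s);
everything downstream (importances, explanations, acceptance checks) reuses
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rsbi_traj import membership_prediction as mp
from rsbi_traj import synthetic_cohort as sc
from rsbi_traj import trajectory_clustering as tc
from rsbi_traj.weaning_indices import TrajectorySeries, VentilatorMeasurement


def make_series(weeks, rsbi, subject_id="s0", tv=0.4):
    """Build a trajectory whose derived RSBI equals the given values.

    With constant tidal volume tv, rr = rsbi * tv and mv = rr * tv give
    rr^2 / mv = rsbi exactly.
    """
    ms = [
        VentilatorMeasurement(week=int(w), rr=float(r) * tv, mv=float(r) * tv * tv)
        for w, r in zip(weeks, rsbi)
    ]
    return TrajectorySeries(subject_id=subject_id, measurements=ms)


@pytest.fixture(scope="session")
def make_series_factory():
    return make_series


def _sized_config(n, seed, **overrides):
    spec = sc.ScreeningSpec()
    return sc.default_config(
        n_subjects=n,
        seed=seed,
        screening=sc.ScreeningSpec(
            n_screened=n + spec.n_excluded, reason_counts=spec.reason_counts
        ),
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject default-world cohort (fast everyday fixture)."""
    cfg = _sized_config(300, seed=3)
    records, log = sc.generate_cohort(cfg)
    return records, log, cfg


@pytest.fixture(scope="session")
def default_cohort():
    """The default 4-archetype cohort at the n=1,200 analysis scale."""
    cfg = _sized_config(1200, seed=1)
    records, log = sc.generate_cohort(cfg)
    return records, log, cfg


@pytest.fixture(scope="session")
def clustered_default(default_cohort):
    """Two-step clustering of the default cohort (K range 1..8, min-BIC)."""
    records, _, _ = default_cohort
    feats, bad = tc.featurize(r.trajectory for r in records)
    model, table, _ = tc.select_K(feats, k_range=range(1, 9), seed=101, n_init=50)
    labels = model.labelled_assignments()
    truth = pd.Series({r.subject_id: r.true_cluster for r in records})
    return model, table, labels, truth


@pytest.fixture(scope="session")
def tuned_bundle(default_cohort, clustered_default):
    """Boosted-tree classifier tuned on the full grid (trees 1-15 x depths)."""
    records, _, _ = default_cohort
    _, _, labels, _ = clustered_default
    cov = sc.covariates_frame(records)
    X, _ = mp.encode_features(cov.loc[labels.index])
    return mp.tune_and_fit(X, labels, seed=5), X


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
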