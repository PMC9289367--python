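"""Two-step trajectory clustering: per-subject OLS, then k-means.

Each subject's RSBI series is summarized by the intercept and slope of an
individually fitted ordinary-least-squares line of RSBI on week.  Subjects
are then partitioned by k-means on the z-score-standardized (intercept,
slope) pairs; the number of clusters is chosen by information criteria over
a K range, clusters smaller than a minimum size are dissolved into their
nearest neighbours, and the surviving clusters receive canonical labels:
A persistently high (flat, high intercept), B constantly low (flat, low
intercept), C increasing (positive slope), D declining (negative slope).

Information criteria need a likelihood; k-means itself has none.  Two
hard-assignment Gaussian families are provided (see :func:`model_metrics`):

``pooled``
    spherical Gaussian with one pooled variance,
    ``LL = -(n d / 2) (ln(2 pi sigma^2) + 1)``, ``sigma^2 = WSS/(n d)``,
    ``p = K d + 1``.  This is the simplest model under which the k-means
    assignment is the maximum-likelihood one, but with large n its BIC keeps
    rewarding splits of genuinely Gaussian clusters.
``classification``
    the classification (hard-EM) likelihood of a spherical mixture with
    mixing proportions and per-cluster variances,
    ``LL = sum_c [ n_c ln(n_c/n) - (n_c d / 2)(ln(2 pi sigma_c^2) + 1) ]``,
    ``p = (K - 1) + K d + K``.  The entropy term makes splitting a single
    Gaussian cluster unprofitable (ln 2 per point against a fit gain of
    about 0.39), so min-BIC is consistent for the number of well-separated
    components.  This is the default selection family.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .weaning_indices import TrajectorySeries

__all__ = [
    "CoefficientVector",
    "ClusterModel",
    "fit_subject_regression",
    "featurize",
    "kmeans",
    "model_metrics",
    "merge_small_clusters",
    "select_K",
    "canonical_labels",
    "two_step_cluster",
]


@dataclasses.dataclass(frozen=True)
class CoefficientVector:
    """Per-subject OLS summary of the RSBI trajectory."""

    subject_id: str
    intercept: float  # breaths/min/L at week 0
    slope: float  # breaths/min/L per week
    n_obs: int
    residual_ss: float


class UnclusterableSubjectError(ValueError):
    """Subject has fewer than two distinct measurement weeks."""


def fit_subject_regression(series: TrajectorySeries) -> CoefficientVector:
    """OLS intercept and slope of RSBI on week for one subject.

    Raises :class:`UnclusterableSubjectError` when fewer than two distinct
    weeks are observed (the line is not identifiable); callers batch these
    into an "unclusterable" report rather than dropping them silently.
    """
    w = series.weeks.astype(float)
    y = series.rsbi
    if len(np.unique(w)) < 2:
        raise UnclusterableSubjectError(
            f"subject {series.subject_id}: need >=2 distinct weeks, have {len(np.unique(w))}"
        )
    X = np.column_stack([np.ones_like(w), w])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return CoefficientVector(
        subject_id=series.subject_id,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        n_obs=len(y),
        residual_ss=float(resid @ resid),
    )


def featurize(
    series: Iterable[TrajectorySeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit per-subject regressions over a cohort.

    Returns ``(features, unclusterable)``: features indexed by subject_id
    with columns intercept/slope/n_obs/residual_ss, and a report of subjects
    that could not be featurized, with the reason.
    """
    rows, bad = [], []
    for s in series:
        try:
            c = fit_subject_regression(s)
        except UnclusterableSubjectError as e:
            bad.append({"subject_id": s.subject_id, "reason": str(e)})
            continue
        rows.append(dataclasses.asdict(c))
    feats = pd.DataFrame(
        rows, columns=["subject_id", "intercept", "slope", "n_obs", "residual_ss"]
    ).set_index("subject_id")
    return feats, pd.DataFrame(bad, columns=["subject_id", "reason"])


# ----------------------------------------------------------------------
# k-means (Lloyd's algorithm, k-means++ seeding, best of n_init restarts)
# ----------------------------------------------------------------------


def _kmeanspp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[k] = X[rng.integers(n)]
            continue
        centers[k] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[k]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    K = len(centers)
    prev_wss = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        wss = float(d2[np.arange(len(X)), assign].sum())
        # Lloyd's objective is non-increasing; a rise means a logic error.
        if wss > prev_wss + 1e-8 * max(1.0, prev_wss):
            raise AssertionError("k-means objective increased")
        for k in range(K):
            mask = assign == k
            if mask.any():
                centers[k] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                centers[k] = X[d2[np.arange(len(X)), assign].argmax()]
        if prev_wss - wss <= tol * max(1.0, prev_wss):
            break
        prev_wss = wss
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    wss = float(d2[np.arange(len(X)), assign].sum())
    return assign, centers, wss


def kmeans(
    X: np.ndarray,
    K: int,
    n_init: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means on rows of X; returns (assignments, centroids, WSS).

    Lloyd's algorithm with k-means++ seeding, keeping the best of ``n_init``
    restarts by within-cluster sum of squares; deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of subjects n={n}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        centers = _kmeanspp(X, K, rng)
        assign, centers, wss = _lloyd(X, centers.copy(), max_iter, tol, rng)
        if best is None or wss < best[2]:
            best = (assign, centers, wss)
    return best


# ----------------------------------------------------------------------
# model container + metrics
# ----------------------------------------------------------------------


@dataclasses.dataclass
class ClusterModel:
    """A fitted k-means partition in standardized coefficient space."""

    K: int
    centroids_std: np.ndarray  # (K, d) in z-score space
    feature_mean: np.ndarray  # (d,) standardization location
    feature_sd: np.ndarray  # (d,) standardization scale
    assignments: pd.Series  # subject_id -> cluster index 0..K-1
    wss: float
    n: int
    d: int
    ll: float = float("nan")
    aic: float = float("nan")
    bic: float = float("nan")
    labels: dict[int, str] = dataclasses.field(default_factory=dict)

    @property
    def centroids_raw(self) -> np.ndarray:
        """Centroids de-standardized to (intercept, slope) units."""
        return self.centroids_std * self.feature_sd + self.feature_mean

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def labelled_assignments(self) -> pd.Series:
        """subject_id -> canonical letter."""
        if not self.labels:
            raise ValueError("model has no canonical labels; call canonical_labels()")
        return self.assignments.map(self.labels).rename("cluster")


def model_metrics(
    model: ClusterModel, X: np.ndarray | None = None, family: str = "classification"
) -> tuple[float, float, float]:
    """(LL, AIC, BIC) of a hard k-means partition under a Gaussian family.

    ``family='pooled'`` uses a single pooled spherical variance
    (sigma^2 = WSS/(n d), p = K d + 1); ``family='classification'`` (default
    for K selection) adds mixing proportions and per-cluster variances.
    Degenerate zero variances are floored at 1e-12 with a warning.
    AIC = -2 LL + 2 p and BIC = -2 LL + p ln n in both families.
    """
    n, d, K = model.n, model.d, model.K
    if family == "pooled":
        sigma2 = model.wss / (n * d)
        sigma2 = _floor_var(sigma2)
        ll = -(n * d / 2.0) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        p = K * d + 1
    elif family == "classification":
        if X is None:
            raise ValueError("family='classification' needs the feature matrix X")
        assign = model.assignments.to_numpy()
        ll = 0.0
        for k in range(K):
            mask = assign == k
            nk = int(mask.sum())
            if nk == 0:
                continue
            wss_k = float(((X[mask] - model.centroids_std[k]) ** 2).sum())
            sigma2_k = _floor_var(wss_k / (nk * d))
            ll += nk * np.log(nk / n) - (nk * d / 2.0) * (
                np.log(2.0 * np.pi * sigma2_k) + 1.0
            )
        p = (K - 1) + K * d + K
    else:
        raise ValueError(f"unknown likelihood family {family!r}")
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * np.log(n)
    return float(ll), float(aic), float(bic)


def _floor_var(sigma2: float, floor: float = 1e-12) -> float:
    if sigma2 < floor:
        warnings.warn("degenerate zero within-cluster variance; flooring at 1e-12")
        return floor
    return sigma2


def _fit_model(
    Xstd: np.ndarray,
    index: pd.Index,
    mean: np.ndarray,
    sd: np.ndarray,
    K: int,
    n_init: int,
    max_iter: int,
    tol: float,
    seed: int | None,
) -> ClusterModel:
    assign, centers, wss = kmeans(
        Xstd, K, n_init=n_init, max_iter=max_iter, tol=tol, seed=seed
    )
    return ClusterModel(
        K=int(len(centers)),
        centroids_std=centers,
        feature_mean=mean,
        feature_sd=sd,
        assignments=pd.Series(assign, index=index, name="cluster"),
        wss=wss,
        n=len(Xstd),
        d=Xstd.shape[1],
    )


def merge_small_clusters(
    model: ClusterModel, X: np.ndarray, min_size: int = 20
) -> ClusterModel:
    """Dissolve clusters smaller than ``min_size`` into their neighbours.

    Iteratively removes the smallest undersized cluster, reassigns its
    members to the nearest remaining centroid (standardized space),
    recomputes centroids, and repeats until every cluster has at least
    ``min_size`` members or a single cluster remains.  Subject count is
    conserved; cluster indices are re-packed to 0..K'-1.
    """
    assign = model.assignments.to_numpy().copy()
    centers = model.centroids_std.copy()
    while True:
        sizes = np.bincount(assign, minlength=len(centers))
        small = np.where(sizes < min_size)[0]
        if len(small) == 0 or len(centers) == 1:
            break
        victim = small[np.argsort(sizes[small])][0]
        keep = np.array([k for k in range(len(centers)) if k != victim])
        moved = assign == victim
        d2 = ((X[moved][:, None, :] - centers[keep][None, :, :]) ** 2).sum(axis=2)
        assign[moved] = keep[d2.argmin(axis=1)]
        # re-pack indices and recompute centroids from members
        remap = {old: new for new, old in enumerate(keep)}
        assign = np.array([remap[a] for a in assign])
        centers = np.vstack(
            [X[assign == k].mean(axis=0) for k in range(len(keep))]
        )
    wss = float(((X - centers[assign]) ** 2).sum())
    return ClusterModel(
        K=len(centers),
        centroids_std=centers,
        feature_mean=model.feature_mean,
        feature_sd=model.feature_sd,
        assignments=pd.Series(assign, index=model.assignments.index, name="cluster"),
        wss=wss,
        n=model.n,
        d=model.d,
    )


def select_K(
    features: pd.DataFrame,
    k_range: Sequence[int] = tuple(range(1, 9)),
    min_size: int = 20,
    n_init: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    family: str = "classification",
) -> tuple[ClusterModel, pd.DataFrame, dict[int, ClusterModel]]:
    """Fit k-means over a K range and choose K by minimum BIC.

    Features (columns ``intercept``, ``slope``) are z-score standardized per
    dimension first.  For each K the partition is fitted, undersized
    clusters are merged, and metrics are computed on the post-merge model;
    the chosen model minimizes BIC (ties to the smaller K).  The full
    metrics table is returned so a human can override the automatic choice.

    Returns ``(best_model, metrics_table, models_by_requested_K)``.
    """
    X = features[["intercept", "slope"]].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xstd = (X - mean) / sd

    rows, models = [], {}
    for K in k_range:
        model = _fit_model(
            Xstd, features.index, mean, sd, K, n_init, max_iter, tol,
            None if seed is None else seed + K,
        )
        model = merge_small_clusters(model, Xstd, min_size=min_size)
        model.ll, model.aic, model.bic = model_metrics(model, Xstd, family=family)
        models[K] = model
        rows.append(
            {
                "K_requested": K,
                "K_effective": model.K,
                "WSS": model.wss,
                "LL": model.ll,
                "AIC": model.aic,
                "BIC": model.bic,
            }
        )
    table = pd.DataFrame(rows).set_index("K_requested")
    best_K = int(table["BIC"].idxmin())
    best = models[best_K]
    canonical_labels(best)
    return best, table, models


def canonical_labels(
    model: ClusterModel, flat_slope_threshold: float = 2.0
) -> dict[int, str]:
    """Assign canonical letters by de-standardized centroid shape.

    Flat clusters (|slope| < ``flat_slope_threshold`` breaths/min/L/week)
    take A (higher intercept) then B (lower); clusters with positive slope
    take C, negative slope D; any leftover clusters continue E, F, ... in
    descending-intercept order.  Ties break by intercept descending.
    The map is stored on ``model.labels`` and returned.
    """
    raw = model.centroids_raw
    flats = [k for k in range(model.K) if abs(raw[k, 1]) < flat_slope_threshold]
    ups = [k for k in range(model.K) if raw[k, 1] >= flat_slope_threshold]
    downs = [k for k in range(model.K) if raw[k, 1] <= -flat_slope_threshold]
    by_int = lambda ks: sorted(ks, key=lambda k: (-raw[k, 0], k))

    labels: dict[int, str] = {}
    for slot, k in zip(("A", "B"), by_int(flats)):
        labels[k] = slot
    for slot, k in zip(("C",), by_int(ups)):
        labels[k] = slot
    for slot, k in zip(("D",), by_int(downs)):
        labels[k] = slot
    leftovers = by_int([k for k in range(model.K) if k not in labels])
    extra = [c for c in "EFGHIJKLMNOP"]
    for k, slot in zip(leftovers, extra):
        labels[k] = slot
    model.labels = labels
    return labels


def two_step_cluster(
    series: Iterable[TrajectorySeries],
    k_range: Sequence[int] = tuple(range(1, 9)),
    min_size: int = 20,
    n_init: int = 50,
    seed: int | None = None,
    family: str = "classification",
) -> tuple[ClusterModel, pd.DataFrame, pd.DataFrame]:
    """Featurize a cohort and select the clustering in one call.

    Returns ``(best_model, metrics_table, unclusterable_report)``.
    """
    feats, bad = featurize(series)
    best, table, _ = select_K(
        feats, k_range=k_range, min_size=min_size, n_init=n_init, seed=seed,
        family=family,
    )
    return best, table, bad
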