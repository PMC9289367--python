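"""Per-cluster trajectory summaries and outcome tabulation.

For each cluster and ventilator parameter (RSBI, RR, MV, TV, Pimax) the
profile is the cross-sectional mean over subjects observed at each week with
a 90% t-distribution confidence band; categorical outcomes are tabulated as
per-cluster counts with half-up integer percentages, the familiar
"n (%)" table-one style.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .weaning_indices import TrajectorySeries, trajectories_to_frame

__all__ = [
    "PARAMETERS",
    "round_half_up",
    "trajectory_band",
    "outcome_rates",
    "plot_cluster_trajectories",
]

PARAMETERS = ("rsbi", "rr", "mv", "tv", "pimax")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def trajectory_band(
    series: Iterable[TrajectorySeries],
    assignments: Mapping[str, str] | pd.Series,
    parameter: str = "rsbi",
    week_range: tuple[int, int] | None = None,
    level: float = 0.90,
) -> pd.DataFrame:
    """Cross-sectional mean and t-distribution CI band per (cluster, week).

    Parameters
    ----------
    series
        Subject trajectories.
    assignments
        subject_id -> cluster label; subjects without an assignment are
        ignored.
    parameter
        One of ``rsbi``, ``rr``, ``mv``, ``tv``, ``pimax``.
    week_range
        Optional (lo, hi) inclusive filter on weeks.
    level
        Band coverage (default 0.90).

    Returns
    -------
    DataFrame with columns cluster, week, n, mean, lower, upper; the band is
    NaN (flagged, not fabricated) wherever fewer than 2 subjects contribute.
    """
    if parameter not in PARAMETERS:
        raise KeyError(
            f"unknown parameter {parameter!r}; available: {', '.join(PARAMETERS)}"
        )
    frame = trajectories_to_frame(series)
    if not isinstance(assignments, pd.Series):
        assignments = pd.Series(dict(assignments))
    frame = frame[frame["subject_id"].isin(assignments.index)]
    frame = frame.assign(cluster=frame["subject_id"].map(assignments))
    if week_range is not None:
        lo, hi = week_range
        frame = frame[(frame["week"] >= lo) & (frame["week"] <= hi)]

    rows = []
    for (cluster, week), grp in frame.groupby(["cluster", "week"], sort=True):
        vals = grp[parameter].dropna().to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            continue
        mean = float(vals.mean())
        if n >= 2:
            se = vals.std(ddof=1) / np.sqrt(n)
            half = float(stats.t.ppf(0.5 + level / 2.0, n - 1) * se)
            lo_, hi_ = mean - half, mean + half
        else:
            lo_ = hi_ = float("nan")
        rows.append(
            {"cluster": cluster, "week": int(week), "n": n,
             "mean": mean, "lower": lo_, "upper": hi_}
        )
    return pd.DataFrame(rows, columns=["cluster", "week", "n", "mean", "lower", "upper"])


def outcome_rates(
    outcomes: pd.DataFrame,
    assignments: Mapping[str, str] | pd.Series,
    outcome: str,
    clusters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster counts/denominators/percentages for one categorical outcome.

    Returns a table with one row per outcome category (plus a ``missing``
    row when values are absent — never silently excluded) and one column
    triple (count, denominator, pct) per cluster plus an ``overall`` group.
    Percentages are half-up integers of 100*count/denominator; an empty
    cluster (possible when ``clusters`` lists labels explicitly) reports
    denominator 0 and an undefined (NaN) percentage.
    """
    if outcome not in outcomes.columns:
        raise KeyError(f"outcome {outcome!r} not in table; have {list(outcomes.columns)}")
    if not isinstance(assignments, pd.Series):
        assignments = pd.Series(dict(assignments))
    vals = outcomes[outcome].reindex(assignments.index)
    clusters = sorted(assignments.unique()) if clusters is None else list(clusters)
    cats = sorted(vals.dropna().unique())
    has_missing = vals.isna().any()

    rows = []
    for cat in list(cats) + (["missing"] if has_missing else []):
        row: dict[str, object] = {"category": cat}
        total_cnt = 0
        for cl in clusters:
            mask = assignments == cl
            denom = int(mask.sum())
            if cat == "missing":
                cnt = int(vals[mask].isna().sum())
            else:
                cnt = int((vals[mask] == cat).sum())
            total_cnt += cnt
            row[f"{cl}_count"] = cnt
            row[f"{cl}_denom"] = denom
            row[f"{cl}_pct"] = (
                float("nan") if denom == 0 else round_half_up(100.0 * cnt / denom)
            )
        denom_all = int(len(assignments))
        row["overall_count"] = total_cnt
        row["overall_denom"] = denom_all
        row["overall_pct"] = (
            float("nan") if denom_all == 0 else round_half_up(100.0 * total_cnt / denom_all)
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def plot_cluster_trajectories(
    series: Sequence[TrajectorySeries],
    assignments: Mapping[str, str] | pd.Series,
    parameter: str = "rsbi",
    path: str | None = None,
    max_spaghetti: int = 60,
    seed: int = 0,
):
    """Spaghetti + mean/90%-band panel per cluster (one figure).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(assignments, pd.Series):
        assignments = pd.Series(dict(assignments))
    band = trajectory_band(series, assignments, parameter)
    clusters = sorted(assignments.unique())
    by_id = {s.subject_id: s for s in series}
    rng = np.random.default_rng(seed)

    fig, axes = plt.subplots(1, len(clusters), figsize=(4 * len(clusters), 3.2),
                             sharey=True, squeeze=False)
    for ax, cl in zip(axes[0], clusters):
        ids = assignments.index[assignments == cl]
        pick = rng.permutation(ids)[:max_spaghetti]
        for sid in pick:
            s = by_id.get(sid)
            if s is not None:
                ax.plot(s.weeks, s.values(parameter), color="0.6", lw=0.4, alpha=0.5)
        b = band[band["cluster"] == cl]
        ax.plot(b["week"], b["mean"], color="C3", lw=2)
        ax.fill_between(b["week"], b["lower"], b["upper"], color="C3", alpha=0.25)
        frac = 100.0 * len(ids) / len(assignments)
        ax.set_title(f"{cl} ({frac:.0f}%)")
        ax.set_xlabel("week")
    axes[0][0].set_ylabel(parameter)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
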