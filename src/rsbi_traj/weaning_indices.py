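"""Derivation and I/O of bedside weaning indices.

Weaning indices are measured with the patient briefly disconnected from the
ventilator: a handheld respirometer yields minute ventilation (MV, L/min)
and respiratory rate (RR, breaths/min).  Average tidal volume and the rapid
shallow breathing index follow arithmetically:

    TV   = MV / RR            (liters)
    RSBI = RR / TV = RR**2/MV (breaths/min/L)

High RSBI indicates rapid shallow breathing and predicts weaning failure.
Measurements are taken on arrival at the respiratory care center (week 0)
and then weekly, so a subject's record is a short irregular weekly series.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryValidationError",
    "VentilatorMeasurement",
    "TrajectorySeries",
    "derive_indices",
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "TRAJECTORY_COLUMNS",
]

#: Required columns of a long-format trajectory table.
TRAJECTORY_COLUMNS = ("subject_id", "week", "rr", "mv", "pimax")


class TrajectoryValidationError(ValueError):
    """Raised for malformed trajectory tables (missing columns, duplicates)."""


def derive_indices(rr, mv):
    """Derive tidal volume (L) and RSBI (breaths/min/L) from RR and MV.

    Parameters
    ----------
    rr : float or array-like
        Respiratory rate in breaths/min; must be strictly positive.
    mv : float or array-like
        Minute ventilation in L/min; must be strictly positive.

    Returns
    -------
    (tv, rsbi)
        Tidal volume ``mv / rr`` in liters and RSBI ``rr / tv`` in
        breaths/min/L (equivalently ``rr**2 / mv``).
    """
    rr = np.asarray(rr, dtype=float)
    mv = np.asarray(mv, dtype=float)
    if np.any(rr <= 0) or not np.all(np.isfinite(rr)):
        raise ValueError("respiratory rate (rr) must be finite and > 0")
    if np.any(mv <= 0) or not np.all(np.isfinite(mv)):
        raise ValueError("minute ventilation (mv) must be finite and > 0")
    tv = mv / rr
    rsbi = rr / tv
    if tv.ndim == 0:
        return float(tv), float(rsbi)
    return tv, rsbi


@dataclasses.dataclass(frozen=True)
class VentilatorMeasurement:
    """One weekly set of ventilator parameters for one subject."""

    week: int
    rr: float
    mv: float
    pimax: float = float("nan")  # cmH2O, negative = inspiratory effort

    @property
    def tv(self) -> float:
        return self.mv / self.rr

    @property
    def rsbi(self) -> float:
        return self.rr * self.rr / self.mv


@dataclasses.dataclass
class TrajectorySeries:
    """One subject's weekly ventilator measurements with derived indices.

    Weeks must be strictly increasing; week 0 is RCC arrival.
    """

    subject_id: str
    measurements: list[VentilatorMeasurement]

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise TrajectoryValidationError(
                f"subject {self.subject_id}: trajectory must have >=1 observation"
            )
        weeks = [m.week for m in self.measurements]
        if any(w < 0 for w in weeks):
            raise TrajectoryValidationError(
                f"subject {self.subject_id}: negative week index"
            )
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise TrajectoryValidationError(
                f"subject {self.subject_id}: weeks must be strictly increasing, got {weeks}"
            )

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def weeks(self) -> np.ndarray:
        return np.array([m.week for m in self.measurements], dtype=int)

    @property
    def rsbi(self) -> np.ndarray:
        return np.array([m.rsbi for m in self.measurements], dtype=float)

    def values(self, parameter: str) -> np.ndarray:
        """Values of one parameter ('rsbi', 'rr', 'mv', 'tv', 'pimax')."""
        try:
            return np.array([getattr(m, parameter) for m in self.measurements], float)
        except AttributeError:
            raise KeyError(
                f"unknown parameter {parameter!r}; available: rsbi, rr, mv, tv, pimax"
            ) from None


def trajectories_to_frame(series: Iterable[TrajectorySeries]) -> pd.DataFrame:
    """Long-format table (subject_id, week, rr, mv, pimax, tv, rsbi)."""
    rows = []
    for s in series:
        for m in s.measurements:
            rows.append((s.subject_id, m.week, m.rr, m.mv, m.pimax, m.tv, m.rsbi))
    return pd.DataFrame(
        rows, columns=["subject_id", "week", "rr", "mv", "pimax", "tv", "rsbi"]
    )


def frame_to_trajectories(frame: pd.DataFrame) -> list[TrajectorySeries]:
    """Group a validated long-format table into per-subject series."""
    out = []
    for sid, grp in frame.groupby("subject_id", sort=True):
        grp = grp.sort_values("week")
        ms = [
            VentilatorMeasurement(
                week=int(r.week),
                rr=float(r.rr),
                mv=float(r.mv),
                pimax=float(r.pimax) if pd.notna(r.pimax) else float("nan"),
            )
            for r in grp.itertuples()
        ]
        out.append(TrajectorySeries(subject_id=str(sid), measurements=ms))
    return out


def read_trajectories(
    path: str | os.PathLike | io.TextIOBase,
    mv_units: str = "L",
) -> tuple[list[TrajectorySeries], pd.DataFrame]:
    """Read a trajectory CSV, validate rows, and derive TV/RSBI.

    Parameters
    ----------
    path
        CSV with header ``subject_id,week,rr,mv,pimax`` (pimax may be empty).
    mv_units
        ``"L"`` (default) if minute ventilation is recorded in L/min, or
        ``"ml"`` if in ml/min (converted on read; the RSBI ratio always uses
        tidal volume in liters).

    Returns
    -------
    (series, rejects)
        Validated per-subject series and a DataFrame of rejected rows with a
        ``reason`` column.  Rows are rejected, never silently dropped, for
        non-positive or missing rr/mv or negative week.

    Raises
    ------
    TrajectoryValidationError
        If a required column is missing or a (subject, week) pair occurs
        more than once.
    """
    if mv_units not in ("L", "ml"):
        raise ValueError(f"mv_units must be 'L' or 'ml', got {mv_units!r}")
    raw = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in raw.columns]
    if missing:
        raise TrajectoryValidationError(f"missing required column(s): {missing}")
    raw = raw.copy()
    for col in ("week", "rr", "mv", "pimax"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    if mv_units == "ml":
        raw["mv"] = raw["mv"] / 1000.0

    dup = raw.duplicated(subset=["subject_id", "week"], keep=False)
    if dup.any():
        offenders = (
            raw.loc[dup, ["subject_id", "week"]].drop_duplicates().to_records(index=False)
        )
        raise TrajectoryValidationError(
            f"duplicate (subject, week) rows: {list(offenders)}"
        )

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[raw["rr"].isna()] = "missing rr"
    reasons[raw["mv"].isna() & (reasons == "")] = "missing mv"
    reasons[(raw["rr"] <= 0) & (reasons == "")] = "non-positive rr"
    reasons[(raw["mv"] <= 0) & (reasons == "")] = "non-positive mv"
    reasons[(raw["week"].isna() | (raw["week"] < 0)) & (reasons == "")] = "invalid week"
    bad = reasons != ""
    rejects = raw.loc[bad].copy()
    rejects["reason"] = reasons[bad]
    good = raw.loc[~bad]
    return frame_to_trajectories(good), rejects.reset_index(drop=True)


def write_trajectories(
    series: Sequence[TrajectorySeries], path: str | os.PathLike
) -> None:
    """Write series as a long CSV with the canonical column set.

    Missing pimax is written as an empty field; numeric round-trip through
    :func:`read_trajectories` is lossless to float repr precision.
    """
    frame = trajectories_to_frame(series)[list(TRAJECTORY_COLUMNS)]
    frame.to_csv(path, index=False)
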