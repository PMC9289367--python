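"""Synthetic cohorts of prolonged-mechanical-ventilation patients.

The generator emulates the statistical structure the downstream analysis
assumes, standing in for restricted clinical data:

* four RSBI-trajectory archetypes — A persistently high, B constantly low,
  C increasing, D declining — realised as per-subject random lines
  (intercept + slope * week) plus within-subject noise, observed on a
  weekly schedule with variable follow-up length and missed visits;
* baseline covariates drawn conditionally on the (latent) archetype, with
  cluster-conditional medians matching the published per-cluster medians of
  the real cohort (e.g. lower serum magnesium in the increasing-RSBI
  cluster);
* categorical outcomes (last-follow-up status, weaning, in-hospital death,
  tracheostomy, sex) drawn from per-cluster rates matching the published
  cohort table;
* a screening log reproducing the enrollment flow (1,720 admissions
  screened, 349 excluded, 1,371 included).

Covariate *location* parameters are the published medians; the default
within-cluster *scales* are shrunk by ``covariate_signal`` (see
``SimulationConfig``) so that cluster membership is recoverable from
baselines by construction.  ``covariate_signal=1`` restores the published
interquartile-range spreads (realistic weak-signal world).
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weaning_indices import (
    TrajectorySeries,
    VentilatorMeasurement,
    write_trajectories,
)

__all__ = [
    "ArchetypeParams",
    "Schedule",
    "CovariateSpec",
    "OutcomeSpec",
    "ScreeningSpec",
    "SimulationConfig",
    "SubjectRecord",
    "ScreeningLog",
    "generate_trajectory",
    "generate_cohort",
    "covariates_frame",
    "outcomes_frame",
    "write_cohort",
    "default_config",
    "CLUSTER_LABELS",
]

CLUSTER_LABELS = ("A", "B", "C", "D")

# q3 - q1 of a standard normal; converts an IQR to an SD for normal draws
_IQR_TO_SD = 1.3489795003921634


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclasses.dataclass(frozen=True)
class ArchetypeParams:
    """Per-cluster trajectory law: RSBI_i(w) = b0_i + b1_i * w + noise.

    Units: intercepts in breaths/min/L, slopes in breaths/min/L per week.
    """

    intercept_mean: float
    slope_mean: float
    intercept_sd: float = 15.0
    slope_sd: float = 2.0
    noise_sd: float = 10.0

    def validate(self, name: str) -> None:
        for f in ("intercept_sd", "slope_sd", "noise_sd"):
            if getattr(self, f) < 0:
                raise ConfigError(f"archetype_params[{name}].{f} must be >= 0")


@dataclasses.dataclass(frozen=True)
class Schedule:
    """Weekly measurement schedule starting at RCC arrival (week 0).

    The last scheduled week is ``min(max_weeks - 1, visit_floor + G)`` with
    ``G ~ Geometric(visit_tail_p)``, giving a geometric-tailed follow-up
    length whose median visit count is ~9 (a ~65-day median hospital stay
    implies roughly nine weekly measurements).  Scheduled weeks after week 0
    are then missed independently with ``miss_prob``; week 0 is never missed.
    """

    max_weeks: int = 10
    miss_prob: float = 0.10
    visit_floor: int = 7
    visit_tail_p: float = 0.35

    def validate(self) -> None:
        if self.max_weeks < 1:
            raise ConfigError("schedule.max_weeks must be >= 1")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ConfigError("schedule.miss_prob must be in [0, 1)")
        if not 0.0 < self.visit_tail_p <= 1.0:
            raise ConfigError("schedule.visit_tail_p must be in (0, 1]")
        if self.visit_floor < 0:
            raise ConfigError("schedule.visit_floor must be >= 0")


@dataclasses.dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate with cluster-conditional location/scale.

    family 'normal': value ~ N(location_c, scale); 'lognormal':
    value ~ exp(N(ln location_c, scale)) so location_c is the median either
    way.  ``scale`` is the weak-signal (published-IQR) scale; the effective
    scale is ``scale / covariate_signal``.
    """

    name: str
    family: str  # "normal" | "lognormal"
    locations: tuple[float, float, float, float]  # per cluster A..D
    scale: float

    def validate(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ConfigError(
                f"covariate_specs[{self.name}].family must be 'normal' or 'lognormal'"
            )
        if self.scale < 0:
            raise ConfigError(f"covariate_specs[{self.name}].scale must be >= 0")
        if self.family == "lognormal" and any(l <= 0 for l in self.locations):
            raise ConfigError(
                f"covariate_specs[{self.name}]: lognormal locations must be > 0"
            )


@dataclasses.dataclass(frozen=True)
class OutcomeSpec:
    """One categorical outcome with per-cluster category probabilities."""

    name: str
    categories: tuple[str, ...]
    probs: tuple[tuple[float, ...], ...]  # [cluster][category]

    def validate(self) -> None:
        if len(self.probs) != len(CLUSTER_LABELS):
            raise ConfigError(
                f"outcome_probs[{self.name}] must give one probability vector per cluster"
            )
        for lab, p in zip(CLUSTER_LABELS, self.probs):
            if len(p) != len(self.categories):
                raise ConfigError(
                    f"outcome_probs[{self.name}][{lab}] length != number of categories"
                )
            if any(x < 0 for x in p):
                raise ConfigError(f"outcome_probs[{self.name}][{lab}] has negative entries")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ConfigError(
                    f"outcome_probs[{self.name}][{lab}] must sum to 1 (got {sum(p)!r})"
                )


#: Exclusion reasons mirroring the enrollment flow.
EXCLUSION_REASONS = (
    "duplicate_admission",
    "declined_weaning",
    "withdrawal_of_life_support",
    "transfer_before_weaning",
    "no_spontaneous_breathing",
    "missing_ventilator_data",
)


@dataclasses.dataclass(frozen=True)
class ScreeningSpec:
    """Admission screening flow: screened, excluded (with reasons), included.

    The published flow reports 1,720 screened and 349 excluded admissions;
    the per-reason breakdown is not published and the default split is an
    invented one summing to 349.
    """

    n_screened: int = 1720
    reason_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {
            "duplicate_admission": 120,
            "declined_weaning": 60,
            "withdrawal_of_life_support": 45,
            "transfer_before_weaning": 40,
            "no_spontaneous_breathing": 34,
            "missing_ventilator_data": 50,
        }
    )

    @property
    def n_excluded(self) -> int:
        return int(sum(self.reason_counts.values()))

    def validate(self) -> None:
        if self.n_screened < 0:
            raise ConfigError("screening.n_screened must be >= 0")
        for k, v in self.reason_counts.items():
            if k not in EXCLUSION_REASONS:
                raise ConfigError(f"screening.reason_counts: unknown reason {k!r}")
            if v < 0:
                raise ConfigError(f"screening.reason_counts[{k}] must be >= 0")
        if self.n_excluded > self.n_screened:
            raise ConfigError("screening: n_excluded must be <= n_screened")


def _default_archetypes() -> dict[str, ArchetypeParams]:
    # Shapes: A persistently high, B constantly low, C increasing, D declining.
    # Values are invented so that the archetypes are well separated and the
    # clinical RSBI ~ 105 weaning threshold splits "high" from "low".
    return {
        "A": ArchetypeParams(115.0, 0.0),
        "B": ArchetypeParams(55.0, 0.0),
        "C": ArchetypeParams(70.0, 8.0),
        "D": ArchetypeParams(110.0, -8.0),
    }


def _default_covariates() -> list[CovariateSpec]:
    # Locations are the published per-cluster medians (clusters A,B,C,D);
    # scales back-solved from published total-cohort IQRs (normal: IQR/1.349;
    # lognormal: log-scale IQR ratio).  Right-skewed labs are lognormal.
    return [
        CovariateSpec("age", "normal", (76.84, 75.10, 75.71, 76.36), 13.09),
        CovariateSpec("apache2", "normal", (24.0, 23.0, 23.0, 23.0), 5.19),
        CovariateSpec("magnesium", "normal", (1.99, 1.88, 1.87, 1.92), 0.386),
        CovariateSpec("ph", "normal", (7.49, 7.49, 7.49, 7.49), 0.0445),
        CovariateSpec("tsh", "lognormal", (2.51, 2.05, 2.11, 2.13), 0.948),
        CovariateSpec("cortisol_am", "lognormal", (14.51, 14.97, 13.91, 13.04), 0.414),
        CovariateSpec("bun", "lognormal", (32.1, 27.7, 26.2, 25.3), 0.888),
        CovariateSpec("platelet", "normal", (210.0, 224.0, 213.0, 223.5), 119.0),
        CovariateSpec("free_t4", "normal", (0.95, 0.98, 0.98, 0.99), 0.267),
        CovariateSpec("prealbumin_day14", "normal", (17.9, 17.75, 16.65, 20.0), 7.86),
    ]


def _default_outcomes() -> list[OutcomeSpec]:
    # Per-cluster probabilities are the published per-cluster counts over the
    # cluster sizes (A 349, B 461, C 323, D 238).
    n = np.array([349.0, 461.0, 323.0, 238.0])

    def binary(cnt, cats=("yes", "no")):
        p = np.array(cnt, float) / n
        return tuple((float(pi), float(1 - pi)) for pi in p)

    dead = np.array([250.0, 283.0, 201.0, 151.0])
    novent = np.array([90.0, 168.0, 108.0, 85.0])
    onvent = n - dead - novent  # (9, 10, 14, 2)
    lf = tuple(
        (float(d / t), float(v / t), float(o / t))
        for d, v, o, t in zip(dead, novent, onvent, n)
    )
    return [
        OutcomeSpec(
            "last_follow_up", ("dead", "no_ventilator", "on_ventilator"), lf
        ),
        OutcomeSpec("weaning", ("yes", "no"), binary([141, 239, 151, 123])),
        OutcomeSpec("in_hospital_death", ("yes", "no"), binary([86, 125, 84, 68])),
        OutcomeSpec("tracheostomy", ("yes", "no"), binary([94, 127, 92, 58])),
        OutcomeSpec("sex", ("male", "female"), binary([178, 289, 194, 138])),
    ]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full stated world of the synthetic cohort.

    ``cluster_probs`` defaults to the published cluster sizes 349/461/323/238
    out of 1,371.  ``covariate_signal`` divides all covariate scales; the
    default (20) makes clusters recoverable from baselines by construction
    (strong-signal world) while preserving every cluster-conditional median;
    set it to 1 for published-IQR realism.
    """

    n_subjects: int = 1371
    cluster_probs: tuple[float, float, float, float] = (
        349 / 1371,
        461 / 1371,
        323 / 1371,
        238 / 1371,
    )
    archetype_params: Mapping[str, ArchetypeParams] = dataclasses.field(
        default_factory=_default_archetypes
    )
    schedule: Schedule = dataclasses.field(default_factory=Schedule)
    covariate_specs: Sequence[CovariateSpec] = dataclasses.field(
        default_factory=_default_covariates
    )
    outcome_specs: Sequence[OutcomeSpec] = dataclasses.field(
        default_factory=_default_outcomes
    )
    screening: ScreeningSpec = dataclasses.field(default_factory=ScreeningSpec)
    covariate_signal: float = 20.0
    rsbi_floor: float = 5.0  # breaths/min/L, positivity floor
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if len(self.cluster_probs) != 4:
            raise ConfigError("cluster_probs must have 4 entries")
        if any(p < 0 for p in self.cluster_probs):
            raise ConfigError("cluster_probs entries must be >= 0")
        if abs(sum(self.cluster_probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"cluster_probs must sum to 1 (got {sum(self.cluster_probs)!r})"
            )
        for lab in CLUSTER_LABELS:
            if lab not in self.archetype_params:
                raise ConfigError(f"archetype_params missing cluster {lab!r}")
            self.archetype_params[lab].validate(lab)
        self.schedule.validate()
        for spec in self.covariate_specs:
            spec.validate()
        for spec in self.outcome_specs:
            spec.validate()
        self.screening.validate()
        if self.covariate_signal <= 0:
            raise ConfigError("covariate_signal must be > 0")
        if self.rsbi_floor <= 0:
            raise ConfigError("rsbi_floor must be > 0")


def default_config(**overrides) -> SimulationConfig:
    """The default stated world, with keyword overrides."""
    return dataclasses.replace(SimulationConfig(), **overrides)


@dataclasses.dataclass
class SubjectRecord:
    """One included subject: latent cluster, trajectory, baselines, outcomes."""

    subject_id: str
    true_cluster: str
    trajectory: TrajectorySeries
    covariates: dict[str, float | str]
    outcomes: dict[str, str]


@dataclasses.dataclass
class ScreeningLog:
    """Admission-level screening log; ``included + excluded == screened``."""

    records: pd.DataFrame  # columns: admission_id, included, exclusion_reason

    @property
    def n_screened(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return int((~self.records["included"]).sum())

    @property
    def n_included(self) -> int:
        return int(self.records["included"].sum())


def generate_trajectory(
    cluster_label: str,
    params: ArchetypeParams,
    schedule: Schedule,
    rng: np.random.Generator,
    subject_id: str = "s0",
    rsbi_floor: float = 5.0,
) -> TrajectorySeries:
    """Draw one subject's weekly ventilator series under an archetype.

    The latent RSBI line is ``b0 + b1*week`` with subject-level coefficients
    drawn around the archetype means; observed RSBI adds within-subject noise
    and is floored at ``rsbi_floor``.  Observed RR/MV are back-solved from
    RSBI through a lognormal tidal volume around 0.3 L, so that
    ``rr**2 / mv`` reproduces the simulated RSBI exactly.
    """
    b0 = params.intercept_mean + params.intercept_sd * rng.standard_normal()
    b1 = params.slope_mean + params.slope_sd * rng.standard_normal()

    last_week = min(
        schedule.max_weeks - 1,
        schedule.visit_floor + int(rng.geometric(schedule.visit_tail_p)),
    )
    weeks = [0] + [
        w
        for w in range(1, last_week + 1)
        if rng.random() >= schedule.miss_prob  # week 0 never dropped
    ]

    ms = []
    for w in weeks:
        rsbi = b0 + b1 * w + params.noise_sd * rng.standard_normal()
        rsbi = max(rsbi, rsbi_floor)
        tv = float(np.exp(np.log(0.3) + 0.15 * rng.standard_normal()))
        rr = rsbi * tv
        mv = rr * tv
        # pimax: effort strengthens (more negative) for recovering shapes
        pimax = -25.0 - 0.5 * w + 5.0 * rng.standard_normal()
        ms.append(VentilatorMeasurement(week=w, rr=rr, mv=mv, pimax=pimax))
    return TrajectorySeries(subject_id=subject_id, measurements=ms)


def _draw_covariate(
    spec: CovariateSpec, cluster_idx: np.ndarray, signal: float, rng: np.random.Generator
) -> np.ndarray:
    loc = np.asarray(spec.locations, dtype=float)[cluster_idx]
    sd = spec.scale / signal
    z = rng.standard_normal(len(cluster_idx))
    if spec.family == "normal":
        return loc + sd * z
    return np.exp(np.log(loc) + sd * z)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], ScreeningLog]:
    """Generate an included cohort and its screening log.

    Deterministic given ``config.seed``: the same config yields bit-identical
    cohorts.  Cluster labels are multinomial draws from ``cluster_probs``;
    trajectories, covariates and outcomes are drawn conditionally on the
    subject's true cluster (outcomes independently of one another given the
    cluster, as only marginal per-cluster rates are targeted).
    """
    config.validate()
    if config.screening.n_screened - config.screening.n_excluded != config.n_subjects:
        raise ConfigError(
            "screening: n_screened - n_excluded must equal n_subjects "
            f"({config.screening.n_screened} - {config.screening.n_excluded} "
            f"!= {config.n_subjects})"
        )
    rng = np.random.default_rng(config.seed)

    # --- screening log -------------------------------------------------
    n_scr = config.screening.n_screened
    reasons = []
    for r, cnt in config.screening.reason_counts.items():
        reasons += [r] * cnt
    flags = np.array(reasons + [""] * (n_scr - len(reasons)), dtype=object)
    rng.shuffle(flags)
    log = ScreeningLog(
        pd.DataFrame(
            {
                "admission_id": [f"adm{i:05d}" for i in range(n_scr)],
                "included": flags == "",
                "exclusion_reason": flags,
            }
        )
    )

    # --- included subjects ---------------------------------------------
    n = config.n_subjects
    cluster_idx = rng.choice(4, size=n, p=np.asarray(config.cluster_probs))
    subject_ids = [f"subj{i:05d}" for i in range(n)]

    cov_values = {
        spec.name: _draw_covariate(spec, cluster_idx, config.covariate_signal, rng)
        for spec in config.covariate_specs
    }
    out_values: dict[str, np.ndarray] = {}
    for spec in config.outcome_specs:
        vals = np.empty(n, dtype=object)
        for c in range(4):
            mask = cluster_idx == c
            vals[mask] = rng.choice(
                spec.categories, size=int(mask.sum()), p=np.asarray(spec.probs[c])
            )
        out_values[spec.name] = vals

    records = []
    for i, sid in enumerate(subject_ids):
        lab = CLUSTER_LABELS[cluster_idx[i]]
        traj = generate_trajectory(
            lab,
            config.archetype_params[lab],
            config.schedule,
            rng,
            subject_id=sid,
            rsbi_floor=config.rsbi_floor,
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                true_cluster=lab,
                trajectory=traj,
                covariates={k: float(v[i]) for k, v in cov_values.items()},
                outcomes={k: str(v[i]) for k, v in out_values.items()},
            )
        )
    return records, log


def covariates_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Wide baseline table, one row per subject (sex copied in as a baseline)."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, **r.covariates}
        if "sex" in r.outcomes:
            row["sex"] = r.outcomes["sex"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def outcomes_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [{"subject_id": r.subject_id, **r.outcomes} for r in records]
    return pd.DataFrame(rows).set_index("subject_id")


def true_clusters(records: Sequence[SubjectRecord]) -> pd.Series:
    return pd.Series(
        {r.subject_id: r.true_cluster for r in records}, name="true_cluster"
    )


_DATA_DICTIONARY = """\
# Synthetic cohort data dictionary

trajectories.csv (long format, one row per subject-week)
  subject_id : opaque subject identifier
  week       : weeks since RCC arrival (0 = arrival), integer
  rr         : respiratory rate, breaths/min
  mv         : minute ventilation, L/min
  pimax      : maximal inspiratory pressure, cmH2O (negative = effort; may be empty)

covariates.csv (one row per subject; baselines on RCC arrival)
  age, apache2, magnesium (mg/dl), ph, tsh (mIU/L), cortisol_am (mcg/dl),
  bun (mg/dl), platelet (1e9/L), free_t4, prealbumin_day14 (mg/dl), sex

outcomes.csv (one row per subject; categorical outcomes)
  last_follow_up    : dead | no_ventilator | on_ventilator
  weaning           : yes | no   (weaned from MV in hospital or RCC)
  in_hospital_death : yes | no
  tracheostomy      : yes | no
  sex               : male | female

truth.csv
  true_cluster : generating archetype (A high, B low, C increasing, D declining)

screening_log.csv (one row per screened admission)
  admission_id, included (bool), exclusion_reason (empty when included)
"""


def write_cohort(
    records: Sequence[SubjectRecord],
    log: ScreeningLog,
    outdir: str | os.PathLike,
    config: SimulationConfig | None = None,
) -> dict[str, str]:
    """Write trajectories/covariates/outcomes/truth/screening-log CSVs.

    Returns a name -> path map of everything written.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    paths["trajectories"] = os.path.join(outdir, "trajectories.csv")
    write_trajectories([r.trajectory for r in records], paths["trajectories"])

    paths["covariates"] = os.path.join(outdir, "covariates.csv")
    covariates_frame(records).to_csv(paths["covariates"])
    paths["outcomes"] = os.path.join(outdir, "outcomes.csv")
    outcomes_frame(records).to_csv(paths["outcomes"])
    paths["truth"] = os.path.join(outdir, "truth.csv")
    true_clusters(records).rename_axis("subject_id").to_csv(paths["truth"])
    paths["screening_log"] = os.path.join(outdir, "screening_log.csv")
    log.records.to_csv(paths["screening_log"], index=False)

    paths["data_dictionary"] = os.path.join(outdir, "data_dictionary.md")
    with open(paths["data_dictionary"], "w") as fh:
        fh.write(_DATA_DICTIONARY)

    if config is not None:
        paths["config"] = os.path.join(outdir, "config.json")
        with open(paths["config"], "w") as fh:
            json.dump(_config_to_jsonable(config), fh, indent=2)
    return paths


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["archetype_params"] = {
        k: dataclasses.asdict(v) for k, v in config.archetype_params.items()
    }
    d["screening"]["reason_counts"] = dict(config.screening.reason_counts)
    return d
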