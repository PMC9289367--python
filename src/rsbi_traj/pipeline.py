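"""End-to-end pipeline: simulate -> derive -> cluster -> profile -> compare -> predict.

Each stage reads only files (or in-memory results) produced by earlier
stages, writes its outputs under its own subdirectory, and is recorded in a
run manifest (package version, seeds, parameters, SHA-256 digests and file
lists) so a run can be verified byte-for-byte.  Every stochastic stage has
its own explicit seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any, Mapping

import pandas as pd

from . import __version__
from . import cluster_profiles as cp
from . import group_comparison as gc
from . import membership_prediction as mp
from . import synthetic_cohort as sc
from . import trajectory_clustering as tc
from . import weaning_indices as wi

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("rsbi_traj")

STAGES = ("simulate", "derive", "cluster", "profile", "compare", "predict")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``stages`` toggles each stage; ``seeds`` must name a seed for every
    enabled stochastic stage (simulate, cluster, predict).  ``simulate``,
    ``cluster`` and ``predict`` hold per-stage parameter blocks.
    """

    outdir: str
    overwrite: bool = False
    trajectories: str | None = None  # input CSV when simulate is off
    covariates: str | None = None
    outcomes: str | None = None
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    seeds: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"simulate": 0, "cluster": 1, "predict": 2}
    )
    simulate: dict[str, Any] = dataclasses.field(default_factory=dict)
    cluster: dict[str, Any] = dataclasses.field(default_factory=dict)
    predict: dict[str, Any] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        for stage in ("simulate", "cluster", "predict"):
            if self.stages.get(stage) and stage not in self.seeds:
                raise ValueError(f"stage {stage!r} is enabled but has no seed")


def load_run_config(path: str) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and its log."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    if os.listdir(config.outdir) and not config.overwrite:
        existing = [f for f in os.listdir(config.outdir) if f != "pipeline.log"]
        if existing:
            raise FileExistsError(
                f"output directory {config.outdir!r} is not empty; "
                "pass overwrite=True to reuse it"
            )

    log_path = os.path.join(config.outdir, "pipeline.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seeds": dict(config.seeds),
        "parameters": {
            "simulate": dict(config.simulate),
            "cluster": dict(config.cluster),
            "predict": dict(config.predict),
        },
        "stages": {},
    }

    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            if not config.stages.get(stage, False):
                continue
            log.info("stage %s: start", stage)
            try:
                files = _STAGE_FNS[stage](config, state)
            except Exception as e:
                log.error("stage %s: failed: %s", stage, e)
                raise StageError(
                    f"stage {stage!r} failed ({e}); see log at {log_path}"
                ) from e
            manifest["stages"][stage] = {
                "files": {os.path.relpath(f, config.outdir): _sha256(f) for f in files}
            }
            log.info("stage %s: wrote %d file(s)", stage, len(files))
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict) -> list[str]:
    params = dict(config.simulate)
    params["seed"] = config.seeds["simulate"]
    n = params.get("n_subjects")
    if n is not None and "screening" not in params:
        # keep the screening identity included = screened - excluded exact
        spec = sc.ScreeningSpec()
        params["screening"] = sc.ScreeningSpec(
            n_screened=int(n) + spec.n_excluded, reason_counts=spec.reason_counts
        )
    sim = sc.default_config(**params)
    records, screening = sc.generate_cohort(sim)
    outdir = os.path.join(config.outdir, "data")
    paths = sc.write_cohort(records, screening, outdir, config=sim)
    state["records"] = records
    state["trajectories_path"] = paths["trajectories"]
    state["covariates_path"] = paths["covariates"]
    state["outcomes_path"] = paths["outcomes"]
    return list(paths.values())


def _stage_derive(config: RunConfig, state: dict) -> list[str]:
    traj_path = state.get("trajectories_path") or config.trajectories
    if traj_path is None:
        raise FileNotFoundError(
            "derive needs a trajectories CSV: enable the simulate stage or set "
            "config.trajectories"
        )
    series, rejects = wi.read_trajectories(traj_path)
    outdir = os.path.join(config.outdir, "derived")
    os.makedirs(outdir, exist_ok=True)
    derived = os.path.join(outdir, "trajectories_derived.csv")
    wi.trajectories_to_frame(series).to_csv(derived, index=False)
    rej = os.path.join(outdir, "rejects.csv")
    rejects.to_csv(rej, index=False)
    state["series"] = series
    return [derived, rej]


def _require(state: dict, key: str, needed_by: str, hint: str) -> Any:
    if key not in state:
        raise FileNotFoundError(f"stage {needed_by!r} needs {hint}")
    return state[key]


def _stage_cluster(config: RunConfig, state: dict) -> list[str]:
    series = _require(
        state, "series", "cluster", "derived trajectories (enable the derive stage)"
    )
    params = dict(config.cluster)
    k_range = params.pop("k_range", tuple(range(1, 9)))
    model, table, bad = tc.two_step_cluster(
        series, k_range=k_range, seed=config.seeds["cluster"], **params
    )
    outdir = os.path.join(config.outdir, "clustering")
    os.makedirs(outdir, exist_ok=True)
    files = []

    assignments = model.labelled_assignments()
    p = os.path.join(outdir, "assignments.csv")
    assignments.rename_axis("subject_id").to_csv(p)
    files.append(p)

    p = os.path.join(outdir, "metrics.csv")
    table.to_csv(p)
    files.append(p)

    cent = pd.DataFrame(model.centroids_raw, columns=["intercept", "slope"])
    cent["cluster"] = [model.labels[k] for k in range(model.K)]
    cent[["intercept_std", "slope_std"]] = model.centroids_std
    p = os.path.join(outdir, "centroids.csv")
    cent.to_csv(p, index=False)
    files.append(p)

    p = os.path.join(outdir, "unclusterable.csv")
    bad.to_csv(p, index=False)
    files.append(p)

    state["assignments"] = assignments
    state["cluster_model"] = model
    return files


def _stage_profile(config: RunConfig, state: dict) -> list[str]:
    series = _require(state, "series", "profile", "derived trajectories")
    assignments = _require(
        state, "assignments", "profile",
        "an assignments file (enable the cluster stage)",
    )
    outdir = os.path.join(config.outdir, "profiles")
    os.makedirs(outdir, exist_ok=True)
    files = []
    for param in cp.PARAMETERS:
        band = cp.trajectory_band(series, assignments, param)
        p = os.path.join(outdir, f"band_{param}.csv")
        band.to_csv(p, index=False)
        files.append(p)
    p = os.path.join(outdir, "trajectories_rsbi.png")
    cp.plot_cluster_trajectories(series, assignments, "rsbi", path=p)
    files.append(p)

    outcomes = _load_outcomes(config, state)
    if outcomes is not None:
        for col in outcomes.columns:
            tab = cp.outcome_rates(outcomes, assignments, col)
            p = os.path.join(outdir, f"outcome_{col}.csv")
            tab.to_csv(p)
            files.append(p)
    return files


def _load_outcomes(config: RunConfig, state: dict) -> pd.DataFrame | None:
    if "records" in state:
        return sc.outcomes_frame(state["records"])
    path = state.get("outcomes_path") or config.outcomes
    if path is None:
        return None
    return pd.read_csv(path, index_col="subject_id")


def _load_covariates(config: RunConfig, state: dict) -> pd.DataFrame | None:
    if "records" in state:
        return sc.covariates_frame(state["records"])
    path = state.get("covariates_path") or config.covariates
    if path is None:
        return None
    return pd.read_csv(path, index_col="subject_id")


def _stage_compare(config: RunConfig, state: dict) -> list[str]:
    assignments = _require(
        state, "assignments", "compare", "an assignments file (enable cluster)"
    )
    covariates = _load_covariates(config, state)
    outcomes = _load_outcomes(config, state)
    if covariates is None:
        raise FileNotFoundError("compare needs a covariates CSV")
    manifest: dict[str, str] = {
        c: "categorical" if covariates[c].dtype == object else "numeric"
        for c in covariates.columns
    }
    if outcomes is not None:
        manifest.update({c: "categorical" for c in outcomes.columns})
    rows, skipped = gc.comparison_report(covariates, assignments, manifest, outcomes)
    outdir = os.path.join(config.outdir, "comparison")
    os.makedirs(outdir, exist_ok=True)
    files = []
    p = os.path.join(outdir, "comparison.csv")
    gc.report_frame(rows).to_csv(p, index=False)
    files.append(p)
    p = os.path.join(outdir, "comparison.md")
    with open(p, "w") as fh:
        fh.write(gc.render_markdown(rows))
        if skipped:
            fh.write("\n\nSkipped variables (absent from cohort): " + ", ".join(skipped))
    files.append(p)
    return files


def _stage_predict(config: RunConfig, state: dict) -> list[str]:
    assignments = _require(
        state, "assignments", "predict", "an assignments file (enable cluster)"
    )
    covariates = _load_covariates(config, state)
    if covariates is None:
        raise FileNotFoundError("predict needs a covariates CSV")
    params = dict(config.predict)
    seed = config.seeds["predict"]
    X, imput = mp.encode_features(covariates.loc[assignments.index])
    bundle = mp.tune_and_fit(X, assignments, seed=seed)

    outdir = os.path.join(config.outdir, "prediction")
    os.makedirs(outdir, exist_ok=True)
    files = []
    p = os.path.join(outdir, "cv_table.csv")
    bundle.cv_table.to_csv(p, index=False)
    files.append(p)
    p = os.path.join(outdir, "importance.csv")
    mp.relative_influence(bundle).to_csv(p, index=False)
    files.append(p)
    p = os.path.join(outdir, "imputation_report.csv")
    imput.to_csv(p, index=False)
    files.append(p)

    if params.get("compare_models", False):
        res = mp.compare_models(
            X,
            assignments,
            n_repeats=int(params.get("n_repeats", 5)),
            n_folds=int(params.get("n_folds", 10)),
            seed=seed,
            gbm_params=bundle.best_params,
        )
        p = os.path.join(outdir, "model_comparison.csv")
        res.to_csv(p, index=False)
        files.append(p)
        p = os.path.join(outdir, "model_comparison_summary.csv")
        mp.compare_summary(res).to_csv(p, index=False)
        files.append(p)

    n_expl = int(params.get("n_explanations", 4))
    expl_out = []
    for sid in list(X.index[:n_expl]):
        e = mp.breakdown_explain(bundle, X.loc[sid], seed=seed)
        expl_out.append(
            {
                "subject_id": str(sid),
                "explained_class": e.explained_class,
                "baseline": e.baseline,
                "prediction": e.prediction,
                "contributions": e.contributions.to_dict(orient="records"),
                "interactions": e.interactions.to_dict(orient="records"),
            }
        )
    p = os.path.join(outdir, "explanations.json")
    with open(p, "w") as fh:
        json.dump(expl_out, fh, indent=2)
    files.append(p)

    p = os.path.join(outdir, "model.joblib")
    mp.save_bundle(bundle, p)
    files.extend([p, p + ".json"])
    state["bundle"] = bundle
    return files


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "derive": _stage_derive,
    "cluster": _stage_cluster,
    "profile": _stage_profile,
    "compare": _stage_compare,
    "predict": _stage_predict,
}
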