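"""One-shot orchestration of the full analysis with reproducible configuration.

The run sequence mirrors the study: simulate-or-ingest, response construction,
insecticide-efficacy regression, forward global-model build, all-subsets
enumeration, confidence set and averaging, local/landscape class comparison,
standardized impacts, harvest-adaptation check, and the residual Moran's I
correlogram.  All outputs are delimited text plus a JSON run log; re-running
the same configuration reproduces identical numbers.
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .inference import (
    baseline_profile,
    expected_infestation,
    harvest_adaptation,
    impacts_to_frame,
    insecticide_model,
    standardized_impacts,
)
from .io import (
    attach_response,
    build_design,
    read_table,
    validate_table,
    write_table,
    write_truth,
)
from .multimodel import (
    MAX_ENUM_VARS,
    average_parameters,
    averages_to_frame,
    class_result,
    compare_classes,
    confidence_set,
    enumerate_and_fit,
    refit_subset,
)
from .registry import default_registry, default_truth, landscape_names, local_names
from .synth import generate_dataset
from .spatial import correlogram, correlogram_to_frame
from .stepwise import build_global_model


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (file values < flag overrides)."""

    input: str | None = None
    simulate: dict | None = None          # {n_fields, seed, sigma?, ...}
    tolerance: float = 2.0
    delta_max: float = 2.0
    aic: str = "plain"                    # plain | corrected
    correlogram: dict = field(default_factory=lambda: {
        "max_dist": 3000.0, "interval": 250.0, "n_perm": 1000})
    outdir: str = "weevilinf_out"

    def __post_init__(self):
        if (self.input is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of 'input' and 'simulate' must be given")
        if self.tolerance < 0 or self.delta_max <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.aic not in ("plain", "corrected"):
            raise ConfigurationError("aic must be 'plain' or 'corrected'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a run report (also written to disk)."""
    registry = default_registry()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corrected = config.aic == "corrected"
    report: dict = {"config": {
        "input": config.input, "simulate": config.simulate,
        "tolerance": config.tolerance, "delta_max": config.delta_max,
        "aic": config.aic, "correlogram": config.correlogram,
    }, "version": __version__, "python": platform.python_version(),
        "stages": {}}
    t0 = time.perf_counter()

    def stage(name):
        def wrap(fn):
            start = time.perf_counter()
            try:
                result = fn()
            except Exception as err:  # noqa: BLE001 - stage-named diagnostics
                raise StageError(name, err) from err
            report["stages"][name] = round(time.perf_counter() - start, 3)
            return result
        return wrap

    def _ingest():
        if config.simulate is not None:
            sim = dict(config.simulate)
            truth = default_truth(registry, seed=sim.get("seed"))
            if "sigma" in sim:
                truth = truth.with_(sigma=float(sim["sigma"]))
            table, truth = generate_dataset(
                registry, n_fields=int(sim.get("n_fields", 138)),
                n_observers=int(sim.get("n_observers", 4)), truth=truth)
            write_truth(truth, outdir / "truth.json")
            return table
        return read_table(config.input, registry)

    table = stage("ingest")(_ingest)
    stage("validate")(lambda: validate_table(table, registry))
    table = stage("response")(lambda: attach_response(table))
    write_table(table, outdir / "dataset.csv")

    insect = stage("insecticide")(lambda: insecticide_model(table, registry))
    insect.to_csv(outdir / "insecticide.csv", index=False)

    traj = stage("global_model")(lambda: build_global_model(
        table, tolerance=config.tolerance, registry=registry,
        corrected=corrected))
    traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
    report["global_model"] = {
        "selected": traj.selected,
        "aic_intercept_only": traj.aic_intercept_only,
        "aic_min_reached": traj.aic_min_reached,
        "best_r2": traj.best_r2,
    }

    selected = list(traj.selected)
    if len(selected) > MAX_ENUM_VARS:
        warnings.warn(f"{len(selected)} variables selected; enumerating the "
                      f"first {MAX_ENUM_VARS} in entry order")
        selected = selected[:MAX_ENUM_VARS]

    mset = stage("enumerate")(lambda: enumerate_and_fit(
        table, selected, registry, corrected=corrected))
    report["n_models"] = len(mset)
    cset = stage("confidence_set")(lambda: confidence_set(mset, config.delta_max))
    report["n_confidence_set"] = len(cset)
    best_fit = refit_subset(mset, mset.best_index, table, registry)
    report["best_model"] = {"variables": best_fit.variable_names,
                            "aic": best_fit.aic, "r2": best_fit.r2}

    avg = stage("average")(lambda: average_parameters(cset, table, registry))
    averages_to_frame(avg).to_csv(outdir / "averaged_parameters.csv", index=False)

    combined_result = class_result("combined", selected, mset, table, registry)
    comparison = stage("class_comparison")(lambda: compare_classes(
        table, local_names(registry), landscape_names(registry),
        registry=registry, tolerance=config.tolerance, corrected=corrected,
        combined=combined_result))
    comparison.to_frame().to_csv(outdir / "class_comparison.csv", index=False)
    report["class_weights"] = {
        "combined": comparison.combined.weight,
        "local": comparison.local.weight,
        "landscape": comparison.landscape.weight,
    }

    def _impacts():
        profile = baseline_profile(table, registry)
        return standardized_impacts(avg, profile, table, registry)

    impacts = stage("impacts")(_impacts)
    impacts_to_frame(impacts).to_csv(outdir / "impacts.csv", index=False)

    def _harvest():
        expected = expected_infestation(table, avg, registry)
        fit = harvest_adaptation(table, expected)
        return {"slope": fit.slope, "intercept": fit.intercept,
                "df": fit.df, "p_value": fit.p_value}

    report["harvest_adaptation"] = stage("harvest")(_harvest)

    def _correlogram():
        design = build_design(table, best_fit.variable_names, registry)
        resid = design.y - design.X @ best_fit.coefficients
        cg = config.correlogram
        return correlogram(
            resid, table[["x", "y"]].to_numpy(),
            max_dist=float(cg.get("max_dist", 3000.0)),
            interval=float(cg.get("interval", 250.0)),
            n_perm=int(cg.get("n_perm", 1000)),
            seed=cg.get("seed", (config.simulate or {}).get("seed")))

    bins = stage("correlogram")(_correlogram)
    correlogram_to_frame(bins).to_csv(outdir / "correlogram.csv", index=False)
    report["correlogram_min_p"] = float(np.nanmin(
        [b.p_perm for b in bins])) if bins else None

    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    (outdir / "run_log.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
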