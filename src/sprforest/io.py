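"""File formats, packaged defaults and run manifests.

Tabular data is CSV (comma, UTF-8, header required); configurations are
YAML; single results are JSON.  A dead tree's occasion-2 dbh is written
as an empty field, never 0.  Numeric output keeps 12 significant
digits, so CSV round-trips are lossless well past 10 digits.
"""

from __future__ import annotations

from dataclasses import asdict
from datetime import datetime, timezone
import hashlib
import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError
from .montecarlo import DesignSpec, ExperimentConfig
from .population import (
    PopulationParams,
    TreePopulation,
    params_from_dict,
    params_to_dict,
)
from .scenarios import ScenarioSpec

FLOAT_FMT = "%.12g"
TREE_COLUMNS = ["plot_id", "tree_id", "dbh_t1_cm", "alive_t2", "dbh_t2_cm"]
PANEL_COLUMNS = ["plot_id", "x_t1_tha", "y_t2_undist_tha", "y_t2_dist_tha",
                 "affected", "scenario"]


# ---------------------------------------------------------------------------
# tree tables

def write_tree_table(pop: TreePopulation, path) -> None:
    df = pd.DataFrame(
        {
            "plot_id": pop.trees["plot_id"],
            "tree_id": pop.trees["tree_id"],
            "dbh_t1_cm": pop.trees["dbh_t1"],
            "alive_t2": pop.trees["alive_t2"].astype(int),
            "dbh_t2_cm": pop.trees["dbh_t2"],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tree_table(path, n_plots: int | None = None,
                    plot_area_m2: float = 400.0) -> TreePopulation:
    """Load and validate a tree table CSV.

    Row-level schema errors (negative dbh, a dead tree carrying an
    occasion-2 dbh, shrinkage, duplicate tree keys) name the offending
    row.  ``n_plots`` defaults to the largest plot id present.
    """
    df = pd.read_csv(path)
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["plot_id", "tree_id"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (plot_id, tree_id) at row {int(dup.idxmax())}")
    alive = df["alive_t2"].astype(bool)
    bad = df["dbh_t1_cm"] <= 0
    if bad.any():
        raise SchemaError(f"{path}: non-positive dbh_t1_cm at row {int(bad.idxmax())}")
    dead_with_d2 = (~alive) & df["dbh_t2_cm"].notna()
    if dead_with_d2.any():
        raise SchemaError(
            f"{path}: dead tree with dbh_t2_cm at row {int(dead_with_d2.idxmax())}")
    live_missing = alive & df["dbh_t2_cm"].isna()
    if live_missing.any():
        raise SchemaError(
            f"{path}: living tree without dbh_t2_cm at row {int(live_missing.idxmax())}")
    shrink = alive & (df["dbh_t2_cm"] < df["dbh_t1_cm"])
    if shrink.any():
        raise SchemaError(f"{path}: dbh shrinkage at row {int(shrink.idxmax())}")
    trees = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(int),
            "tree_id": df["tree_id"].astype(int),
            "dbh_t1": df["dbh_t1_cm"].astype(float),
            "alive_t2": alive,
            "dbh_t2": df["dbh_t2_cm"].astype(float),
        }
    )
    if n_plots is None:
        n_plots = int(trees["plot_id"].max()) if len(trees) else 0
    return TreePopulation(trees=trees, n_plots=n_plots, plot_area_m2=plot_area_m2)


# ---------------------------------------------------------------------------
# plot panels

def write_panel(panel: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "plot_id": panel["plot_id"],
            "x_t1_tha": panel["x_t1"],
            "y_t2_undist_tha": panel["y_t2_undisturbed"],
            "y_t2_dist_tha": panel["y_t2_disturbed"],
            "affected": panel["affected"].astype(int),
            "scenario": panel["scenario"],
        }
    )
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(int),
            "x_t1": df["x_t1_tha"].astype(float),
            "y_t2_undisturbed": df["y_t2_undist_tha"].astype(float),
            "y_t2_disturbed": df["y_t2_dist_tha"].astype(float),
            "affected": df["affected"].astype(bool),
            "scenario": df["scenario"],
        }
    )


# ---------------------------------------------------------------------------
# YAML configurations

def write_params(params: PopulationParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def read_params(path) -> PopulationParams:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))


def write_scenarios(scenarios, path) -> None:
    Path(path).write_text(yaml.safe_dump([asdict(s) for s in scenarios], sort_keys=False))


def read_scenarios(path) -> tuple[ScenarioSpec, ...]:
    raw = yaml.safe_load(Path(path).read_text())
    out = tuple(ScenarioSpec(**d) for d in raw)
    for s in out:
        s.validate()
    return out


def write_designs(designs, path) -> None:
    Path(path).write_text(yaml.safe_dump([asdict(d) for d in designs], sort_keys=False))


def read_designs(path) -> tuple[DesignSpec, ...]:
    raw = yaml.safe_load(Path(path).read_text())
    out = tuple(DesignSpec(**d) for d in raw)
    for d in out:
        d.validate()
    return out


def read_experiment_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    if "population" in raw:
        kwargs["population"] = params_from_dict(raw["population"])
    if "scenarios" in raw:
        kwargs["scenarios"] = tuple(ScenarioSpec(**d) for d in raw["scenarios"])
    if "designs" in raw:
        kwargs["designs"] = tuple(DesignSpec(**d) for d in raw["designs"])
    for key in ("bias_variants", "iterations", "master_seed",
                "spr_variance_mode", "redraw_scenarios"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "bias_variants" else raw[key]
    cfg = ExperimentConfig(**kwargs)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# packaged defaults

def _data_text(name: str) -> str:
    return importlib.resources.files("sprforest.data").joinpath(name).read_text()


def default_params() -> PopulationParams:
    """The shipped calibrated population parameters."""
    return params_from_dict(yaml.safe_load(_data_text("default_params.yaml")))


def default_scenarios() -> tuple[ScenarioSpec, ...]:
    raw = yaml.safe_load(_data_text("scenarios.yaml"))
    return tuple(ScenarioSpec(**d) for d in raw)


def default_designs() -> tuple[DesignSpec, ...]:
    raw = yaml.safe_load(_data_text("designs.yaml"))
    return tuple(DesignSpec(**d) for d in raw)


# ---------------------------------------------------------------------------
# results + manifest

def _config_fingerprint(cfg: ExperimentConfig) -> str:
    blob = json.dumps(
        {
            "population": params_to_dict(cfg.population),
            "scenarios": [asdict(s) for s in cfg.scenarios],
            "designs": [asdict(d) for d in cfg.designs],
            "bias_variants": list(cfg.bias_variants),
            "iterations": cfg.iterations,
            "master_seed": cfg.master_seed,
            "spr_variance_mode": cfg.spr_variance_mode,
            "redraw_scenarios": cfg.redraw_scenarios,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def write_results(results: pd.DataFrame, summary: pd.DataFrame,
                  outdir, cfg: ExperimentConfig,
                  write_iterations: bool = True) -> dict:
    """Write iterations.csv (optional), summary.csv and manifest.json;
    returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if write_iterations:
        results.to_csv(outdir / "iterations.csv", index=False, float_format=FLOAT_FMT)
    summary.to_csv(outdir / "summary.csv", index=False, float_format=FLOAT_FMT)
    counts = (
        results.groupby(["scenario", "design", "bias"]).size() if len(results)
        else pd.Series(dtype=int)
    )
    manifest = {
        "package_version": __version__,
        "config_sha256": _config_fingerprint(cfg),
        "master_seed": cfg.master_seed,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "cells": {
            " / ".join(map(str, k)): int(v) for k, v in counts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
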