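"""Cohort table and results I/O, plus JSON/YAML configuration handling.

Cohort CSVs carry one row per patient with columns
``id,time,event[,mets_at_diag,<covariates...>]`` (days, event in {0,1});
optional ``true_alpha``/``true_mu``/``true_vdiag`` columns hold generator
ground truth.  Structured results are written as schema-versioned JSON,
curves as two-column CSV with an m_diag sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population import CovariateEffect, PopulationParams, SurvivalCurve

SCHEMA_VERSION = 1

REQUIRED_COLUMNS = ("id", "time", "event")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Requires id, time, event columns; coerces event to {0,1}; checks time > 0
    for patients not flagged metastatic at diagnosis (flagged rows may carry
    time 0).  Errors name the offending row.
    """
    table = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "mets_at_diag" not in table.columns:
        table["mets_at_diag"] = 0
    ev = table["event"]
    bad = ~ev.isin([0, 1, True, False])
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: non-binary event at row {row} (value {ev[row]!r})")
    table["event"] = ev.astype(int)
    mets = table["mets_at_diag"].astype(int)
    tm = table["time"]
    bad = (tm <= 0) & (mets == 0) | tm.isna() | (tm < 0)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: nonpositive time at row {row} (value {tm[row]!r})")
    table["mets_at_diag"] = mets
    return table


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and (math.isinf(obj) or math.isnan(obj)):
        return None if math.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results(results, path) -> list[Path]:
    """Write a result object (FitResult, IdentifiabilityResult, SurvivalCurve,
    or plain dict) to ``path``; curves get a CSV plus a JSON sidecar.

    Returns the list of files written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, SurvivalCurve):
        csv_path = path.with_suffix(".csv")
        pd.DataFrame({"time": results.times, "survival": results.survival}).to_csv(
            csv_path, index=False
        )
        side = path.with_suffix(".json")
        side.write_text(
            json.dumps(
                {"schema_version": SCHEMA_VERSION, "m_diag": results.m_diag}, indent=2
            )
        )
        return [csv_path, side]
    payload = {"schema_version": SCHEMA_VERSION, **_jsonify(results)}
    out = path if path.suffix == ".json" else path.with_suffix(".json")
    out.write_text(json.dumps(payload, indent=2))
    return [out]


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def population_from_config(cfg: dict) -> PopulationParams:
    """Build PopulationParams from the ``population`` section of a config."""
    from . import core

    sec = dict(cfg.get("population", cfg))
    kwargs = {}
    for key in (
        "log_alpha_pop",
        "omega_alpha",
        "log_mu_pop",
        "omega_mu",
        "vdiag_log_mean",
        "vdiag_log_sd",
        "carrying_capacity",
    ):
        if key in sec:
            kwargs[key] = float(sec[key])
    if "v_vis_diameter_mm" in sec or "cells_per_mm3" in sec:
        kwargs["v_vis"] = core.visible_volume_cells(
            float(sec.get("v_vis_diameter_mm", core.DEFAULT_VIS_DIAMETER_MM)),
            float(sec.get("cells_per_mm3", core.DEFAULT_CELLS_PER_MM3)),
        )
    return PopulationParams(**kwargs)


def effects_from_config(cfg: dict) -> list[CovariateEffect]:
    """Build covariate effects from the ``effects`` list of a config."""
    out = []
    for spec in cfg.get("effects", []):
        spec = dict(spec)
        if "b_k" in spec and spec["b_k"] is not None:
            spec["b_k"] = {int(k): float(v) for k, v in spec["b_k"].items()}
        out.append(CovariateEffect(**spec))
    return out


def default_config() -> dict:
    """The shipped defaults: model constants and estimation settings."""
    return {
        "population": {
            "log_alpha_pop": PopulationParams().log_alpha_pop,
            "omega_alpha": 1.0,
            "log_mu_pop": PopulationParams().log_mu_pop,
            "omega_mu": 2.2,
            "vdiag_log_mean": 3.196,
            "vdiag_log_sd": 1.711,
            "carrying_capacity": 1e12,
            "v_vis_diameter_mm": 5.0,
            "cells_per_mm3": 1e6,
        },
        "estimation": {
            "objective": "ss_mdiag",
            "lambda": 0.01,
            "m_scale": "percent",
            "n_starts": 5,
            "max_grid_points": 100,
        },
        "effects": [],
    }
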