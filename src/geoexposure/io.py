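"""Study bundling, configuration and output writing.

All study inputs are plain delimited text or JSON: a node table
(`node_id,x,y,population`), long-format exposure/outcome fields
(`node_id,time,variable,value`), a context CSV, JSON scenario files and an
optional causal unit table.  `load_study` cross-validates node ids and
time axes and returns one bundle; `write_outputs` emits predictions,
vulnerability maps and reports together with a manifest carrying the
config echo, seed and content hashes, so every artifact can be regenerated
from scratch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spatial import (SpatioTemporalField, SpatialGraph, build_adjacency,
                      read_node_table, read_field_long)
from .model import ContextSeries
from .cam import ExposureScenario

log = logging.getLogger("geoexposure")

__all__ = ["RunConfig", "StudyBundle", "load_study", "write_outputs",
           "read_scenarios_json", "read_context_csv"]

_CONFIG_KEYS = {
    "node_file", "exposure_file", "outcome_file", "context_file",
    "scenario_file", "causal_file", "output_dir",
    "sigma", "delta",
    "d", "diffusion_depth", "tau",
    "use_gpl", "use_tam", "use_aci",
    "lambda_epi", "mu_lap", "epsilon",
    "epochs", "lr", "seed",
}

_CONFIG_DEFAULTS = {
    "node_file": None, "exposure_file": None, "outcome_file": None,
    "context_file": None, "scenario_file": None, "causal_file": None,
    "output_dir": "geoexposure_out",
    "sigma": 0.2, "delta": 0.5,
    "d": 8, "diffusion_depth": 2, "tau": 4,
    "use_gpl": True, "use_tam": True, "use_aci": True,
    "lambda_epi": 0.0, "mu_lap": 0.0, "epsilon": 1e-3,
    "epochs": 200, "lr": 1e-3, "seed": 17,
}


@dataclass
class RunConfig:
    """Strictly validated run configuration; unknown keys are rejected and
    every default is explicit in the echoed dict."""

    values: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a YAML mapping")
        return cls(values=data)

    def override(self, **kwargs) -> "RunConfig":
        vals = dict(self.values)
        vals.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(values=vals)

    def __getitem__(self, key):
        return self.values[key]


@dataclass
class StudyBundle:
    graph: SpatialGraph
    exposure: SpatioTemporalField
    outcomes: SpatioTemporalField | None = None
    context: ContextSeries | None = None
    scenarios: list = dc_field(default_factory=list)


def read_context_csv(path) -> ContextSeries:
    """Context CSV: a `time` column, optional `policy*` columns, the rest
    context variables."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError("context file must have a 'time' column")
    df = df.sort_values("time")
    policy_cols = [c for c in df.columns if c.startswith("policy")]
    ctx_cols = [c for c in df.columns if c not in policy_cols and c != "time"]
    return ContextSeries(
        values=df[ctx_cols].to_numpy(dtype=float) if ctx_cols
        else np.zeros((len(df), 0)),
        policy=df[policy_cols].to_numpy(dtype=float) if policy_cols else None,
    )


def read_scenarios_json(path) -> list:
    """Scenario file: JSON array of {label, trajectory: tau x p lists}."""
    with open(path) as fh:
        spec = json.load(fh)
    if not isinstance(spec, list) or not spec:
        raise ValueError("scenario file must be a nonempty JSON array")
    return [ExposureScenario(trajectory=np.asarray(s["trajectory"], dtype=float),
                             label=s.get("label", f"scenario_{k}"))
            for k, s in enumerate(spec)]


def load_study(config: RunConfig) -> StudyBundle:
    """Read and cross-validate all study inputs named in the config."""
    if config["node_file"] is None or config["exposure_file"] is None:
        raise ValueError("node_file and exposure_file are required")
    nodes = read_node_table(config["node_file"])
    node_ids = nodes["node_id"].tolist()
    graph = build_adjacency(
        nodes[["x", "y"]].to_numpy(dtype=float),
        sigma=config["sigma"], delta=config["delta"],
        population=nodes["population"].to_numpy(dtype=float),
        node_ids=node_ids,
    )
    exposure = read_field_long(config["exposure_file"], node_ids=node_ids)
    outcomes = None
    if config["outcome_file"]:
        outcomes = read_field_long(config["outcome_file"], node_ids=node_ids)
        if not np.all(np.isin(outcomes.times, exposure.times)):
            raise ValueError("outcome times are not a subset of exposure times")
    context = read_context_csv(config["context_file"]) if config["context_file"] else None
    if context is not None and context.values.shape[0] != exposure.n_times:
        raise ValueError(
            f"context length {context.values.shape[0]} != exposure times "
            f"{exposure.n_times} (ragged time axes)"
        )
    scenarios = (read_scenarios_json(config["scenario_file"])
                 if config["scenario_file"] else [])
    log.info("loaded study: N=%d nodes, T=%d times, p=%d exposures%s",
             exposure.n_nodes, exposure.n_times, exposure.n_variables,
             f", q={outcomes.n_variables} outcomes" if outcomes else "")
    return StudyBundle(graph=graph, exposure=exposure, outcomes=outcomes,
                       context=context, scenarios=scenarios)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: dict, out_dir, config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write result artifacts plus a manifest with config echo and hashes.

    `results` maps artifact names to payloads: a DataFrame becomes CSV,
    anything else is written as JSON.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, payload in results.items():
        if isinstance(payload, pd.DataFrame):
            path = out / f"{name}.csv"
            payload.to_csv(path, index=False)
        else:
            path = out / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        files.append({"name": path.name, "sha256": _sha256(path)})
        log.info("wrote %s", path)
    manifest = {
        "files": sorted(files, key=lambda f: f["name"]),
        "config": dict(config.values) if config is not None else None,
        "seed": seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
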