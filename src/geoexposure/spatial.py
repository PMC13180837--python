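"""Spatial graphs and aggregation operators over spatiotemporal fields.

A study domain is a set of monitoring locations with planar coordinates and
population sizes.  Exposure and health-outcome measurements live on a dense
(node, time, variable) cube; this module provides the graph construction
(Gaussian proximity kernel with a locality cutoff), the population-weighted
nonlocal aggregation operator, regional averaging, and lookback windowing
used by the predictive model.

Coordinates are Euclidean in planar units: geographic longitude/latitude
must be projected by the caller before building a graph.  Integrals over
space and time are discretized as sums over nodes / time steps.  Missing
values are never imputed; an optional boolean mask (True = observed) may be
attached to a field and masked entries are excluded from aggregation means
with the weights renormalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "SpatioTemporalField",
    "SpatialGraph",
    "RegionMask",
    "SusceptibilityField",
    "build_adjacency",
    "graph_laplacian",
    "population_weights",
    "nonlocal_aggregate",
    "regional_mean",
    "exposure_window",
    "read_node_table",
    "read_field_long",
    "write_field_long",
    "read_region_json",
]


# ----------------------------------------------------------------- containers
@dataclass
class SpatioTemporalField:
    """Dense real-valued field over (node, time, variable).

    `mask`, if given, is boolean with the same shape; True marks observed
    entries.
    """

    values: np.ndarray
    node_ids: list
    times: np.ndarray
    variable_names: list
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.node_ids = list(self.node_ids)
        self.variable_names = list(self.variable_names)
        expected = (len(self.node_ids), len(self.times), len(self.variable_names))
        if self.values.shape != expected:
            raise ValueError(
                f"field shape {self.values.shape} != (nodes, times, variables) {expected}"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in field")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
            if not np.all(np.isfinite(self.values[self.mask])):
                raise ValueError("non-finite values at observed entries")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite field values (attach a mask for missing data)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)


@dataclass
class SpatialGraph:
    """Node coordinates, populations, Gaussian-kernel adjacency and Laplacian."""

    coords: np.ndarray
    population: np.ndarray
    sigma: float
    delta: float
    adjacency: np.ndarray
    laplacian: np.ndarray
    node_ids: list = dc_field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if not self.node_ids:
            self.node_ids = list(range(len(self.coords)))

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


@dataclass
class RegionMask:
    """A nonempty subset of nodes with optional positive area weights."""

    member_nodes: list
    area_weight: np.ndarray | None = None

    def __post_init__(self):
        self.member_nodes = list(self.member_nodes)
        if not self.member_nodes:
            raise ValueError("region must contain at least one node")
        if self.area_weight is None:
            self.area_weight = np.ones(len(self.member_nodes))
        else:
            self.area_weight = np.asarray(self.area_weight, dtype=float)
            if self.area_weight.shape != (len(self.member_nodes),):
                raise ValueError("one area weight per member node required")
            if np.any(self.area_weight <= 0):
                raise ValueError("area weights must be positive")


@dataclass
class SusceptibilityField:
    """Static per-node susceptibility covariates, shape (node, covariate)."""

    values: np.ndarray
    node_ids: list = dc_field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.node_ids:
            self.node_ids = list(range(self.values.shape[0]))
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node axis must match node ids")


# ------------------------------------------------------------------ operators
def _pairwise_sq_dists(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def build_adjacency(coords, sigma: float, delta: float, *, population=None,
                    node_ids=None) -> SpatialGraph:
    """Gaussian-kernel adjacency with a hard locality cutoff.

    A_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)) for pairs closer than `delta`,
    zero otherwise.  The diagonal is set to zero (no self-loops) so that
    L = D - A is the standard combinatorial graph Laplacian.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if sigma <= 0 or delta <= 0:
        raise ValueError("sigma and delta must be positive")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if node_ids is not None and len(set(node_ids)) != len(node_ids):
        raise ValueError("duplicate node ids")
    n = coords.shape[0]
    if n < 1:
        raise ValueError("at least one node required")
    d2 = _pairwise_sq_dists(coords)
    adj = np.exp(-d2 / (2.0 * sigma**2)) * (np.sqrt(d2) < delta)
    np.fill_diagonal(adj, 0.0)
    if population is None:
        population = np.ones(n)
    else:
        population = np.asarray(population, dtype=float)
        if np.any(population <= 0):
            raise ValueError("population must be strictly positive")
    return SpatialGraph(
        coords=coords,
        population=population,
        sigma=float(sigma),
        delta=float(delta),
        adjacency=adj,
        laplacian=graph_laplacian(adj),
        node_ids=list(node_ids) if node_ids is not None else list(range(n)),
    )


def graph_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian L = D - A with D the degree matrix."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(A - A.T), initial=0.0) > 1e-12:
        raise ValueError("adjacency must be symmetric (tolerance 1e-12)")
    if np.any(A < 0):
        raise ValueError("adjacency entries must be nonnegative")
    return np.diag(A.sum(axis=1)) - A


def population_weights(coords, population, sigma: float) -> np.ndarray:
    """Population-weighted proximity kernel W(x, x') = k_sigma(x, x') P(x').

    The self term (x' = x) is included: W(x, x) = P(x).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    population = np.asarray(population, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if np.any(population <= 0):
        raise ValueError("population must be strictly positive")
    d2 = _pairwise_sq_dists(coords)
    return np.exp(-d2 / (2.0 * sigma**2)) * population[None, :]


def nonlocal_aggregate(weights: np.ndarray, exposure_slice: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Weighted spatial smoothing: row-normalized kernel average of exposure.

    `exposure_slice` is (N,) or (N, variables); returns the same shape.
    With a mask, unobserved donor nodes are dropped from the average and the
    weights renormalized (per variable).
    """
    W = np.asarray(weights, dtype=float)
    E = np.asarray(exposure_slice, dtype=float)
    squeeze = E.ndim == 1
    E2 = E[:, None] if squeeze else E
    if mask is None:
        denom = W.sum(axis=1)
        bad = np.nonzero(denom <= 0)[0]
        if bad.size:
            raise ValueError(f"all-zero weight row for node index {bad[0]}")
        out = (W @ np.where(np.isfinite(E2), E2, 0.0)) / denom[:, None]
    else:
        M = (mask[:, None] if mask.ndim == 1 else mask).astype(float)
        denom = W @ M
        bad = np.argwhere(denom <= 0)
        if bad.size:
            raise ValueError(
                f"all-zero effective weight row for node index {int(bad[0][0])}"
            )
        out = (W @ (np.where(M > 0, E2, 0.0))) / denom
    return out[:, 0] if squeeze else out


def regional_mean(field: SpatioTemporalField, region: RegionMask,
                  time_index: int) -> np.ndarray:
    """Area-weight-normalized mean over region members at one time step.

    Serves both the regional exposure indicator and the regional health
    indicator; returns one value per field variable.
    """
    index = {nid: i for i, nid in enumerate(field.node_ids)}
    try:
        rows = np.array([index[n] for n in region.member_nodes])
    except KeyError as e:
        raise ValueError(f"region member {e.args[0]!r} not in field nodes") from None
    vals = field.values[rows, time_index, :]
    w = region.area_weight[:, None]
    if field.mask is not None:
        m = field.mask[rows, time_index, :].astype(float)
        denom = (w * m).sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("region entirely unobserved for some variable")
        return (w * m * np.where(m > 0, vals, 0.0)).sum(axis=0) / denom
    return (w * vals).sum(axis=0) / w.sum()


def exposure_window(field: SpatioTemporalField, t_index: int,
                    tau_steps: int) -> np.ndarray:
    """Lookback window: the (node, tau_steps, variable) slice ending at t.

    Both endpoints are included; no implicit padding — a window reaching
    before the first timestamp is an error.
    """
    if tau_steps < 1:
        raise ValueError("tau_steps must be >= 1")
    start = t_index - tau_steps + 1
    if start < 0:
        raise ValueError(
            f"window of {tau_steps} steps at t_index={t_index} extends before the series"
        )
    if t_index >= field.n_times:
        raise ValueError("t_index beyond the series")
    return field.values[:, start : t_index + 1, :]


# ------------------------------------------------------------------------- IO
def read_node_table(path) -> pd.DataFrame:
    """Read `node_id,x,y,population` delimited text."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"node_id", "x", "y", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    df["node_id"] = df["node_id"].astype(str)  # ids compare as text across files
    if df["node_id"].duplicated().any():
        dup = df.loc[df["node_id"].duplicated(), "node_id"].iloc[0]
        raise ValueError(f"duplicate node id {dup!r} in node table")
    return df


def read_field_long(path, node_ids=None) -> SpatioTemporalField:
    """Read long-format `node_id,time,variable,value` text into a dense cube.

    Duplicate (node, time, variable) keys are an error.  If `node_ids` is
    given, the node axis follows that order and unknown ids are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"node_id", "time", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"field file missing columns: {sorted(missing)}")
    df["node_id"] = df["node_id"].astype(str)
    if node_ids is not None:
        node_ids = [str(n) for n in node_ids]
    if df.duplicated(subset=["node_id", "time", "variable"]).any():
        row = df[df.duplicated(subset=["node_id", "time", "variable"])].iloc[0]
        raise ValueError(
            f"duplicate key (node={row['node_id']!r}, time={row['time']}, "
            f"variable={row['variable']!r}) in field file"
        )
    if node_ids is not None:
        unknown = set(df["node_id"]) - set(node_ids)
        if unknown:
            raise ValueError(f"field references unknown node id {sorted(unknown)[0]!r}")
        nodes = list(node_ids)
    else:
        nodes = sorted(df["node_id"].unique().tolist())
    times = np.sort(df["time"].unique())
    variables = sorted(df["variable"].unique().tolist())
    wide = df.pivot_table(index=["node_id", "time"], columns="variable",
                          values="value", aggfunc="first")
    full_index = pd.MultiIndex.from_product([nodes, times], names=["node_id", "time"])
    wide = wide.reindex(full_index)[variables]
    values = wide.to_numpy().reshape(len(nodes), len(times), len(variables))
    mask = None
    if np.isnan(values).any():
        mask = ~np.isnan(values)
        values = np.where(mask, values, 0.0)
    return SpatioTemporalField(values, nodes, times, variables, mask=mask)


def write_field_long(field: SpatioTemporalField, path) -> None:
    """Write a field as long-format `node_id,time,variable,value` text."""
    n, t, v = field.values.shape
    node_col = np.repeat(field.node_ids, t * v)
    time_col = np.tile(np.repeat(field.times, v), n)
    var_col = np.tile(field.variable_names, n * t)
    df = pd.DataFrame(
        {"node_id": node_col, "time": time_col, "variable": var_col,
         "value": field.values.ravel()}
    )
    if field.mask is not None:
        df = df[field.mask.ravel()]
    df.to_csv(path, index=False)


def read_region_json(path) -> RegionMask:
    """Read a region as a JSON list of node ids, or of {node, weight} pairs."""
    with open(path) as fh:
        spec = json.load(fh)
    if not isinstance(spec, list) or not spec:
        raise ValueError("region file must be a nonempty JSON list")
    if isinstance(spec[0], dict):
        members = [item["node"] for item in spec]
        weights = np.array([item.get("weight", 1.0) for item in spec], dtype=float)
        return RegionMask(members, weights)
    return RegionMask(spec)
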