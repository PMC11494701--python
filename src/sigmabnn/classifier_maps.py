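"""Response maps over input grids, decision boundaries, and comparisons.

A :class:`ResponseMap` holds per-node steady-state complex concentrations on
a regular lattice over ``[0, x_max]^2``.  Decision boundaries are thresholded
regions at a fraction ``theta`` of a map's maximum; mechanistic maps are
compared with the ideal resource-free reference both at matched theta and at
the decision-region convention the original figures use (ideal region =
where the ideal output is positive; mechanistic region = cells above a small
onset fraction of the map maximum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .bnn_network import evaluate_network, ideal_relu_network
from .mass_action import CompiledNetwork, compile_network
from .model_core import ContractError, NetworkSpec, network_hash, validate_network

__all__ = [
    "ResponseMap",
    "DecisionBoundary",
    "response_map",
    "ideal_response_map",
    "extract_decision_boundary",
    "overlap_metric",
    "region_mismatch",
    "deviation_from_ideal",
    "map_to_dataframe",
    "write_map",
]

#: default onset fraction used for decision-region comparisons
ONSET_THETA = 0.05

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class ResponseMap:
    """Per-node steady-state outputs on an input lattice.

    ``values[node][i, j]`` is the output at ``(x1[i], x2[j])``.  For
    mechanistic maps values are complex concentrations (uM) and
    ``normalized`` divides by ``c_tot``; for ideal maps values are the ideal
    node outputs and ``c_tot`` is None.
    """

    x1: np.ndarray
    x2: np.ndarray
    values: dict[str, np.ndarray]
    output_id: str
    c_tot: float | None
    metadata: dict = field(default_factory=dict)
    failed_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.x1) <= 0) or np.any(np.diff(self.x2) <= 0):
            raise ContractError("grid axes must be strictly increasing")

    @property
    def flagged(self) -> bool:
        return bool(self.failed_points)

    @property
    def resolution(self) -> int:
        return len(self.x1)

    def node(self, node_id: str | None = None) -> np.ndarray:
        return self.values[node_id or self.output_id]

    def normalized(self, node_id: str | None = None) -> np.ndarray:
        """Map scaled by c_tot (mechanistic) or returned as-is (ideal)."""
        vals = self.node(node_id)
        return vals / self.c_tot if self.c_tot else vals.copy()

    def max_normalized(self, node_id: str | None = None) -> np.ndarray:
        """Map scaled to its own maximum (zero map stays zero)."""
        vals = self.node(node_id)
        m = vals.max()
        return vals / m if m > 0 else vals.copy()


@dataclass
class DecisionBoundary:
    """Thresholded region of a response map and its 4-connected contour."""

    theta: float
    level: float  # absolute threshold theta * max
    region: np.ndarray  # boolean lattice
    contour: list[tuple[int, int]]
    n_components: int
    empty: bool


def response_map(
    network: NetworkSpec | CompiledNetwork,
    resolution: int = 51,
    solver: str = "algebraic",
    x_max: float = 1.0,
    tol: float = 1e-9,
) -> ResponseMap:
    """Steady-state output of every node over a resolution^2 input grid."""
    if resolution < 2:
        raise ContractError(f"resolution must be >= 2, got {resolution}")
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    net = comp.network
    if net.n_inputs != 2:
        raise ContractError("response maps are defined for 2-input networks")
    axis = np.linspace(0.0, x_max, resolution)
    values = {nid: np.zeros((resolution, resolution)) for nid in net.node_ids}
    failed: list[tuple[float, float]] = []
    for i, x1 in enumerate(axis):
        for j, x2 in enumerate(axis):
            resp = evaluate_network(comp, (x1, x2), solver=solver, tol=tol)
            for nid, val in resp.complexes.items():
                values[nid][i, j] = val
            if not resp.converged:
                failed.append((float(x1), float(x2)))
    meta = {
        "network": network_hash(net),
        "solver": solver,
        "resolution": resolution,
        "x_max": x_max,
        "tol": tol,
        "c_tot": net.c_tot,
    }
    return ResponseMap(
        x1=axis.copy(),
        x2=axis.copy(),
        values=values,
        output_id=net.output_id,
        c_tot=net.c_tot,
        metadata=meta,
        failed_points=failed,
    )


def ideal_response_map(network: NetworkSpec, resolution: int = 51, x_max: float = 1.0) -> ResponseMap:
    """Ideal resource-free ReLU reference on the same grid convention."""
    if resolution < 2:
        raise ContractError(f"resolution must be >= 2, got {resolution}")
    net = validate_network(network)
    axis = np.linspace(0.0, x_max, resolution)
    values = {nid: np.zeros((resolution, resolution)) for nid in net.node_ids}
    for i, x1 in enumerate(axis):
        for j, x2 in enumerate(axis):
            out = ideal_relu_network(net, (x1, x2))
            for nid, val in out.items():
                values[nid][i, j] = val
    meta = {"network": network_hash(net), "solver": "ideal", "resolution": resolution, "x_max": x_max}
    return ResponseMap(
        x1=axis.copy(),
        x2=axis.copy(),
        values=values,
        output_id=net.output_id,
        c_tot=None,
        metadata=meta,
    )


def _region(values: np.ndarray, theta: float) -> tuple[np.ndarray, float]:
    m = float(values.max())
    if m <= 0.0:
        return np.zeros_like(values, dtype=bool), 0.0
    level = theta * m
    return values >= level, level  # ties at the level are included


def extract_decision_boundary(map_or_values, theta: float = 0.5, node_id: str | None = None) -> DecisionBoundary:
    """Region at ``value >= theta * max`` plus its 4-connected edge cells.

    Accepts a ResponseMap (output node by default) or a raw 2-D array.
    A zero map yields an empty, explicitly flagged boundary.
    """
    if not 0.0 < theta < 1.0:
        raise ContractError(f"theta must be in (0, 1), got {theta}")
    values = map_or_values.node(node_id) if isinstance(map_or_values, ResponseMap) else np.asarray(map_or_values)
    region, level = _region(values, theta)
    if not region.any():
        return DecisionBoundary(theta, level, region, [], 0, empty=True)
    interior = ndimage.binary_erosion(region, structure=_FOUR_CONNECTED, border_value=0)
    edge = region & ~interior
    contour = [(int(i), int(j)) for i, j in np.argwhere(edge)]
    _, n_comp = ndimage.label(region, structure=_FOUR_CONNECTED)
    return DecisionBoundary(theta, level, region, contour, int(n_comp), empty=False)


def overlap_metric(values_i: np.ndarray, values_j: np.ndarray, eps: float = 0.1) -> float:
    """Fraction of cells where both maps exceed eps times their own max."""
    a = np.asarray(values_i, dtype=float)
    b = np.asarray(values_j, dtype=float)
    if a.shape != b.shape:
        raise ContractError(f"grid mismatch: {a.shape} vs {b.shape}")
    sa, _ = _region(a, eps)
    sb, _ = _region(b, eps)
    return float(np.mean(sa & sb))


def region_mismatch(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Fraction of grid cells on which two boolean regions disagree."""
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ContractError(f"grid mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a ^ b))


def deviation_from_ideal(
    mech: ResponseMap,
    ideal: ResponseMap,
    node_id: str | None = None,
    ideal_node_id: str | None = None,
    theta: float = 0.5,
    onset_theta: float = ONSET_THETA,
) -> dict:
    """Deviation of a mechanistic map from the ideal reference.

    Returns ``max_abs_norm_diff`` (maps scaled to their own maxima),
    ``region_mismatch_fraction`` (theta-of-max regions of both maps), and
    ``decision_region_mismatch`` (mechanistic onset region vs the ideal
    positive-support region -- the convention the reference figures draw as
    dashed ideal boundaries).  A zero ideal map against a nonzero mechanistic
    map is flagged degenerate.
    """
    mv = mech.node(node_id)
    iv = ideal.node(ideal_node_id or node_id)
    if mv.shape != iv.shape:
        raise ContractError(f"grid mismatch: {mv.shape} vs {iv.shape}")
    degenerate = bool(iv.max() <= 0.0 or mv.max() <= 0.0)
    mn = mech.max_normalized(node_id)
    inorm = iv / iv.max() if iv.max() > 0 else iv
    mech_region, _ = _region(mv, theta)
    ideal_region, _ = _region(iv, theta)
    onset_region, _ = _region(mv, onset_theta)
    return {
        "max_abs_norm_diff": float(np.max(np.abs(mn - inorm))),
        "region_mismatch_fraction": region_mismatch(mech_region, ideal_region),
        "decision_region_mismatch": region_mismatch(onset_region, iv > 0.0),
        "degenerate": degenerate,
    }


def map_to_dataframe(rm: ResponseMap) -> pd.DataFrame:
    """Long-format table: one row per (x1, x2, node)."""
    rows = []
    c_tot = rm.c_tot
    for nid in sorted(rm.values):
        vals = rm.values[nid]
        for i, x1 in enumerate(rm.x1):
            for j, x2 in enumerate(rm.x2):
                v = float(vals[i, j])
                rows.append(
                    {
                        "x1": float(x1),
                        "x2": float(x2),
                        "node_id": nid,
                        "c_bar": v,
                        "c_bar_norm": v / c_tot if c_tot else v,
                    }
                )
    return pd.DataFrame(rows, columns=["x1", "x2", "node_id", "c_bar", "c_bar_norm"])


def write_map(rm: ResponseMap, path: str | Path) -> tuple[Path, Path]:
    """Write the map as CSV plus a JSON metadata sidecar.

    ``path`` is the CSV destination; the sidecar replaces the suffix with
    ``.meta.json``.  Output is deterministic byte-for-byte.
    """
    csv_path = Path(path)
    meta_path = csv_path.with_suffix(".meta.json")
    df = map_to_dataframe(rm)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False, float_format="%.12g")
    meta = dict(rm.metadata)
    meta["failed_points"] = rm.failed_points
    meta["output_id"] = rm.output_id
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, meta_path
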