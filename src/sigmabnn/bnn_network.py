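"""Multilayer biomolecular neural networks and the ideal ReLU reference.

In a multilayer network the output of each node is its sigma-polymerase
complex; the occupancy of that complex drives production of the sigma (for a
positive weight) or antisigma (negative weight) of downstream nodes, while
every node in every layer competes for the same polymerase pool.  The ideal
reference network applies the same signed weights and biases through exact
ReLU units, with no kinetics and no resource pool.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .mass_action import CompiledNetwork, compile_network
from .model_core import (
    ContractError,
    NetworkSpec,
    NodeSpec,
    TopologyError,
    as_input,
    external_input_names,
    validate_network,
)
from .steady_state import SteadyStateResult, integrate_to_steady_state, solve_resource_fixed_point

__all__ = [
    "NetworkResponse",
    "evaluate_network",
    "ideal_relu_network",
    "production_rates_from_layer",
    "isolate_node",
]


@dataclass
class NetworkResponse:
    """Per-node steady-state outputs of a full network evaluation."""

    complexes: dict[str, float]
    normalized_complexes: dict[str, float]
    output_id: str
    steady_state: SteadyStateResult

    @property
    def output(self) -> float:
        return self.complexes[self.output_id]

    @property
    def output_normalized(self) -> float:
        return self.normalized_complexes[self.output_id]

    @property
    def converged(self) -> bool:
        return self.steady_state.converged


def evaluate_network(
    network: NetworkSpec | CompiledNetwork,
    x,
    solver: str = "algebraic",
    **solver_kwargs,
) -> NetworkResponse:
    """Steady-state complexes of every node of a feed-forward network."""
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    if solver == "algebraic":
        res = solve_resource_fixed_point(comp, x, **solver_kwargs)
    elif solver == "integration":
        res = integrate_to_steady_state(comp, x, **solver_kwargs)
    else:
        raise ContractError(f"solver must be 'algebraic' or 'integration', got {solver!r}")
    return NetworkResponse(
        complexes=res.complexes,
        normalized_complexes=res.normalized_complexes,
        output_id=comp.network.output_id,
        steady_state=res,
    )


def production_rates_from_layer(node: NodeSpec, sources: Mapping[str, float]) -> tuple[float, float]:
    """Accumulate signed weights into (sigma, antisigma) production rates.

    ``sources`` maps every source the node references (external input names
    or upstream node ids) to its drive value; biases are applied to the
    constant 1.  Raises ContractError on a missing source.
    """
    u = sum(b.magnitude for b in node.bias if b.sign > 0)
    v = sum(b.magnitude for b in node.bias if b.sign < 0)
    for source, w in node.input_weights.items():
        if source not in sources:
            raise ContractError(f"node {node.node_id!r} references unsolved source {source!r}")
        val = float(sources[source])
        if w.sign > 0:
            u += w.magnitude * val
        else:
            v += w.magnitude * val
    return float(u), float(v)


def ideal_relu_network(network: NetworkSpec, x) -> dict[str, float]:
    """Resource-free reference: node_out = max(0, signed weighted sum).

    Layer-1 sources are the external inputs; deeper sources are the upstream
    ideal outputs.  No kinetics, no pool, no saturation.
    """
    net = validate_network(network)
    xv = as_input(x, net.n_inputs)
    sources: dict[str, float] = dict(zip(external_input_names(net.n_inputs), xv))
    out: dict[str, float] = {}
    for node in net.nodes:  # canonical order = layer ascending
        u, v = production_rates_from_layer(node, sources)
        out[node.node_id] = max(0.0, u - v)
        sources[node.node_id] = out[node.node_id]
    return out


def isolate_node(network: NetworkSpec, node_id: str) -> NetworkSpec:
    """Single-node network containing only ``node_id`` (same pool, kinetics).

    Only meaningful for nodes whose sources are all external inputs.
    """
    net = validate_network(network)
    node = net.node(node_id)
    externals = set(external_input_names(net.n_inputs))
    internal = [s for s in node.input_weights if s not in externals]
    if internal:
        raise TopologyError(f"cannot isolate {node_id!r}: it reads upstream nodes {internal}")
    return validate_network(replace(net, nodes=(node,), output_node=node_id))
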