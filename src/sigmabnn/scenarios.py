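"""Named parameter presets and randomized fixture networks.

Every computational scenario of the study is available as a named preset:
single sequestration pairs, the resource-limited single perceptron with and
without a competing sigma factor, the two-node interference network, the
two-layer band-stop (dual-region) and band-pass classifiers, and the coupled
input-output variant.  Shared defaults are delta = 1 h^-1 and gamma2 =
10 uM^-1 h^-1; the sequestration rate gamma1 is the regime dial and must be
given explicitly for the activation-function scenarios (the study sweeps it
over {1, 10, 100, 1000} uM^-1 h^-1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model_core import (
    ConfigError,
    KineticParameters,
    NetworkSpec,
    NodeSpec,
    SignedWeight,
    network_to_json,
    validate_network,
)

__all__ = [
    "PRESET_NAMES",
    "GAMMA1_SWEEP",
    "load_preset",
    "generate_random_network",
    "write_preset_files",
]

#: gamma1 values used for the sequestration-regime sweeps (uM^-1 h^-1)
GAMMA1_SWEEP = (1.0, 10.0, 100.0, 1000.0)

_DELTA = 1.0
_GAMMA2 = 10.0


def _kin(gamma1: float) -> KineticParameters:
    return KineticParameters(gamma1=gamma1, gamma2=_GAMMA2, delta=_DELTA)


def _w(mag: float, sign: int) -> SignedWeight:
    return SignedWeight(mag, sign)


def _require_gamma1(name: str, gamma1: float | None) -> float:
    if gamma1 is None:
        raise ConfigError(
            f"preset {name!r} requires gamma1 explicitly; the regime sweeps use {GAMMA1_SWEEP}"
        )
    return float(gamma1)


def _single_node(w1: float = 1.0, w2: float = 1.0) -> NodeSpec:
    return NodeSpec(
        node_id="node1",
        layer=1,
        input_weights={"x1": _w(w1, +1), "x2": _w(w2, -1)},
    )


def _competitor(node_id: str, alpha: float, beta: float) -> NodeSpec:
    bias = []
    if alpha:
        bias.append(_w(alpha, +1))
    if beta:
        bias.append(_w(beta, -1))
    return NodeSpec(node_id=node_id, layer=1, bias=tuple(bias))


def fig2_single(gamma1: float | None = None, c_tot: float = 0.5) -> NetworkSpec:
    """One sigma/antisigma pair driven by (x1, x2); output is free sigma."""
    g1 = _require_gamma1("fig2_single", gamma1)
    return NetworkSpec(nodes=(_single_node(),), c_tot=c_tot, kinetics=_kin(g1))


def fig2_resources(gamma1: float | None = None, c_tot: float = 0.5) -> NetworkSpec:
    """Single perceptron with the limited polymerase pool; output c1."""
    g1 = _require_gamma1("fig2_resources", gamma1)
    return NetworkSpec(nodes=(_single_node(),), c_tot=c_tot, kinetics=_kin(g1))


def fig2_competition(
    gamma1: float | None = None,
    alpha: float = 0.5,
    beta: float = 0.0,
    c_tot: float = 0.5,
) -> NetworkSpec:
    """Perceptron plus a competing sigma/antisigma pair produced at (alpha, beta)."""
    g1 = _require_gamma1("fig2_competition", gamma1)
    return NetworkSpec(
        nodes=(_single_node(), _competitor("node2", alpha, beta)),
        c_tot=c_tot,
        kinetics=_kin(g1),
        output_node="node1",
    )


def fig3_node(gamma1: float = 100.0, c_tot: float = 0.5, w1: float = 1.0, w2: float = 1.0) -> NetworkSpec:
    """Isolated perceptron of the decision-boundary analyses (r = 0.1 default)."""
    return NetworkSpec(nodes=(_single_node(w1, w2),), c_tot=c_tot, kinetics=_kin(gamma1))


def fig3_competition(
    gamma1: float = 100.0,
    alpha2: float = 0.5,
    beta2: float = 0.5,
    c_tot: float = 0.5,
    w1: float = 1.0,
    w2: float = 1.0,
) -> NetworkSpec:
    """Perceptron with a constitutive competing node (alpha2, beta2)."""
    return NetworkSpec(
        nodes=(_single_node(w1, w2), _competitor("node2", alpha2, beta2)),
        c_tot=c_tot,
        kinetics=_kin(gamma1),
        output_node="node1",
    )


def fig4a_two_node(gamma1: float = 100.0, c_tot: float = 0.2) -> NetworkSpec:
    """Two same-layer perceptrons with deliberately overlapping responses.

    Node 1 peaks at (x1 -> 1, x2 -> 0) in isolation, node 2 at (1, 1);
    resource sharing attenuates each where the other is strongest.
    """
    node1 = NodeSpec(
        node_id="node1",
        layer=1,
        bias=(_w(1.0, +1),),
        input_weights={"x1": _w(1.0, +1), "x2": _w(1.0, -1)},
    )
    node2 = NodeSpec(
        node_id="node2",
        layer=1,
        bias=(_w(0.5, -1),),
        input_weights={"x1": _w(1.0, +1), "x2": _w(1.0, +1)},
    )
    return NetworkSpec(nodes=(node1, node2), c_tot=c_tot, kinetics=_kin(gamma1), output_node="node1")


def fig4e_bandstop(gamma1: float = 1000.0, c_tot: float = 0.2) -> NetworkSpec:
    """Two-layer dual-region (band-stop) classifier."""
    node1 = NodeSpec(
        node_id="node1",
        layer=1,
        bias=(_w(1.2, -1),),
        input_weights={"x1": _w(1.0, +1), "x2": _w(1.0, +1)},
    )
    node2 = NodeSpec(
        node_id="node2",
        layer=1,
        bias=(_w(0.7, +1),),
        input_weights={"x1": _w(1.0, -1), "x2": _w(1.0, -1)},
    )
    node3 = NodeSpec(
        node_id="node3",
        layer=2,
        bias=(_w(0.15, -1),),
        input_weights={"node1": _w(4.0, +1), "node2": _w(4.0, +1)},
    )
    return NetworkSpec(nodes=(node1, node2, node3), c_tot=c_tot, kinetics=_kin(gamma1))


def fig4h_bandpass(gamma1: float = 1000.0, c_tot: float = 0.5) -> NetworkSpec:
    """Two-layer band-pass classifier (high only in a central input band).

    c_tot is not tabulated for this design; the default 0.5 uM (mid-range of
    the study's [0, 1] uM polymerase range) makes the layer-1 complexes large
    enough that their summed inhibition can overcome the output node's
    0.3 uM/h constitutive bias, which the band-pass function requires.
    """
    node1 = NodeSpec(
        node_id="node1",
        layer=1,
        bias=(_w(0.4, +1),),
        input_weights={"x1": _w(0.5, -1), "x2": _w(0.5, -1)},
    )
    node2 = NodeSpec(
        node_id="node2",
        layer=1,
        bias=(_w(0.8, -1),),
        input_weights={"x1": _w(1.5, +1), "x2": _w(0.5, -1)},
    )
    node3 = NodeSpec(
        node_id="node3",
        layer=1,
        bias=(_w(0.8, -1),),
        input_weights={"x1": _w(0.5, -1), "x2": _w(1.5, +1)},
    )
    node4 = NodeSpec(
        node_id="node4",
        layer=2,
        bias=(_w(0.3, +1),),
        input_weights={"node1": _w(1.0, -1), "node2": _w(1.0, -1), "node3": _w(1.0, -1)},
    )
    return NetworkSpec(nodes=(node1, node2, node3, node4), c_tot=c_tot, kinetics=_kin(gamma1))


def s2_coupled(gamma1: float = 100.0, c_tot: float = 0.5, s_c: float = 1.0) -> NetworkSpec:
    """Single perceptron whose inputs consume the shared pool (housekeeping-driven)."""
    return NetworkSpec(
        nodes=(_single_node(),),
        c_tot=c_tot,
        coupling_mode="coupled",
        kinetics=_kin(gamma1),
        s_c=s_c,
    )


_PRESETS = {
    "fig2_single": fig2_single,
    "fig2_resources": fig2_resources,
    "fig2_competition": fig2_competition,
    "fig3_node": fig3_node,
    "fig3_competition": fig3_competition,
    "fig4a_two_node": fig4a_two_node,
    "fig4e_bandstop": fig4e_bandstop,
    "fig4h_bandpass": fig4h_bandpass,
    "s2_coupled": s2_coupled,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def load_preset(name: str, **overrides) -> NetworkSpec:
    """Return the validated preset network; keyword overrides are applied.

    Overrides are preset-builder arguments (gamma1, c_tot, alpha2, ...), not
    raw spec fields.
    """
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {list(PRESET_NAMES)}") from None
    return validate_network(builder(**overrides))


def generate_random_network(seed: int, n_nodes: int = 3, n_layers: int = 2) -> NetworkSpec:
    """Seeded random valid feed-forward network for property/oracle tests.

    Bimolecular rates are log-uniform in [0.1, 1000] uM^-1 h^-1, weights
    uniform in [0, 2] h^-1 with random signs, c_tot uniform in [0.1, 1] uM,
    delta = 1 h^-1.  The same seed yields a bitwise-identical serialization.
    """
    if not 1 <= n_nodes <= 4:
        raise ConfigError(f"n_nodes must be in [1, 4], got {n_nodes}")
    if not 1 <= n_layers <= 2:
        raise ConfigError(f"n_layers must be in [1, 2], got {n_layers}")
    rng = np.random.default_rng(seed)
    kin = KineticParameters(
        gamma1=float(10 ** rng.uniform(-1, 3)),
        gamma2=float(10 ** rng.uniform(-1, 3)),
        delta=1.0,
    )
    n_layers = min(n_layers, n_nodes)
    layers = [1 + (i % n_layers) for i in range(n_nodes)]  # layer 1 always populated
    nodes = []
    for i, layer in enumerate(layers):
        nid = f"n{i + 1}"
        sources = ["x1", "x2"]
        if layer > 1:
            sources += [f"n{j + 1}" for j in range(n_nodes) if layers[j] < layer]
        weights = {}
        for src in sources:
            if rng.random() < 0.7:
                weights[src] = SignedWeight(float(rng.uniform(0, 2)), 1 if rng.random() < 0.5 else -1)
        bias = ()
        if rng.random() < 0.5:
            bias = (SignedWeight(float(rng.uniform(0, 2)), 1 if rng.random() < 0.5 else -1),)
        nodes.append(NodeSpec(node_id=nid, layer=layer, bias=bias, input_weights=weights))
    top = max(layers)
    output = f"n{layers.index(top) + 1}"
    spec = NetworkSpec(
        nodes=tuple(nodes),
        c_tot=float(rng.uniform(0.1, 1.0)),
        kinetics=kin,
        output_node=output,
    )
    return validate_network(spec)


def write_preset_files(directory: str | Path) -> list[Path]:
    """Write every preset as a JSON config file (gamma1 = 1000 where required)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in PRESET_NAMES:
        try:
            spec = load_preset(name)
        except ConfigError:
            spec = load_preset(name, gamma1=1000.0)
        path = directory / f"{name}.json"
        path.write_text(network_to_json(spec) + "\n")
        written.append(path)
    return written
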