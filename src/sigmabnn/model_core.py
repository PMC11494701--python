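"""Domain types for sequestration-based biomolecular networks.

A network is a feed-forward arrangement of *nodes*, each a sigma-factor
perceptron: a sigma protein ``S_i`` and its antisigma ``A_i`` are produced at
rates set by signed weights on the external inputs (or on upstream node
outputs), sequester each other irreversibly, degrade, and the free sigma
competes with every other node's sigma for one conserved pool of core RNA
polymerase ``C``.  Concentrations are in uM and time in hours throughout.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ConfigError",
    "ParameterError",
    "TopologyError",
    "ContractError",
    "KineticParameters",
    "RegimeIndicators",
    "SignedWeight",
    "NodeSpec",
    "NetworkSpec",
    "StateLayout",
    "StateVector",
    "validate_network",
    "as_input",
    "external_input_names",
    "network_to_dict",
    "network_from_dict",
    "network_to_json",
    "network_from_json",
    "network_hash",
]


class ConfigError(ValueError):
    """Malformed or inconsistent network configuration."""


class ParameterError(ConfigError):
    """A numeric parameter violates its invariant (sign, finiteness)."""


class TopologyError(ConfigError):
    """Wiring violates the feed-forward (strictly lower layer) constraint."""


class ContractError(ValueError):
    """A call violated an operation contract (wrong shape, missing value)."""


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ParameterError(f"{name} must be finite and > 0, got {value!r}")
    return value


def _require_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of one node.

    gamma1 : sigma-antisigma sequestration rate constant (uM^-1 h^-1)
    gamma2 : sigma-polymerase complex formation rate constant (uM^-1 h^-1)
    delta  : first-order degradation / complex turnover rate (h^-1)
    """

    gamma1: float
    gamma2: float
    delta: float

    def __post_init__(self) -> None:
        _require_positive("gamma1", self.gamma1)
        _require_positive("gamma2", self.gamma2)
        _require_positive("delta", self.delta)

    @property
    def r(self) -> float:
        """Competitive binding ratio gamma2/gamma1."""
        return self.gamma2 / self.gamma1

    def to_dict(self) -> dict:
        return {"gamma1": self.gamma1, "gamma2": self.gamma2, "delta": self.delta}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "KineticParameters":
        try:
            return cls(float(d["gamma1"]), float(d["gamma2"]), float(d["delta"]))
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ConfigError(f"kinetics missing key {exc}") from exc


@dataclass(frozen=True)
class RegimeIndicators:
    """Dimensionless regime numbers of a network at a given input.

    ``r = gamma2/gamma1`` is the competitive binding ratio; ``r << 1`` is the
    fast competitive binding regime in which the thresholding (AReLU-like)
    response survives the resource limit.  ``xi`` is the sequestration-speed
    indicator; ``xi << 1`` marks fast sequestration, where thresholding
    emerges at all.
    """

    r: float
    xi: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ParameterError(f"r must be > 0, got {self.r}")
        if not self.xi > 0:
            raise ParameterError(f"xi must be > 0, got {self.xi}")

    @property
    def binding_regime(self) -> str:
        return "fast" if self.r < 1.0 else "slow"

    @property
    def sequestration_regime(self) -> str:
        return "fast" if self.xi < 1.0 else "slow"


@dataclass(frozen=True)
class SignedWeight:
    """A production-rate weight with a target choice.

    Positive sign drives production of the node's sigma factor, negative sign
    drives production of its antisigma.  ``magnitude`` is in h^-1 when applied
    to a concentration source (or uM h^-1 when applied to the constant virtual
    input 1 uM, i.e. a bias / constitutive production term).
    """

    magnitude: float
    sign: int = 1

    def __post_init__(self) -> None:
        _require_nonnegative("weight magnitude", self.magnitude)
        if self.sign not in (-1, 1):
            raise ConfigError(f"sign must be +1 or -1, got {self.sign!r}")

    @property
    def signed(self) -> float:
        return self.sign * self.magnitude

    def to_dict(self) -> dict:
        return {"w": self.magnitude, "sign": "+" if self.sign > 0 else "-"}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignedWeight":
        try:
            sign_str = d["sign"]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"weight must be {{'w':..,'sign':..}}, got {d!r}") from exc
        if sign_str not in ("+", "-"):
            raise ConfigError(f"weight sign must be '+' or '-', got {sign_str!r}")
        return cls(float(d["w"]), 1 if sign_str == "+" else -1)


def _as_bias(bias) -> tuple[SignedWeight, ...]:
    """Normalize a bias argument to a tuple of SignedWeights.

    A node may carry several constitutive production terms (e.g. a competitor
    node produced at rate alpha on the sigma side and beta on the antisigma
    side); each is a SignedWeight on the constant 1 uM virtual input.
    """
    if bias is None:
        return ()
    if isinstance(bias, SignedWeight):
        return (bias,)
    return tuple(bias)


@dataclass(frozen=True)
class NodeSpec:
    """One perceptron node: wiring and (optionally node-specific) kinetics."""

    node_id: str
    layer: int
    bias: tuple[SignedWeight, ...] = ()
    input_weights: Mapping[str, SignedWeight] = field(default_factory=dict)
    kinetics: KineticParameters | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias", _as_bias(self.bias))
        object.__setattr__(self, "input_weights", dict(self.input_weights))
        if not isinstance(self.node_id, str) or not self.node_id:
            raise ConfigError(f"node_id must be a nonempty string, got {self.node_id!r}")
        if int(self.layer) != self.layer or self.layer < 0:
            raise ConfigError(f"layer must be a nonnegative integer, got {self.layer!r}")
        object.__setattr__(self, "layer", int(self.layer))

    def to_dict(self) -> dict:
        d: dict = {"id": self.node_id, "layer": self.layer}
        if len(self.bias) == 1:
            d["bias"] = self.bias[0].to_dict()
        elif self.bias:
            d["bias"] = [b.to_dict() for b in self.bias]
        if self.input_weights:
            d["weights"] = {k: w.to_dict() for k, w in sorted(self.input_weights.items())}
        if self.kinetics is not None:
            d["kinetics"] = self.kinetics.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NodeSpec":
        bias_raw = d.get("bias")
        if bias_raw is None:
            bias: tuple[SignedWeight, ...] = ()
        elif isinstance(bias_raw, Mapping):
            bias = (SignedWeight.from_dict(bias_raw),)
        else:
            bias = tuple(SignedWeight.from_dict(b) for b in bias_raw)
        weights = {k: SignedWeight.from_dict(w) for k, w in d.get("weights", {}).items()}
        kin = d.get("kinetics")
        return cls(
            node_id=d["id"],
            layer=d["layer"],
            bias=bias,
            input_weights=weights,
            kinetics=None if kin is None else KineticParameters.from_dict(kin),
        )


@dataclass(frozen=True)
class NetworkSpec:
    """A feed-forward network sharing one finite polymerase pool.

    coupling_mode "coupled" models input species whose expression itself
    consumes the shared pool: a housekeeping sigma held at ``s_c`` uM binds
    polymerase into complexes C_S / C_A which drive layer-1 production.
    ``drive`` selects how upstream outputs enter downstream production rates:
    "occupancy" uses the normalized complex c_i/c_tot (default), scaled by
    ``gain`` (uM h^-1 per unit occupancy); "concentration" uses c_i directly.
    """

    nodes: tuple[NodeSpec, ...]
    c_tot: float
    coupling_mode: str = "uncoupled"
    n_inputs: int = 2
    kinetics: KineticParameters | None = None
    s_c: float = 1.0
    gain: float = 1.0
    drive: str = "concentration"
    output_node: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        _require_positive("c_tot", self.c_tot)
        _require_positive("gain", self.gain)
        _require_nonnegative("s_c", self.s_c)
        if self.coupling_mode not in ("uncoupled", "coupled"):
            raise ConfigError(f"coupling_mode must be 'uncoupled' or 'coupled', got {self.coupling_mode!r}")
        if self.drive not in ("occupancy", "concentration"):
            raise ConfigError(f"drive must be 'occupancy' or 'concentration', got {self.drive!r}")
        if int(self.n_inputs) != self.n_inputs or self.n_inputs < 0:
            raise ConfigError(f"n_inputs must be a nonnegative integer, got {self.n_inputs!r}")
        object.__setattr__(self, "n_inputs", int(self.n_inputs))
        if not self.nodes:
            raise ConfigError("network must contain at least one node")

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.node_id for n in self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def node_kinetics(self, node: NodeSpec) -> KineticParameters:
        kin = node.kinetics or self.kinetics
        if kin is None:
            raise ConfigError(f"node {node.node_id!r} has no kinetics and the network sets no default")
        return kin

    @property
    def output_id(self) -> str:
        """The designated output node: explicit, else the single top-layer node."""
        if self.output_node is not None:
            return self.output_node
        top = max(n.layer for n in self.nodes)
        ids = [n.node_id for n in self.nodes if n.layer == top]
        if len(ids) > 1:
            raise ConfigError(f"output node ambiguous between {ids}; set output_node explicitly")
        return ids[0]

    def to_dict(self) -> dict:
        d: dict = {
            "c_tot": self.c_tot,
            "coupling_mode": self.coupling_mode,
            "n_inputs": self.n_inputs,
        }
        if self.kinetics is not None:
            d["kinetics"] = self.kinetics.to_dict()
        if self.coupling_mode == "coupled":
            d["s_c"] = self.s_c
        if self.gain != 1.0:
            d["gain"] = self.gain
        if self.drive != "concentration":
            d["drive"] = self.drive
        if self.output_node is not None:
            d["output_node"] = self.output_node
        d["nodes"] = [n.to_dict() for n in self.nodes]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkSpec":
        if not isinstance(d, Mapping):
            raise ConfigError(f"network config must be a mapping, got {type(d).__name__}")
        try:
            nodes = tuple(NodeSpec.from_dict(nd) for nd in d["nodes"])
            c_tot = float(d["c_tot"])
        except KeyError as exc:
            raise ConfigError(f"network config missing key {exc}") from exc
        kin = d.get("kinetics")
        return cls(
            nodes=nodes,
            c_tot=c_tot,
            coupling_mode=d.get("coupling_mode", "uncoupled"),
            n_inputs=d.get("n_inputs", 2),
            kinetics=None if kin is None else KineticParameters.from_dict(kin),
            s_c=float(d.get("s_c", 1.0)),
            gain=float(d.get("gain", 1.0)),
            drive=d.get("drive", "concentration"),
            output_node=d.get("output_node"),
        )


def external_input_names(n_inputs: int) -> tuple[str, ...]:
    return tuple(f"x{i + 1}" for i in range(n_inputs))


def validate_network(spec: NetworkSpec) -> NetworkSpec:
    """Validate and canonicalize a network specification.

    Returns the spec with nodes sorted by (layer, node_id).  Raises
    ParameterError / TopologyError / ConfigError on violations.
    """
    ids = [n.node_id for n in spec.nodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate node ids: {dupes}")
    externals = set(external_input_names(spec.n_inputs))
    layer_of = {n.node_id: n.layer for n in spec.nodes}
    for node in spec.nodes:
        spec.node_kinetics(node)  # raises if unresolved
        for source in node.input_weights:
            if source in externals:
                continue
            if source not in layer_of:
                raise TopologyError(
                    f"node {node.node_id!r} weights unknown source {source!r} "
                    f"(externals: {sorted(externals)})"
                )
            if layer_of[source] >= node.layer:
                raise TopologyError(
                    f"node {node.node_id!r} (layer {node.layer}) may only read nodes in "
                    f"strictly lower layers; {source!r} is in layer {layer_of[source]}"
                )
    if spec.coupling_mode == "coupled":
        if spec.kinetics is None:
            raise ConfigError("coupled mode requires network-level kinetics for the housekeeping sigma")
        if spec.s_c < 0:
            raise ConfigError("coupled mode requires s_c >= 0")
    spec.output_id  # raises ConfigError when ambiguous
    canonical = tuple(sorted(spec.nodes, key=lambda n: (n.layer, n.node_id)))
    return replace(spec, nodes=canonical)


def as_input(x, n_inputs: int) -> np.ndarray:
    """Coerce an input point to a validated float vector of length n_inputs."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (n_inputs,):
        raise ContractError(f"input must have shape ({n_inputs},), got {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ContractError(f"input concentrations must be finite and >= 0, got {arr}")
    return arr


class StateLayout:
    """Index bookkeeping for the flat state vector of a network.

    Layout: ``[s_0..s_{n-1}, a_0..a_{n-1}, c_0..c_{n-1}, c_free(, c_S, c_A)]``
    in canonical node order; the housekeeping complexes are present only in
    coupled mode.
    """

    def __init__(self, network: NetworkSpec):
        self.network = network
        self.node_ids = network.node_ids
        n = len(self.node_ids)
        self.n_nodes = n
        self.s = slice(0, n)
        self.a = slice(n, 2 * n)
        self.c = slice(2 * n, 3 * n)
        self.c_free = 3 * n
        self.coupled = network.coupling_mode == "coupled"
        if self.coupled:
            self.c_s = 3 * n + 1
            self.c_a = 3 * n + 2
            self.size = 3 * n + 3
        else:
            self.c_s = self.c_a = None
            self.size = 3 * n + 1
        self.index = {nid: i for i, nid in enumerate(self.node_ids)}

    def zeros(self) -> np.ndarray:
        return np.zeros(self.size)

    def initial_state(self) -> np.ndarray:
        """Default initial condition: no proteins or complexes, pool all free."""
        y = np.zeros(self.size)
        y[self.c_free] = self.network.c_tot
        return y

    def pool_indices(self) -> list[int]:
        idx = list(range(self.c.start, self.c.stop)) + [self.c_free]
        if self.coupled:
            idx += [self.c_s, self.c_a]
        return idx


@dataclass
class StateVector:
    """A concentration state plus its layout, with labeled accessors."""

    y: np.ndarray
    layout: StateLayout

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.layout.size,):
            raise ContractError(
                f"state vector must have shape ({self.layout.size},), got {self.y.shape}"
            )

    def _node_dict(self, sl: slice) -> dict[str, float]:
        return dict(zip(self.layout.node_ids, self.y[sl]))

    @property
    def free_sigma(self) -> dict[str, float]:
        return self._node_dict(self.layout.s)

    @property
    def free_antisigma(self) -> dict[str, float]:
        return self._node_dict(self.layout.a)

    @property
    def complexes(self) -> dict[str, float]:
        return self._node_dict(self.layout.c)

    @property
    def normalized_complexes(self) -> dict[str, float]:
        c_tot = self.layout.network.c_tot
        return {k: v / c_tot for k, v in self.complexes.items()}

    @property
    def c_free(self) -> float:
        return float(self.y[self.layout.c_free])

    @property
    def housekeeping_complexes(self) -> tuple[float, float] | None:
        if not self.layout.coupled:
            return None
        return float(self.y[self.layout.c_s]), float(self.y[self.layout.c_a])

    @property
    def conservation_residual(self) -> float:
        """|c_free + sum(complexes) - c_tot|."""
        pool = self.y[self.layout.pool_indices()].sum()
        return abs(pool - self.layout.network.c_tot)

    def to_dict(self) -> dict:
        d = {
            "free_sigma": self.free_sigma,
            "free_antisigma": self.free_antisigma,
            "complexes": self.complexes,
            "normalized_complexes": self.normalized_complexes,
            "c_free": self.c_free,
        }
        hk = self.housekeeping_complexes
        if hk is not None:
            d["c_S"], d["c_A"] = hk
        return d


def network_to_dict(spec: NetworkSpec) -> dict:
    return spec.to_dict()


def network_from_dict(d: Mapping) -> NetworkSpec:
    return validate_network(NetworkSpec.from_dict(d))


def network_to_json(spec: NetworkSpec, indent: int | None = 2) -> str:
    return json.dumps(spec.to_dict(), indent=indent, sort_keys=True)


def network_from_json(text: str) -> NetworkSpec:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON: {exc}") from exc
    return network_from_dict(data)


def network_hash(spec: NetworkSpec) -> str:
    """Stable content hash of the canonical serialized network."""
    canonical = network_to_json(validate_network(spec), indent=None)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
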