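"""Mass-action ODE right-hand sides for sequestration networks.

Per node i the reaction set is::

    (sources) -> S_i        at u_i           (weighted sigma production)
    (sources) -> A_i        at v_i           (weighted antisigma production)
    S_i + A_i -> 0          at gamma1_i      (irreversible sequestration)
    S_i       -> 0          at delta_i
    A_i       -> 0          at delta_i
    S_i + C   -> C_i        at gamma2_i      (polymerase capture)
    C_i       -> S_i + C    at delta_i       (complex turnover)

Complex turnover returns both partners, so the polymerase pool
``c_free + sum(c_i)`` is conserved exactly and the free-pool degradation at
``delta`` is the only sigma sink.  This is what makes the normalized complex
``c_i/c_tot`` of an isolated node independent of the pool size, as the
saturated-ReLU analysis requires.

In coupled mode a housekeeping sigma held at ``s_c`` uM additionally captures
polymerase into complexes C_S and C_A (forward ``gamma2``, turnover
``delta``), and every externally-driven production term of the network is
proportional to the corresponding housekeeping occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    ConfigError,
    ContractError,
    NetworkSpec,
    StateLayout,
    StateVector,
    as_input,
    external_input_names,
    validate_network,
)

__all__ = ["CompiledNetwork", "compile_network", "build_rhs", "build_rhs_coupled", "check_conservation"]


@dataclass
class CompiledNetwork:
    """Vectorized parameter arrays for one validated network."""

    network: NetworkSpec
    layout: StateLayout
    # production wiring
    w_s_ext: np.ndarray  # (n_nodes, n_inputs) sigma-side external weights
    w_a_ext: np.ndarray
    b_s: np.ndarray  # (n_nodes,) sigma-side bias (constitutive, uM/h)
    b_a: np.ndarray
    w_s_int: np.ndarray  # (n_nodes, n_nodes) sigma-side weights on upstream drive
    w_a_int: np.ndarray
    # kinetics
    gamma1: np.ndarray
    gamma2: np.ndarray
    delta: np.ndarray
    # housekeeping (coupled mode)
    s_c: float
    hk_gamma2: float
    hk_delta: float

    @property
    def occupancy_drive(self) -> bool:
        return self.network.drive == "occupancy"


def compile_network(network: NetworkSpec) -> CompiledNetwork:
    net = validate_network(network)
    layout = StateLayout(net)
    n, m = layout.n_nodes, net.n_inputs
    externals = {name: k for k, name in enumerate(external_input_names(m))}
    w_s_ext = np.zeros((n, m))
    w_a_ext = np.zeros((n, m))
    b_s = np.zeros(n)
    b_a = np.zeros(n)
    w_s_int = np.zeros((n, n))
    w_a_int = np.zeros((n, n))
    gamma1 = np.zeros(n)
    gamma2 = np.zeros(n)
    delta = np.zeros(n)
    for i, node in enumerate(net.nodes):
        kin = net.node_kinetics(node)
        gamma1[i], gamma2[i], delta[i] = kin.gamma1, kin.gamma2, kin.delta
        for b in node.bias:
            if b.sign > 0:
                b_s[i] += b.magnitude
            else:
                b_a[i] += b.magnitude
        for source, w in node.input_weights.items():
            if source in externals:
                tgt = w_s_ext if w.sign > 0 else w_a_ext
                tgt[i, externals[source]] += w.magnitude
            else:
                j = layout.index[source]
                tgt = w_s_int if w.sign > 0 else w_a_int
                tgt[i, j] += w.magnitude
    if net.coupling_mode == "coupled":
        hk = net.kinetics
        if hk is None:  # validate_network already enforces this
            raise ConfigError("coupled mode requires network-level kinetics")
        s_c, hk_g2, hk_d = net.s_c, hk.gamma2, hk.delta
    else:
        s_c, hk_g2, hk_d = 0.0, 0.0, 0.0
    return CompiledNetwork(
        network=net,
        layout=layout,
        w_s_ext=w_s_ext,
        w_a_ext=w_a_ext,
        b_s=b_s,
        b_a=b_a,
        w_s_int=w_s_int,
        w_a_int=w_a_int,
        gamma1=gamma1,
        gamma2=gamma2,
        delta=delta,
        s_c=s_c,
        hk_gamma2=hk_g2,
        hk_delta=hk_d,
    )


def production_rates(comp: CompiledNetwork, x: np.ndarray, drive: np.ndarray,
                     hk_occupancy: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sigma / antisigma production rate vectors (uM/h) for a given state.

    ``drive`` is the per-node upstream drive value (occupancy or raw complex
    concentration, per network.drive).  In coupled mode the external + bias
    terms are scaled by the housekeeping occupancies ``hk_occupancy``.
    """
    fs = fa = 1.0
    if hk_occupancy is not None:
        fs, fa = hk_occupancy
    gain = comp.network.gain
    u = fs * (comp.w_s_ext @ x + comp.b_s) + gain * (comp.w_s_int @ drive)
    v = fa * (comp.w_a_ext @ x + comp.b_a) + gain * (comp.w_a_int @ drive)
    return u, v


def _rhs_factory(comp: CompiledNetwork):
    lo = comp.layout
    net = comp.network
    c_tot = net.c_tot
    occ = comp.occupancy_drive
    coupled = lo.coupled

    def rhs(t: float, y: np.ndarray, x) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (lo.size,):
            raise ContractError(f"state must have shape ({lo.size},), got {y.shape}")
        xv = as_input(x, net.n_inputs)
        s = y[lo.s]
        a = y[lo.a]
        c = y[lo.c]
        cf = y[lo.c_free]
        drive = c / c_tot if occ else c
        hk = None
        if coupled:
            cs, ca = y[lo.c_s], y[lo.c_a]
            hk = (cs / c_tot, ca / c_tot) if occ else (cs, ca)
        u, v = production_rates(comp, xv, drive, hk)
        seq = comp.gamma1 * s * a
        bind = comp.gamma2 * s * cf
        turn = comp.delta * c
        dy = np.empty_like(y)
        dy[lo.s] = u - seq - comp.delta * s - bind + turn
        dy[lo.a] = v - seq - comp.delta * a
        dy[lo.c] = bind - turn
        dcf = -bind.sum() + turn.sum()
        if coupled:
            hk_bind = comp.hk_gamma2 * comp.s_c * cf
            dy[lo.c_s] = hk_bind - comp.hk_delta * cs
            dy[lo.c_a] = hk_bind - comp.hk_delta * ca
            dcf += -2.0 * hk_bind + comp.hk_delta * (cs + ca)
        dy[lo.c_free] = dcf
        return dy

    return rhs


def build_rhs(network: NetworkSpec | CompiledNetwork):
    """Return the rate function ``rhs(t, y, x) -> dy`` for a network.

    Dispatches to the coupled variant when the spec requests it.
    """
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    return _rhs_factory(comp)


def build_rhs_coupled(network: NetworkSpec, s_c: float | None = None):
    """Rate function for the coupled input-output variant.

    ``s_c`` overrides the network's housekeeping sigma concentration (uM).
    """
    if network.coupling_mode != "coupled":
        from dataclasses import replace

        network = replace(network, coupling_mode="coupled")
    if s_c is not None:
        from dataclasses import replace

        network = replace(network, s_c=float(s_c))
    if network.kinetics is None:
        raise ConfigError("coupled mode requires network-level kinetics for the housekeeping sigma")
    return build_rhs(network)


def check_conservation(rhs, state: StateVector, x) -> float:
    """|d/dt (c_free + sum of complexes)| at a state -- a structural check.

    Zero (to rounding) for any rate function built by this module.
    """
    dy = rhs(0.0, state.y, x)
    return abs(float(np.sum(dy[state.layout.pool_indices()])))
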