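"""Steady states: time integration, exact algebraic solution, and limits.

Two independent routes to the same steady state are provided and are
cross-checked against each other in the test suite:

* :func:`integrate_to_steady_state` integrates the mass-action ODEs from the
  all-zero state until the right-hand side is numerically quiescent;
* :func:`solve_resource_fixed_point` solves the steady-state algebra exactly:
  each node's free sigma is the positive root of the sequestration quadratic

      gamma1*s^2 + (delta - gamma1*(u - v)/delta)*s - u = 0,

  its complex is ``c_i = (gamma2/delta) * s_i * c_free``, and the free pool
  ``c_free`` is the unique root of the strictly monotone pool balance
  ``c_free + sum(c_i(c_free)) = c_tot`` on [0, c_tot] (bracketed brentq).

The closed-form activation limits are :func:`arelu` (fast sequestration,
``max(0, (u-v)/delta)``) and the saturated form implied by
``c_n = gamma2*s/(delta + gamma2*s)`` for an isolated node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .mass_action import CompiledNetwork, build_rhs, compile_network
from .model_core import (
    ContractError,
    KineticParameters,
    NetworkSpec,
    RegimeIndicators,
    StateVector,
    as_input,
)

__all__ = [
    "SteadyStateResult",
    "Trajectory",
    "solve_sequestration_pair",
    "arelu",
    "solve_resource_fixed_point",
    "integrate_to_steady_state",
    "transient_trajectory",
    "regime",
]

#: default quiescence criterion on ||rhs||_inf, in uM/h
DEFAULT_TOL = 1e-9
#: default integration horizon, hours
DEFAULT_T_MAX = 1e4


@dataclass
class SteadyStateResult:
    """A steady state with convergence diagnostics."""

    state: StateVector
    converged: bool
    residual_norm: float
    method: str
    t_final: float | None = None

    @property
    def complexes(self) -> dict[str, float]:
        return self.state.complexes

    @property
    def normalized_complexes(self) -> dict[str, float]:
        return self.state.normalized_complexes

    @property
    def free_sigma(self) -> dict[str, float]:
        return self.state.free_sigma

    @property
    def conservation_residual(self) -> float:
        return self.state.conservation_residual


@dataclass
class Trajectory:
    """Time-indexed states from the transient response of a network."""

    t: np.ndarray
    y: np.ndarray  # (n_times, n_state)
    layout: "StateLayout"

    def state(self, i: int) -> StateVector:
        return StateVector(self.y[i], self.layout)

    def complex_series(self, node_id: str) -> np.ndarray:
        j = self.layout.c.start + self.layout.index[node_id]
        return self.y[:, j]


def _seq_quadratic_root(u: float, v: float, gamma1: float, delta: float) -> float:
    """Positive root of gamma1*s^2 + (delta - gamma1*(u-v)/delta)*s - u = 0."""
    if u <= 0.0:
        return 0.0
    b = delta - gamma1 * (u - v) / delta
    disc = b * b + 4.0 * gamma1 * u
    sq = math.sqrt(disc)
    # numerically stable positive branch
    if b >= 0.0:
        return 2.0 * u / (b + sq)
    return (sq - b) / (2.0 * gamma1)


def solve_sequestration_pair(u: float, v: float, k: KineticParameters) -> tuple[float, float]:
    """Exact steady state of one sigma/antisigma pair without polymerase.

    ``u`` and ``v`` are the sigma and antisigma production rates (uM/h).
    Returns ``(s_bar, a_bar)``, the unique nonnegative root pair.
    """
    if u < 0 or v < 0:
        raise ContractError(f"production rates must be >= 0, got u={u}, v={v}")
    s = _seq_quadratic_root(u, v, k.gamma1, k.delta)
    a = v / (k.gamma1 * s + k.delta)
    return s, a


def arelu(u: float, v: float, delta: float) -> float:
    """Asymptotic ReLU: the fast-sequestration limit max(0, (u - v)/delta)."""
    return max(0.0, (u - v) / delta)


def _steady_given_cfree(comp: CompiledNetwork, x: np.ndarray, cf: float):
    """Layer-ordered exact node steady states for a fixed free-pool value."""
    lo = comp.layout
    n = lo.n_nodes
    c_tot = comp.network.c_tot
    occ = comp.occupancy_drive
    s = np.zeros(n)
    a = np.zeros(n)
    c = np.zeros(n)
    drive = np.zeros(n)
    hk = None
    cs = ca = 0.0
    if lo.coupled:
        cs = ca = comp.hk_gamma2 * comp.s_c * cf / comp.hk_delta
        hk_val = cs / c_tot if occ else cs
        hk = (hk_val, hk_val)
    # canonical order is layer-ascending, so upstream drives are already set
    for i in range(n):
        fs, fa = hk if hk is not None else (1.0, 1.0)
        u_i = fs * (comp.w_s_ext[i] @ x + comp.b_s[i]) + comp.network.gain * (comp.w_s_int[i] @ drive)
        v_i = fa * (comp.w_a_ext[i] @ x + comp.b_a[i]) + comp.network.gain * (comp.w_a_int[i] @ drive)
        s[i] = _seq_quadratic_root(u_i, v_i, comp.gamma1[i], comp.delta[i])
        a[i] = v_i / (comp.gamma1[i] * s[i] + comp.delta[i])
        c[i] = comp.gamma2[i] * s[i] * cf / comp.delta[i]
        drive[i] = c[i] / c_tot if occ else c[i]
    return s, a, c, cs, ca


def solve_resource_fixed_point(
    network: NetworkSpec | CompiledNetwork,
    x,
    tol: float = DEFAULT_TOL,
) -> SteadyStateResult:
    """Exact algebraic steady state of the shared-pool network.

    Solves the scalar pool balance g(c_free) = c_free + sum(c_i) +
    (housekeeping complexes) - c_tot, which is strictly increasing on
    [0, c_tot], then reassembles the full state.  ``converged`` reflects the
    mass-action residual of the assembled state against ``tol``.
    """
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    net = comp.network
    xv = as_input(x, net.n_inputs)
    c_tot = net.c_tot

    def pool_balance(cf: float) -> float:
        _, _, c, cs, ca = _steady_given_cfree(comp, xv, cf)
        return cf + c.sum() + cs + ca - c_tot

    hi = pool_balance(c_tot)
    if hi <= 0.0:  # no polymerase consumed anywhere
        cf = c_tot
    else:
        cf = brentq(pool_balance, 0.0, c_tot, xtol=1e-16 * max(1.0, c_tot), rtol=8.9e-16)
    s, a, c, cs, ca = _steady_given_cfree(comp, xv, cf)
    lo = comp.layout
    y = lo.zeros()
    y[lo.s] = s
    y[lo.a] = a
    y[lo.c] = c
    # place the pool remainder exactly so conservation is identical
    y[lo.c_free] = c_tot - c.sum() - cs - ca
    if lo.coupled:
        y[lo.c_s] = cs
        y[lo.c_a] = ca
    rhs = build_rhs(comp)
    residual = float(np.max(np.abs(rhs(0.0, y, xv))))
    return SteadyStateResult(
        state=StateVector(y, lo),
        converged=residual < tol,
        residual_norm=residual,
        method="algebraic",
    )


def integrate_to_steady_state(
    network: NetworkSpec | CompiledNetwork,
    x,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SteadyStateResult:
    """Integrate the mass-action ODEs from the all-zero state to quiescence.

    Integration proceeds in doubling time chunks until ``||rhs||_inf < tol``
    or ``t_max`` is reached; non-convergence is flagged, not raised.
    """
    if tol <= 0:
        raise ContractError(f"tol must be > 0, got {tol}")
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    net = comp.network
    xv = as_input(x, net.n_inputs)
    rhs = build_rhs(comp)
    fun = lambda t, y: rhs(t, y, xv)  # noqa: E731
    lo = comp.layout
    y = lo.initial_state()
    t0, t1 = 0.0, 16.0
    residual = float(np.max(np.abs(fun(t0, y))))
    while residual >= tol and t0 < t_max:
        t1 = min(t1, t_max)
        sol = solve_ivp(fun, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover - LSODA failure is pathological here
            break
        y = sol.y[:, -1]
        t0, t1 = t1, t1 * 2.0
        residual = float(np.max(np.abs(fun(t0, y))))
    return SteadyStateResult(
        state=StateVector(y, lo),
        converged=residual < tol,
        residual_norm=residual,
        method="integration",
        t_final=t0,
    )


def transient_trajectory(
    network: NetworkSpec | CompiledNetwork,
    x,
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Full transient from the all-zero initial condition on a time grid."""
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ContractError("t_grid must be nonempty")
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ContractError("t_grid must be strictly increasing and start at 0")
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    xv = as_input(x, comp.network.n_inputs)
    rhs = build_rhs(comp)
    lo = comp.layout
    sol = solve_ivp(
        lambda tt, y: rhs(tt, y, xv),
        (0.0, float(t[-1])),
        lo.initial_state(),
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    return Trajectory(t=sol.t, y=sol.y.T, layout=lo)


def regime(network: NetworkSpec | CompiledNetwork, x) -> RegimeIndicators:
    """Regime indicators r = gamma2/gamma1 and xi at a given input.

    xi = delta^2 / (gamma1 * max production flux), the dimensionless group
    comparing degradation to sequestration at the operating flux; the flux
    maximum runs over the individual externally-driven production terms
    (w*x and biases).  xi is +inf when every such term vanishes.
    """
    comp = network if isinstance(network, CompiledNetwork) else compile_network(network)
    net = comp.network
    xv = as_input(x, net.n_inputs)
    kin = net.kinetics or net.node_kinetics(net.nodes[0])
    terms = [comp.b_s.max(initial=0.0), comp.b_a.max(initial=0.0)]
    if net.n_inputs:
        terms.append(float((comp.w_s_ext * xv).max(initial=0.0)))
        terms.append(float((comp.w_a_ext * xv).max(initial=0.0)))
    flux = max(terms)
    xi = math.inf if flux == 0.0 else kin.delta**2 / (kin.gamma1 * flux)
    return RegimeIndicators(r=kin.gamma2 / kin.gamma1, xi=xi)
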