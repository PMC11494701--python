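import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigmabnn import (
    ContractError,
    KineticParameters,
    NetworkSpec,
    NodeSpec,
    SignedWeight,
    arelu,
    integrate_to_steady_state,
    load_preset,
    regime,
    response_map,
    solve_resource_fixed_point,
    solve_sequestration_pair,
    transient_trajectory,
)


def pair_oracle(u, v, gamma1, delta=1.0):
    """Independent quadratic-formula oracle for the sequestration pair."""
    coeffs = [gamma1, delta - gamma1 * (u - v) / delta, -u]
    roots = np.roots(coeffs)
    real = roots[np.isreal(roots)].real
    return float(max(real.max(), 0.0))


class TestSequestrationPair:
    def test_matches_quadratic_formula_oracle(self):
        k = KineticParameters(10.0, 10.0, 1.0)
        s, a = solve_sequestration_pair(1.0, 0.5, k)
        assert s == pytest.approx((4.0 + np.sqrt(56.0)) / 20.0, rel=1e-12)
        assert s == pytest.approx(pair_oracle(1.0, 0.5, 10.0), rel=1e-10)
        assert a == pytest.approx(s - 0.5, rel=1e-10)  # a = s - (u - v)/delta

    def test_fast_sequestration_approaches_difference(self):
        k = KineticParameters(1000.0, 10.0, 1.0)
        s, _ = solve_sequestration_pair(1.0, 0.5, k)
        assert s == pytest.approx(pair_oracle(1.0, 0.5, 1000.0), rel=1e-10)
        assert abs(s - 0.5) < 2e-3

    def test_slow_sequestration_loses_thresholding(self):
        # gamma1 -> 0: s -> u/delta regardless of v (no subtraction left)
        k = KineticParameters(1e-3, 10.0, 1.0)
        s, _ = solve_sequestration_pair(0.4, 0.8, k)
        assert s == pytest.approx(0.4, rel=5e-3)

    @given(
        u=st.floats(0.0, 10.0),
        v=st.floats(0.0, 10.0),
        g1=st.floats(0.1, 1e4),
    )
    def test_properties_nonnegative_and_oracle_consistent(self, u, v, g1):
        k = KineticParameters(g1, 10.0, 1.0)
        s, a = solve_sequestration_pair(u, v, k)
        assert s >= 0.0 and a >= 0.0
        assert s == pytest.approx(pair_oracle(u, v, g1), rel=1e-8, abs=1e-12)
        if u == v:
            assert s == pytest.approx(a, rel=1e-9, abs=1e-12)

    def test_symmetric_inputs_give_equal_pair(self):
        k = KineticParameters(50.0, 10.0, 1.0)
        s, a = solve_sequestration_pair(0.7, 0.7, k)
        assert s == pytest.approx(a, rel=1e-12)

    def test_negative_production_is_a_contract_error(self):
        with pytest.raises(ContractError):
            solve_sequestration_pair(-1.0, 0.0, KineticParameters(10.0, 10.0, 1.0))


class TestArelu:
    @pytest.mark.parametrize(
        "u,v,delta,expected", [(1.0, 0.0, 1.0, 1.0), (0.3, 0.5, 1.0, 0.0), (0.5, 0.5, 1.0, 0.0), (2.0, 0.5, 2.0, 0.75)]
    )
    def test_thresholded_difference(self, u, v, delta, expected):
        assert arelu(u, v, delta) == expected

    def test_limit_of_exact_pair_on_grid(self):
        k = KineticParameters(1e4, 10.0, 1.0)
        axis = np.linspace(0.0, 1.0, 11)
        worst = max(
            abs(solve_sequestration_pair(x1, x2, k)[0] - arelu(x1, x2, 1.0))
            for x1 in axis
            for x2 in axis
        )
        assert worst <= 1e-2


class TestResourceFixedPoint:
    def test_single_sigma_closed_form(self, single_sigma_only):
        # turnover returns the sigma, so delta*s_bar = u exactly; the complex
        # follows c_n = gamma2*s/(delta + gamma2*s) independent of c_tot
        res = solve_resource_fixed_point(single_sigma_only, (1.0, 0.0))
        assert res.converged
        assert res.free_sigma["n1"] == pytest.approx(1.0, rel=1e-12)
        assert res.normalized_complexes["n1"] == pytest.approx(10.0 / 11.0, rel=1e-12)
        assert res.conservation_residual < 1e-15

    def test_agrees_with_integration(self, single_perceptron):
        ra = solve_resource_fixed_point(single_perceptron, (1.0, 0.5))
        rb = integrate_to_steady_state(single_perceptron, (1.0, 0.5))
        assert rb.converged
        np.testing.assert_allclose(ra.state.y, rb.state.y, rtol=1e-6, atol=1e-9)

    def test_below_threshold_input_gives_no_response(self, single_perceptron):
        res = solve_resource_fixed_point(single_perceptron, (0.3, 0.9))
        assert res.normalized_complexes["node1"] < 0.05

    def test_identical_competing_nodes_split_pool_equally(self):
        kin = KineticParameters(1000.0, 10.0, 1.0)
        nodes = tuple(
            NodeSpec(f"n{i}", layer=1, input_weights={"x1": SignedWeight(1.0, 1)}) for i in (1, 2)
        )
        net = NetworkSpec(nodes=nodes, c_tot=0.4, kinetics=kin, output_node="n1")
        res = solve_resource_fixed_point(net, (0.8, 0.0))
        assert res.complexes["n1"] == pytest.approx(res.complexes["n2"], rel=1e-12)

    def test_zero_inputs_zero_bias_zero_state(self, single_perceptron):
        res = solve_resource_fixed_point(single_perceptron, (0.0, 0.0))
        assert res.converged
        assert res.free_sigma["node1"] == 0.0
        assert res.state.c_free == pytest.approx(single_perceptron.c_tot)

    def test_saturation_bounded_by_competitor_remainder(self):
        # with a competitor holding c2, node 1 can never exceed c_tot - c2
        net = load_preset("fig3_competition", gamma1=1000.0, alpha2=1.0, beta2=0.0)
        axis = np.linspace(0.0, 1.0, 11)
        for x1 in axis:
            res = solve_resource_fixed_point(net, (x1, 0.0))
            c = res.complexes
            assert c["node1"] <= net.c_tot - c["node2"] + 1e-9

    def test_free_sigma_unchanged_by_pool_size(self):
        # the sequestration subtraction is pool-independent; only c scales
        r1 = solve_resource_fixed_point(load_preset("fig2_resources", gamma1=100.0, c_tot=0.2), (1.0, 0.4))
        r2 = solve_resource_fixed_point(load_preset("fig2_resources", gamma1=100.0, c_tot=0.8), (1.0, 0.4))
        assert r1.free_sigma["node1"] == pytest.approx(r2.free_sigma["node1"], rel=1e-12)


class TestTransient:
    def test_complexes_start_at_zero_and_rise_monotonically(self):
        net = load_preset("fig3_node", gamma1=100.0)
        tr = transient_trajectory(net, (0.8, 0.2), np.linspace(0.0, 30.0, 61))
        c1 = tr.complex_series("node1")
        assert c1[0] == 0.0
        assert np.all(np.diff(c1) >= -1e-10)

    def test_final_point_matches_steady_state(self):
        net = load_preset("fig3_node", gamma1=100.0)
        tr = transient_trajectory(net, (0.8, 0.2), np.linspace(0.0, 60.0, 61))
        res = solve_resource_fixed_point(net, (0.8, 0.2))
        np.testing.assert_allclose(tr.y[-1], res.state.y, rtol=1e-6, atol=1e-9)

    def test_transient_argmax_matches_steady_argmax(self):
        # the decision boundary forms before steady state: peak input corner
        # (x1 -> 1, x2 -> 0) is the same at t = 1 h and at steady state
        net = load_preset("fig3_node", gamma1=100.0)
        axis = np.linspace(0.0, 1.0, 6)
        early = np.zeros((6, 6))
        for i, x1 in enumerate(axis):
            for j, x2 in enumerate(axis):
                tr = transient_trajectory(net, (x1, x2), np.array([0.0, 1.0]))
                early[i, j] = tr.complex_series("node1")[-1]
        steady = response_map(net, resolution=6).node("node1")
        assert np.unravel_index(early.argmax(), early.shape) == (5, 0)
        assert np.unravel_index(steady.argmax(), steady.shape) == (5, 0)
        assert early.max() < steady.max()  # transient response magnitude is smaller

    def test_bad_time_grids_are_contract_errors(self):
        net = load_preset("fig3_node")
        with pytest.raises(ContractError):
            transient_trajectory(net, (0.5, 0.5), [])
        with pytest.raises(ContractError):
            transient_trajectory(net, (0.5, 0.5), [1.0, 2.0])


class TestRegime:
    @pytest.mark.parametrize("g1,expected_r", [(100.0, 0.1), (1000.0, 0.01), (10.0, 1.0)])
    def test_competitive_binding_ratio(self, g1, expected_r):
        net = load_preset("fig2_resources", gamma1=g1)
        ind = regime(net, (1.0, 0.5))
        assert ind.r == pytest.approx(expected_r)
        assert ind.binding_regime == ("fast" if expected_r < 1 else "slow")

    def test_sequestration_indicator_scales_with_flux(self):
        net = load_preset("fig2_resources", gamma1=100.0)
        ind = regime(net, (1.0, 0.5))
        assert ind.xi == pytest.approx(1.0 / 100.0)  # delta^2/(gamma1 * max(w*x))
        assert ind.sequestration_regime == "fast"
        quiet = regime(net, (0.0, 0.0))
        assert quiet.xi == np.inf
        assert quiet.sequestration_regime == "slow"
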