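import numpy as np
import pandas as pd
import pytest

from sigmabnn import (
    ContractError,
    KineticParameters,
    NetworkSpec,
    NodeSpec,
    SignedWeight,
    deviation_from_ideal,
    extract_decision_boundary,
    ideal_response_map,
    load_preset,
    map_to_dataframe,
    overlap_metric,
    region_mismatch,
    response_map,
    write_map,
)


def _zero_weight_network():
    node = NodeSpec("n1", layer=1, input_weights={"x1": SignedWeight(0.0, 1)})
    return NetworkSpec(nodes=(node,), c_tot=0.2, kinetics=KineticParameters(10.0, 10.0, 1.0))


class TestResponseMap:
    def test_isolated_perceptron_peaks_at_x1_high_x2_low(self):
        rm = response_map(load_preset("fig3_node", gamma1=1000.0), resolution=21)
        assert np.unravel_index(rm.node("node1").argmax(), (21, 21)) == (20, 0)
        assert rm.node("node1").min() >= 0.0
        assert rm.normalized("node1").max() <= 1.0 + 1e-12

    def test_zero_weights_give_identically_zero_map(self):
        rm = response_map(_zero_weight_network(), resolution=5)
        assert rm.node("n1").max() == 0.0

    def test_algebraic_and_integration_maps_agree(self):
        net = load_preset("fig3_competition", gamma1=100.0)
        ra = response_map(net, resolution=7, solver="algebraic")
        rb = response_map(net, resolution=7, solver="integration")
        for nid in net.node_ids:
            np.testing.assert_allclose(ra.node(nid), rb.node(nid), rtol=1e-6, atol=1e-9)

    def test_resolution_contract(self):
        with pytest.raises(ContractError):
            response_map(load_preset("fig3_node"), resolution=1)


class TestDecisionBoundary:
    def test_constant_positive_map_covers_entire_grid(self):
        values = np.full((5, 5), 2.0)
        db = extract_decision_boundary(values, theta=0.5)
        assert db.region.all() and not db.empty
        assert db.n_components == 1
        # contour is the outer frame of the solid region
        assert (0, 0) in db.contour and (2, 2) not in db.contour

    def test_zero_map_yields_flagged_empty_boundary(self):
        db = extract_decision_boundary(np.zeros((4, 4)), theta=0.5)
        assert db.empty and db.n_components == 0 and not db.region.any()

    def test_theta_contract(self):
        with pytest.raises(ContractError):
            extract_decision_boundary(np.ones((3, 3)), theta=1.5)

    def test_ties_at_threshold_are_included(self):
        values = np.array([[1.0, 0.5], [0.25, 0.0]])
        db = extract_decision_boundary(values, theta=0.5)
        assert db.region[0, 1] and not db.region[1, 0]

    def test_weight_tuning_rotates_boundary_toward_smaller_x1(self):
        # larger w1 lowers the x1 threshold at fixed x2 (ideal line x1 = (w2/w1) x2)
        crossings = []
        for w1 in (1.0, 1.5, 2.0):
            rm = response_map(load_preset("fig3_node", gamma1=1000.0, w1=w1), resolution=41)
            region = extract_decision_boundary(rm, theta=0.5, node_id="node1").region
            j = 30  # x2 = 0.75
            crossings.append(rm.x1[np.argmax(region[:, j])])
        assert crossings[0] > crossings[1] > crossings[2]


class TestOverlap:
    def test_identical_maps_overlap_fully(self):
        vals = np.random.default_rng(0).uniform(0.5, 1.0, (6, 6))
        assert overlap_metric(vals, vals, eps=0.1) == 1.0

    def test_disjoint_supports_do_not_overlap(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[:2] = 1.0
        b[2:] = 1.0
        assert overlap_metric(a, b, eps=0.1) == 0.0

    def test_grid_mismatch_is_a_contract_error(self):
        with pytest.raises(ContractError):
            overlap_metric(np.ones((3, 3)), np.ones((4, 4)))
        with pytest.raises(ContractError):
            region_mismatch(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestDeviation:
    def test_map_compared_with_itself_is_zero(self):
        rm = response_map(load_preset("fig3_node", gamma1=100.0), resolution=9)
        dev = deviation_from_ideal(rm, rm)
        assert dev["max_abs_norm_diff"] == 0.0
        assert dev["region_mismatch_fraction"] == 0.0
        assert not dev["degenerate"]

    def test_zero_ideal_map_is_flagged_degenerate(self):
        net = _zero_weight_network()
        mech = response_map(load_preset("fig3_node", gamma1=100.0), resolution=5)
        ideal = ideal_response_map(net, resolution=5)
        dev = deviation_from_ideal(mech, ideal, node_id="node1", ideal_node_id="n1")
        assert dev["degenerate"]


class TestCompetitorEffects:
    """Amplitude scaling and onset stability under a constitutive competitor."""

    def test_competitor_scales_amplitude_but_not_onset(self):
        maps = {
            a2: response_map(
                load_preset("fig3_competition", gamma1=1000.0, alpha2=a2, beta2=0.5), resolution=21
            )
            for a2 in (0.0, 0.5, 1.0)
        }
        peaks = [maps[a2].node("node1").max() for a2 in (0.0, 0.5, 1.0)]
        assert peaks[0] >= peaks[1] >= peaks[2]
        base = extract_decision_boundary(maps[0.0], theta=0.05, node_id="node1").region
        for a2 in (0.5, 1.0):
            onset = extract_decision_boundary(maps[a2], theta=0.05, node_id="node1").region
            assert region_mismatch(base, onset) < 0.10

    def test_competitor_antisigma_restores_amplitude(self):
        peaks = [
            response_map(
                load_preset("fig3_competition", gamma1=1000.0, alpha2=1.0, beta2=b2), resolution=21
            )
            .node("node1")
            .max()
            for b2 in (0.0, 0.5, 1.0)
        ]
        assert peaks[0] <= peaks[1] <= peaks[2]


class TestArtifacts:
    def test_long_format_dataframe_shape_and_columns(self):
        rm = response_map(load_preset("fig4a_two_node"), resolution=5)
        df = map_to_dataframe(rm)
        assert list(df.columns) == ["x1", "x2", "node_id", "c_bar", "c_bar_norm"]
        assert len(df) == 5 * 5 * 2

    def test_written_artifacts_are_deterministic(self, tmp_path):
        rm = response_map(load_preset("fig3_node", gamma1=100.0), resolution=5)
        p1, m1 = write_map(rm, tmp_path / "a.csv")
        p2, m2 = write_map(rm, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()
        meta1 = m1.read_text().replace('"a.csv"', "").replace('"b.csv"', "")
        assert "network" in meta1 and "solver" in meta1
        back = pd.read_csv(p1)
        assert back["c_bar"].max() == pytest.approx(rm.node("node1").max(), rel=1e-9)
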