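"""Picard network solver: closed-form limits, oracle equivalence,
conservation, symmetry, calibration."""
import math

import numpy as np
import pytest

import cowflow as cf
from cowflow.solver import _class_flows
from cowflow.units import PA_PER_MMHG

from conftest import (brute_force_solve, random_small_network, single_tube)

# Independent unit-checked hand computation of 128*mu*L/(pi*d^4) with the
# composed Carreau viscosity at Q=2.5 ml/s, d=4 mm, L=10 mm.
R_10MM_4MM_2_5 = 0.04736086835952167  # mmHg/(ml/s)


class TestSegmentResistance:
    def test_hand_computed_value(self):
        seg = cf.Segment("s", "a", "b", length=10.0, diameter=4.0,
                         klass="circle")
        assert cf.segment_resistance(seg, 2.5, cf.CarreauParameters()) \
            == pytest.approx(R_10MM_4MM_2_5, rel=1e-12)

    def test_linear_in_length(self):
        p = cf.CarreauParameters()
        r1 = cf.segment_resistance(
            cf.Segment("s", "a", "b", 10.0, 3.0, "circle"), 1.0, p)
        r2 = cf.segment_resistance(
            cf.Segment("s", "a", "b", 20.0, 3.0, "circle"), 1.0, p)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_inverse_fourth_power_in_diameter_at_fixed_viscosity(self):
        newt = cf.CarreauParameters(mu_zero=0.004, mu_inf=0.004)
        r1 = cf.segment_resistance(
            cf.Segment("s", "a", "b", 10.0, 2.0, "circle"), 1.0, newt)
        r2 = cf.segment_resistance(
            cf.Segment("s", "a", "b", 10.0, 4.0, "circle"), 1.0, newt)
        assert r1 == pytest.approx(16.0 * r2, rel=1e-12)


class TestSingleTube:
    def test_newtonian_tube_matches_poiseuille_closed_form(self):
        topo, boundary = single_tube(length=100.0, diameter=3.0,
                                     p_in=90.0, p_out=50.0)
        newt = cf.CarreauParameters(mu_zero=0.004, mu_inf=0.004)
        sol = cf.solve_flows(topo, boundary, newt)
        r_si = 128.0 * 0.004 * 0.1 / (math.pi * 0.003 ** 4)
        q_closed = (40.0 * PA_PER_MMHG) / r_si * 1e6  # ml/s
        assert sol.converged
        assert sol.segment_flows["tube"] == pytest.approx(q_closed,
                                                          rel=1e-10)

    def test_carreau_tube_satisfies_own_resistance_law(self):
        topo, boundary = single_tube()
        sol = cf.solve_flows(topo, boundary)
        q = sol.segment_flows["tube"]
        r = cf.segment_resistance(topo.segments["tube"], q,
                                  cf.CarreauParameters())
        assert q * r == pytest.approx(40.0, rel=1e-7)


class TestOracleEquivalence:
    def test_randomized_networks_match_brute_force(self):
        """Picard fixed point equals a generic nonlinear root-find on the
        full residual system for 20+ random small networks."""
        rng = np.random.default_rng(2024)
        params = cf.CarreauParameters()
        checked = 0
        while checked < 25:
            topo, boundary = random_small_network(rng)
            sol = cf.solve_flows(topo, boundary, params)
            assert sol.converged
            _, oracle_flows = brute_force_solve(topo, boundary, params)
            scale = max(abs(q) for q in oracle_flows.values()) or 1.0
            for sid, q in oracle_flows.items():
                assert sol.segment_flows[sid] == pytest.approx(
                    q, abs=1e-6 * scale)
            checked += 1

    def test_asymmetric_four_node_network(self):
        rng = np.random.default_rng(7)
        topo, boundary = random_small_network(rng)
        params = cf.CarreauParameters()
        sol = cf.solve_flows(topo, boundary, params)
        pressures, flows = brute_force_solve(topo, boundary, params)
        for node, p in pressures.items():
            assert sol.node_pressures[node] == pytest.approx(p, abs=1e-6)


class TestConservationAndInvariance:
    def test_mass_conserved_at_internal_nodes(self, calibrated_topology,
                                              boundary_set):
        sol = cf.solve_flows(calibrated_topology, boundary_set)
        assert sol.converged
        total = sol.total_inflow(calibrated_topology)
        assert sol.max_mass_residual <= 1e-8 * total

    def test_inflow_equals_efferent_outflow(self, calibrated_topology,
                                            boundary_set):
        sol = cf.solve_flows(calibrated_topology, boundary_set)
        out = sum(sol.efferent_outflows(calibrated_topology).values())
        assert out == pytest.approx(sol.total_inflow(calibrated_topology),
                                    rel=1e-8)

    def test_solution_invariant_under_segment_reordering(
            self, calibrated_topology, boundary_set):
        reordered = cf.NetworkTopology(
            segments=dict(reversed(list(
                calibrated_topology.segments.items()))),
            inlet_nodes=calibrated_topology.inlet_nodes,
            outlet_nodes=dict(calibrated_topology.outlet_nodes),
            distal_resistance=dict(calibrated_topology.distal_resistance))
        a = cf.solve_flows(calibrated_topology, boundary_set)
        b = cf.solve_flows(reordered, boundary_set)
        for sid in a.segment_flows:
            assert b.segment_flows[sid] == pytest.approx(
                a.segment_flows[sid], rel=1e-9, abs=1e-12)

    def test_mirrored_topology_gives_mirrored_flows(self, boundary_set):
        def mirror_id(sid):
            if sid.startswith("R"):
                return "L" + sid[1:]
            if sid.startswith("L"):
                return "R" + sid[1:]
            return sid

        table = cf.synthetic_geometry(seed=3, jitter_fraction=0.1)
        mirrored = table.copy()
        mirrored["id"] = [mirror_id(s) for s in mirrored["id"]]
        params = cf.CarreauParameters()
        topo_a = cf.apply_stenosis(cf.build_complete_cow(table),
                                   cf.StenosisSpec("RICA", 75.0))
        topo_b = cf.apply_stenosis(cf.build_complete_cow(mirrored),
                                   cf.StenosisSpec("LICA", 75.0))
        sol_a = cf.solve_flows(topo_a, boundary_set, params)
        sol_b = cf.solve_flows(topo_b, boundary_set, params)
        # straight-through segments map directly; the ACoA (wired
        # left->right) flips sign under the mirror
        for sid in ("RICA", "LICA", "RMCA", "LMCA", "RPCoA", "LPCoA",
                    "RA1", "LA1", "RA2", "LA2"):
            assert sol_b.segment_flows[mirror_id(sid)] == pytest.approx(
                sol_a.segment_flows[sid], rel=1e-8, abs=1e-12)
        assert sol_b.segment_flows["ACoA"] == pytest.approx(
            -sol_a.segment_flows["ACoA"], rel=1e-8, abs=1e-12)


class TestDiagnosticsAndFailure:
    def test_non_convergence_reported_not_silent(self, calibrated_topology,
                                                 boundary_set):
        sol = cf.solve_flows(calibrated_topology, boundary_set,
                             settings=cf.SolverSettings(max_iterations=2))
        assert not sol.converged
        assert any("did not converge" in f for f in sol.flags)

    def test_disconnected_efferent_zero_flow_and_flagged(self, boundary_set):
        # LA1 absent + ACoA removed leaves the left A2 without any inlet
        topo = cf.apply_variant(cf.build_complete_cow(cf.nominal_geometry()),
                                cf.Variant.LA1_ABSENT)
        segments = {k: v for k, v in topo.segments.items() if k != "ACoA"}
        topo = cf.NetworkTopology(segments=segments,
                                  inlet_nodes=topo.inlet_nodes,
                                  outlet_nodes=dict(topo.outlet_nodes))
        assert topo.disconnected_efferents() == ["LA2_out"]
        sol = cf.solve_flows(topo, boundary_set)
        assert sol.converged
        assert sol.segment_flows["LA2"] == pytest.approx(0.0, abs=1e-12)
        assert sol.node_pressures["LA2_out"] == boundary_set.outlet_pressure_aca
        assert any("LA2_out" in f for f in sol.flags)

    def test_reynolds_zero_flow_and_linearity(self, calibrated_topology,
                                              boundary_set):
        sol = cf.solve_flows(calibrated_topology, boundary_set)
        numbers, warnings = cf.reynolds_check(sol, calibrated_topology)
        assert all(re >= 0 for re in numbers.values())
        assert not warnings  # physiological flows are well below 2100
        doubled = cf.FlowSolution(
            node_pressures=sol.node_pressures,
            segment_flows={k: 2 * v for k, v in sol.segment_flows.items()},
            converged=True, iterations=1, max_mass_residual=0.0)
        numbers2, _ = cf.reynolds_check(doubled, calibrated_topology)
        for sid in numbers:
            assert numbers2[sid] == pytest.approx(2 * numbers[sid], rel=1e-12)

    def test_reynolds_warning_path(self):
        topo, boundary = single_tube(length=10.0, diameter=0.5,
                                     p_in=300.0, p_out=10.0)
        newt = cf.CarreauParameters(mu_zero=0.0005, mu_inf=0.0005)
        sol = cf.solve_flows(topo, boundary, newt)
        _, warnings = cf.reynolds_check(sol, topo, newt)
        assert warnings and "tube" in warnings[0]


class TestCalibration:
    def test_recovers_total_cbf_and_split(self, calibrated_topology,
                                          boundary_set):
        sol = cf.solve_flows(calibrated_topology, boundary_set)
        flows = _class_flows(calibrated_topology, sol)
        total = sum(flows.values())
        assert abs(total - 12.5) <= 0.005 * 12.5
        for cls, frac in (("ACA", 0.22), ("MCA", 0.45), ("PCA", 0.33)):
            assert abs(flows[cls] / total - frac) <= 0.01

    def test_recalibration_is_near_identity(self, calibrated_topology,
                                            boundary_set):
        again = cf.calibrate(calibrated_topology, boundary_set)
        for cls, r in calibrated_topology.distal_resistance.items():
            assert again.distal_resistance[cls] == pytest.approx(
                r, rel=1e-3, abs=1e-6)

    def test_smaller_target_fraction_raises_distal_resistance(
            self, complete_topology, boundary_set, calibrated_topology):
        skew = cf.PerfusionConstants(fraction_aca=0.11, fraction_mca=0.56,
                                     fraction_pca=0.33)
        recal = cf.calibrate(complete_topology, boundary_set, targets=skew)
        assert recal.distal_resistance["ACA"] \
            > calibrated_topology.distal_resistance["ACA"]

    def test_unattainable_target_reported(self, complete_topology,
                                          boundary_set):
        greedy = cf.PerfusionConstants(total_cbf=1000.0)
        with pytest.raises(ValueError, match="unattainable"):
            cf.calibrate(complete_topology, boundary_set, targets=greedy)
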