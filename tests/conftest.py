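"""Shared fixtures and the independent brute-force network oracle.

The oracle solves the same steady-network equations as the package's
Picard solver — mass balance at internal nodes and Q·R(Q) = ΔP per
segment — but by a generic root-find on the full residual system, with
the Carreau/Poiseuille physics re-derived here from first principles
rather than imported, so the two routes share only the equations.
"""
from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.optimize

import cowflow as cf

MMHG_PA = 133.322387415


def oracle_resistance(length_mm, diameter_mm, flow_ml_s, params):
    """Poiseuille resistance with Carreau viscosity at the wall shear
    rate, written out independently (SI internally, mmHg/(ml/s) out)."""
    gamma = 32.0 * abs(flow_ml_s) * 1e-6 / (math.pi * (diameter_mm * 1e-3) ** 3)
    mu = params.mu_inf + (params.mu_zero - params.mu_inf) * (
        1.0 + (params.relaxation_time * gamma) ** 2
    ) ** ((params.power_index - 1.0) / 2.0)
    r_si = 128.0 * mu * (length_mm * 1e-3) / (math.pi * (diameter_mm * 1e-3) ** 4)
    return r_si * 1e-6 / MMHG_PA


def brute_force_solve(topology, boundary, params):
    """Root-find on [internal pressures, segment flows] residuals."""
    segs = list(topology.segments.values())
    fixed = {n: boundary.inlet_pressure for n in topology.inlet_nodes}
    for node, klass in topology.outlet_nodes.items():
        fixed[node] = boundary.outlet_pressure(klass)
    internal = [n for n in topology.nodes() if n not in fixed]

    def series_r(seg, q):
        r = oracle_resistance(seg.length, seg.diameter, q, params)
        if seg.klass == "efferent":
            outlet = (seg.to_node if seg.to_node in topology.outlet_nodes
                      else seg.from_node)
            r += topology.distal_resistance.get(
                topology.outlet_nodes[outlet], 0.0)
        return r

    def residual(x):
        p = dict(fixed)
        p.update(zip(internal, x[:len(internal)]))
        q = x[len(internal):]
        res = []
        for n in internal:
            bal = 0.0
            for i, s in enumerate(segs):
                if s.to_node == n:
                    bal += q[i]
                if s.from_node == n:
                    bal -= q[i]
            res.append(bal)
        for i, s in enumerate(segs):
            res.append(q[i] * series_r(s, q[i])
                       - (p[s.from_node] - p[s.to_node]))
        return res

    p0 = np.full(len(internal), np.mean(list(fixed.values())))
    q0 = np.full(len(segs), 0.1)
    sol = scipy.optimize.root(residual, np.concatenate([p0, q0]),
                              method="hybr", tol=1e-13)
    assert sol.success, sol.message
    pressures = dict(fixed)
    pressures.update(zip(internal, sol.x[:len(internal)]))
    flows = {s.identifier: sol.x[len(internal) + i]
             for i, s in enumerate(segs)}
    return pressures, flows


def random_small_network(rng: np.random.Generator):
    """A random connected network of <= 6 segments with 1-2 inlets and
    1-2 outlets, plausible dimensions, for oracle comparisons."""
    n_nodes = int(rng.integers(3, 7))
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n_nodes)]
    if n_nodes >= 4 and len(edges) < 6 and rng.random() < 0.5:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        edges.append((int(a), int(b)))
    n_in = 1 if n_nodes < 5 else int(rng.integers(1, 3))
    boundary_ids = list(rng.choice(n_nodes, size=n_in + 1, replace=False))
    inlets = tuple(nodes[i] for i in boundary_ids[:n_in])
    outlets = {nodes[i]: "MCA" for i in boundary_ids[n_in:]}
    segments = {}
    for k, (a, b) in enumerate(edges):
        sid = f"s{k}"
        segments[sid] = cf.Segment(
            identifier=sid, from_node=nodes[a], to_node=nodes[b],
            length=float(rng.uniform(5, 150)),
            diameter=float(rng.uniform(1.5, 5.0)), klass="circle")
    topo = cf.NetworkTopology(segments=segments, inlet_nodes=inlets,
                              outlet_nodes=outlets)
    boundary = cf.BoundarySet(
        inlet_pressure=float(rng.uniform(80, 100)),
        outlet_pressure_aca=46.0, outlet_pressure_mca=float(rng.uniform(40, 60)),
        outlet_pressure_pca=43.5, cvr_aca=1.0, cvr_mca=1.0, cvr_pca=1.0)
    return topo, boundary


def single_tube(length=100.0, diameter=3.0, p_in=90.0, p_out=50.0):
    """One segment between an inlet and an MCA-class outlet."""
    seg = cf.Segment(identifier="tube", from_node="a", to_node="b",
                     length=length, diameter=diameter, klass="efferent")
    topo = cf.NetworkTopology(segments={"tube": seg}, inlet_nodes=("a",),
                              outlet_nodes={"b": "MCA"})
    boundary = cf.BoundarySet(
        inlet_pressure=p_in, outlet_pressure_aca=p_out,
        outlet_pressure_mca=p_out, outlet_pressure_pca=p_out,
        cvr_aca=1.0, cvr_mca=1.0, cvr_pca=1.0)
    return topo, boundary


# ---------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------

@pytest.fixture(scope="session")
def boundary_set():
    return cf.build_boundary_set()


@pytest.fixture(scope="session")
def complete_topology():
    return cf.build_complete_cow(cf.nominal_geometry())


@pytest.fixture(scope="session")
def calibrated_topology(complete_topology, boundary_set):
    return cf.calibrate(complete_topology, boundary_set)


@pytest.fixture(scope="session")
def standard_sweep(calibrated_topology, boundary_set):
    return cf.run_sweep(calibrated_topology, boundary_set)
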