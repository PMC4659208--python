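"""Steady nonlinear flow solver for the vascular network.

Each segment is a quasi-steady Poiseuille element whose resistance
R(Q) = 128·mu_eff(Q, d)·L/(pi·d^4) depends on its own flow through the
Carreau viscosity evaluated at the wall shear rate.  Nodal pressures are
found by Picard (successive-substitution) iteration: assemble the linear
conductance system at the current viscosities, impose the fixed inlet
and outlet pressures, solve for the internal node pressures, recover the
segment flows, relax the viscosity update and repeat until the flows are
stationary.  Under-relaxation makes the fixed-point iteration robust for
monotone shear-thinning laws.

Calibration appends a constant (Newtonian) lumped resistance to every
efferent segment per territory class, chosen by monotone bisection so
that the complete unstenosed circle carries the target total cerebral
blood flow with the target ACA/MCA/PCA split.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .boundary import BoundarySet, PerfusionConstants
from .network import NetworkTopology, Segment
from .rheology import CarreauParameters, effective_viscosity
from .units import poiseuille_resistance_mmhg_ml_s

__all__ = [
    "SolverSettings",
    "FlowSolution",
    "segment_resistance",
    "solve_flows",
    "reynolds_check",
    "calibrate",
]

#: Laminar-turbulent transition threshold used by the Reynolds diagnostic.
REYNOLDS_LAMINAR_LIMIT = 2100.0

#: Blood density (kg/m^3) for the Reynolds diagnostic only.
BLOOD_DENSITY_KG_M3 = 1050.0


@dataclass(frozen=True)
class SolverSettings:
    """Picard iteration controls."""

    max_iterations: int = 200
    relative_tolerance: float = 1e-8
    under_relaxation: float = 0.5

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.relative_tolerance <= 0:
            raise ValueError("relative_tolerance must be positive")
        if not 0 < self.under_relaxation <= 1:
            raise ValueError("under_relaxation must lie in (0, 1]")


@dataclass(frozen=True)
class FlowSolution:
    """Converged nodal pressures and signed segment flows.

    Flows are positive from ``from_node`` to ``to_node`` of each segment.
    ``max_mass_residual`` is the largest net flow imbalance (ml/s) over
    internal nodes; ``flags`` collects structural/convergence warnings.
    """

    node_pressures: dict[str, float]
    segment_flows: dict[str, float]
    converged: bool
    iterations: int
    max_mass_residual: float
    flags: tuple[str, ...] = ()

    def total_inflow(self, topology: NetworkTopology) -> float:
        """Total flow entering at the inlet roots (ml/s)."""
        total = 0.0
        for seg in topology.segments.values():
            if seg.from_node in topology.inlet_nodes:
                total += self.segment_flows[seg.identifier]
            elif seg.to_node in topology.inlet_nodes:
                total -= self.segment_flows[seg.identifier]
        return total

    def efferent_outflows(self, topology: NetworkTopology) -> dict[str, float]:
        """Flow delivered by each efferent segment (ml/s, toward outlet)."""
        out = {}
        for seg in topology.segments.values():
            if seg.klass == "efferent":
                sign = 1.0 if seg.to_node in topology.outlet_nodes else -1.0
                out[seg.identifier] = sign * self.segment_flows[seg.identifier]
        return out

    def to_frame(self, topology: NetworkTopology) -> pd.DataFrame:
        rows = []
        for seg in topology.segments.values():
            q = self.segment_flows[seg.identifier]
            dp = (self.node_pressures[seg.from_node]
                  - self.node_pressures[seg.to_node])
            rows.append({"id": seg.identifier, "flow_ml_s": q,
                         "pressure_drop_mmHg": dp})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "node_pressures": self.node_pressures,
            "segment_flows": self.segment_flows,
            "converged": self.converged,
            "iterations": self.iterations,
            "max_mass_residual": self.max_mass_residual,
            "flags": list(self.flags),
        }, indent=2))


def segment_resistance(segment: Segment, flow_ml_s: float,
                       params: CarreauParameters) -> float:
    """Flow-dependent Poiseuille resistance of one segment, mmHg/(ml/s)."""
    mu = effective_viscosity(flow_ml_s, segment.diameter, params)
    return poiseuille_resistance_mmhg_ml_s(mu, segment.length, segment.diameter)


def _boundary_pressures(topology: NetworkTopology,
                        boundary: BoundarySet) -> dict[str, float]:
    fixed = {n: boundary.inlet_pressure for n in topology.inlet_nodes}
    for node, klass in topology.outlet_nodes.items():
        fixed[node] = boundary.outlet_pressure(klass)
    return fixed


def _series_resistance(topology: NetworkTopology, seg: Segment,
                       flow: float, params: CarreauParameters) -> float:
    """Segment resistance plus any calibrated distal element in series."""
    r = segment_resistance(seg, flow, params)
    if seg.klass == "efferent":
        outlet = (seg.to_node if seg.to_node in topology.outlet_nodes
                  else seg.from_node)
        r += topology.distal_resistance.get(topology.outlet_nodes[outlet], 0.0)
    return r


def solve_flows(topology: NetworkTopology, boundary: BoundarySet,
                params: CarreauParameters = CarreauParameters(),
                settings: SolverSettings = SolverSettings()) -> FlowSolution:
    """Solve the network by Picard iteration on the nodal system.

    Internal nodes satisfy mass conservation; inlet and outlet nodes are
    held at their boundary pressures.  Parts of the network with no path
    to any pressure-carrying node (possible after variant + occlusion)
    are flagged and reported with zero flow; efferents cut off from every
    inlet are flagged.  Non-convergence is reported via
    ``converged=False``, never silently.
    """
    segs = list(topology.segments.values())
    fixed = _boundary_pressures(topology, boundary)
    nodes = topology.nodes()

    # Components with no fixed-pressure node are indeterminate: flag and
    # exclude them from the linear system.
    g = nx.MultiGraph()
    g.add_nodes_from(nodes)
    for s in segs:
        g.add_edge(s.from_node, s.to_node, key=s.identifier)
    dead_nodes: set[str] = set()
    flags = list(topology.flags)
    for comp in nx.connected_components(g):
        if not comp & set(fixed):
            dead_nodes |= comp
            flags.append(f"component {sorted(comp)} has no boundary node; "
                         "flows set to zero")
    for eff in topology.disconnected_efferents():
        msg = f"efferent {eff} disconnected from all inlets"
        if msg not in flags:
            flags.append(msg)

    live_segs = [s for s in segs if s.from_node not in dead_nodes]
    unknown = [n for n in nodes
               if n not in fixed and n not in dead_nodes]
    index = {n: i for i, n in enumerate(unknown)}

    flows = {s.identifier: 0.0 for s in segs}
    relaxed = dict(flows)          # flows at which viscosity is evaluated
    iterations = 0
    converged = False
    pressures = dict(fixed)

    for iterations in range(1, settings.max_iterations + 1):
        conduct = {s.identifier:
                   1.0 / _series_resistance(topology, s,
                                            relaxed[s.identifier], params)
                   for s in live_segs}
        a = np.zeros((len(unknown), len(unknown)))
        b = np.zeros(len(unknown))
        for s in live_segs:
            gij = conduct[s.identifier]
            fi, ti = s.from_node, s.to_node
            for this, other in ((fi, ti), (ti, fi)):
                if this in index:
                    i = index[this]
                    a[i, i] += gij
                    if other in index:
                        a[i, index[other]] -= gij
                    else:
                        b[i] += gij * fixed.get(other, 0.0) \
                            if other in fixed else 0.0
        if unknown:
            p = np.linalg.solve(a, b)
        else:
            p = np.array([])
        pressures = dict(fixed)
        pressures.update({n: float(p[index[n]]) for n in unknown})
        for n in dead_nodes:
            pressures.setdefault(n, float("nan"))

        new_flows = dict(flows)
        for s in live_segs:
            dp = pressures[s.from_node] - pressures[s.to_node]
            new_flows[s.identifier] = conduct[s.identifier] * dp

        scale = max(max(abs(q) for q in new_flows.values()), 1e-12)
        change = max(abs(new_flows[k] - flows[k]) for k in flows) / scale
        flows = new_flows
        omega = settings.under_relaxation
        relaxed = {k: omega * flows[k] + (1 - omega) * relaxed[k]
                   for k in flows}
        if change < settings.relative_tolerance:
            converged = True
            break

    if not converged:
        flags.append(
            f"Picard iteration did not converge in "
            f"{settings.max_iterations} iterations (last change {change:.3e})")

    # Mass residual over internal nodes.
    imbalance: dict[str, float] = {n: 0.0 for n in unknown}
    for s in live_segs:
        q = flows[s.identifier]
        if s.from_node in imbalance:
            imbalance[s.from_node] -= q
        if s.to_node in imbalance:
            imbalance[s.to_node] += q
    max_residual = max((abs(v) for v in imbalance.values()), default=0.0)

    return FlowSolution(
        node_pressures=pressures, segment_flows=flows,
        converged=converged, iterations=iterations,
        max_mass_residual=max_residual, flags=tuple(flags))


def reynolds_check(solution: FlowSolution, topology: NetworkTopology,
                   params: CarreauParameters = CarreauParameters(),
                   blood_density: float = BLOOD_DENSITY_KG_M3,
                   ) -> tuple[dict[str, float], list[str]]:
    """Per-segment Reynolds numbers and laminar-assumption warnings.

    Re = 4*rho*Q/(pi*d*mu_inf), the most pessimistic (infinite-shear)
    viscosity; segments at or above the transition threshold are listed.
    """
    numbers: dict[str, float] = {}
    warnings: list[str] = []
    for seg in topology.segments.values():
        q_m3_s = abs(solution.segment_flows[seg.identifier]) * 1e-6
        d_m = seg.diameter * 1e-3
        re = 4.0 * blood_density * q_m3_s / (np.pi * d_m * params.mu_inf)
        numbers[seg.identifier] = re
        if re >= REYNOLDS_LAMINAR_LIMIT:
            warnings.append(
                f"{seg.identifier}: Re = {re:.0f} >= {REYNOLDS_LAMINAR_LIMIT:.0f}; "
                "laminar assumption questionable")
    return numbers, warnings


def _class_flows(topology: NetworkTopology, solution: FlowSolution
                 ) -> dict[str, float]:
    flows = {"ACA": 0.0, "MCA": 0.0, "PCA": 0.0}
    for sid, q in solution.efferent_outflows(topology).items():
        seg = topology.segments[sid]
        outlet = (seg.to_node if seg.to_node in topology.outlet_nodes
                  else seg.from_node)
        flows[topology.outlet_nodes[outlet]] += q
    return flows


def calibrate(topology: NetworkTopology, boundary: BoundarySet,
              params: CarreauParameters = CarreauParameters(),
              targets: PerfusionConstants = PerfusionConstants(),
              settings: SolverSettings = SolverSettings(),
              total_tolerance: float = 1e-3,
              fraction_tolerance: float = 2e-3) -> NetworkTopology:
    """Fit per-territory distal resistances to the perfusion targets.

    Cyclic coordinate bisection: for each territory class in turn, the
    appended distal resistance is bisected until that class carries its
    target share of the total CBF; the cycle repeats until the total and
    the split settle.  Class flow decreases monotonically in its own
    distal resistance, which guarantees the bisection brackets.  Raises
    ``ValueError`` when the targets are unattainable (bare network cannot
    deliver the requested flow even with zero distal resistance).
    """
    class_targets = {
        "ACA": targets.fraction_aca * targets.total_cbf,
        "MCA": targets.fraction_mca * targets.total_cbf,
        "PCA": targets.fraction_pca * targets.total_cbf,
    }
    r = dict(topology.distal_resistance)

    def flows_with(r_map: dict[str, float]) -> dict[str, float]:
        sol = solve_flows(topology.with_distal_resistance(r_map),
                          boundary, params, settings)
        if not sol.converged:
            raise RuntimeError("solver failed to converge during calibration")
        return _class_flows(topology, sol)

    base = flows_with({k: 0.0 for k in r})
    for cls, tgt in class_targets.items():
        if base[cls] < tgt:
            raise ValueError(
                f"target {cls} flow {tgt:.3f} ml/s unattainable: the bare "
                f"network delivers only {base[cls]:.3f} ml/s")

    r_hi = 1e4
    for _ in range(60):
        previous = dict(r)
        for cls, tgt in class_targets.items():
            lo, hi = 0.0, r_hi
            for _ in range(80):
                midr = 0.5 * (lo + hi)
                r[cls] = midr
                if flows_with(r)[cls] > tgt:
                    lo = midr
                else:
                    hi = midr
                if hi - lo < 1e-10 * max(1.0, hi):
                    break
            r[cls] = 0.5 * (lo + hi)
        achieved = flows_with(r)
        total = sum(achieved.values())
        frac_err = max(abs(achieved[c] / total - class_targets[c]
                           / targets.total_cbf) for c in achieved)
        r_change = max(abs(r[c] - previous[c]) / max(r[c], 1e-12) for c in r)
        if (abs(total - targets.total_cbf) <= total_tolerance * targets.total_cbf
                and frac_err <= fraction_tolerance and r_change < 1e-7):
            break
    return topology.with_distal_resistance(r)
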