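"""The stenosis-by-variant experiment grid and its derived reporting.

The study design crosses six anatomical configurations of the circle
(complete plus five single-segment absences) with six NASCET stenosis
degrees of the right internal carotid (0/25/50/75/90/100 %).  Derived
quantities follow the reporting conventions of the original study:

* total cerebral flow per cell and its percentage change against the
  reference cell (complete circle, no stenosis);
* signed communicating-artery flows — ACoA positive toward the right
  hemisphere, each PCoA positive toward the anterior circulation;
* the "turning point": the stenosis degree at which a communicating
  artery's flow changes direction, located by linear interpolation
  between grid samples;
* the ranking of configurations by total flow at a given degree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from importlib import resources

import numpy as np
import pandas as pd

from .boundary import BoundarySet
from .network import (NetworkTopology, StenosisSpec, Variant, apply_stenosis,
                      apply_variant)
from .rheology import CarreauParameters
from .solver import FlowSolution, SolverSettings, solve_flows

__all__ = [
    "STANDARD_DEGREES",
    "CellResult",
    "SweepResult",
    "run_sweep",
    "percentage_change_table",
    "communicating_flows",
    "find_reversal_point",
    "rank_configurations",
    "published_total_flows",
]

#: The stenosis grid of the study design (percent diameter reduction).
STANDARD_DEGREES: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 90.0, 100.0)


@dataclass(frozen=True)
class CellResult:
    """Summary of one (variant, degree) cell."""

    variant: Variant
    degree: float
    total_flow: float                       # ml/s, summed efferent outflow
    efferent_flows: dict[str, float]        # ml/s toward each outlet
    acoa_flow: float | None                 # ml/s, positive toward right
    rpcoa_flow: float | None                # ml/s, positive toward anterior
    lpcoa_flow: float | None
    converged: bool
    solution: FlowSolution

    def communicating(self) -> dict[str, float | None]:
        return {"ACoA": self.acoa_flow, "RPCoA": self.rpcoa_flow,
                "LPCoA": self.lpcoa_flow}


@dataclass(frozen=True)
class SweepResult:
    """Grid of solved cells keyed by (variant, degree)."""

    cells: dict[tuple[Variant, float], CellResult]
    variants: tuple[Variant, ...]
    degrees: tuple[float, ...]
    failures: tuple[str, ...] = ()

    def cell(self, variant: Variant | str, degree: float) -> CellResult:
        return self.cells[(Variant(variant), float(degree))]

    def total_flow_table(self) -> pd.DataFrame:
        """Totals (ml/s), degrees as rows and variants as columns."""
        data = {v.value: [self.cells[(v, d)].total_flow for d in self.degrees]
                for v in self.variants}
        return pd.DataFrame(data, index=pd.Index(self.degrees, name="degree"))

    def communicating_table(self, segment: str) -> pd.DataFrame:
        """Signed flow of one communicating artery across the grid."""
        data = {}
        for v in self.variants:
            data[v.value] = [self.cells[(v, d)].communicating()[segment]
                             for d in self.degrees]
        return pd.DataFrame(data, index=pd.Index(self.degrees, name="degree"))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (v, d), cell in self.cells.items():
            rows.append({"variant": v.value, "degree": d,
                         "quantity": "total_flow", "value": cell.total_flow})
            for sid, q in cell.efferent_flows.items():
                rows.append({"variant": v.value, "degree": d,
                             "quantity": f"flow_{sid}", "value": q})
            for name, q in cell.communicating().items():
                rows.append({"variant": v.value, "degree": d,
                             "quantity": f"flow_{name}",
                             "value": np.nan if q is None else q})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def communicating_flows(solution: FlowSolution, topology: NetworkTopology
                        ) -> dict[str, float | None]:
    """Signed communicating-artery flows in the reporting convention.

    The graph orientation already encodes the convention (ACoA wired
    left->right, PCoAs wired posterior->anterior), so the signed segment
    flow is reported directly; absent segments give ``None`` rather than
    zero.
    """
    out: dict[str, float | None] = {}
    for sid in ("ACoA", "RPCoA", "LPCoA"):
        out[sid] = (solution.segment_flows[sid]
                    if sid in topology.segments else None)
    return out


def _solve_cell(topology: NetworkTopology, variant: Variant, degree: float,
                boundary: BoundarySet, params: CarreauParameters,
                settings: SolverSettings, stenosis_target: str,
                stenotic_length: float) -> CellResult:
    cell_topo = apply_variant(topology, variant)
    cell_topo = apply_stenosis(cell_topo, StenosisSpec(
        target_segment=stenosis_target, degree=degree,
        stenotic_length=stenotic_length))
    sol = solve_flows(cell_topo, boundary, params, settings)
    eff = sol.efferent_outflows(cell_topo)
    comm = communicating_flows(sol, cell_topo)
    return CellResult(
        variant=variant, degree=degree, total_flow=sum(eff.values()),
        efferent_flows=eff, acoa_flow=comm["ACoA"],
        rpcoa_flow=comm["RPCoA"], lpcoa_flow=comm["LPCoA"],
        converged=sol.converged, solution=sol)


def run_sweep(topology: NetworkTopology, boundary: BoundarySet,
              params: CarreauParameters = CarreauParameters(),
              variants: tuple[Variant, ...] = tuple(Variant),
              degrees: tuple[float, ...] = STANDARD_DEGREES,
              settings: SolverSettings = SolverSettings(),
              stenosis_target: str = "RICA",
              stenotic_length: float = 10.0) -> SweepResult:
    """Solve every (variant, degree) cell of the grid.

    ``topology`` should be the calibrated complete circle.  Solver
    failures in individual cells are collected in ``failures`` and the
    run continues; results are deterministic given the inputs.
    """
    variants = tuple(Variant(v) for v in variants)
    degrees = tuple(float(d) for d in degrees)
    cells: dict[tuple[Variant, float], CellResult] = {}
    failures: list[str] = []
    for v in variants:
        for d in degrees:
            cell = _solve_cell(topology, v, d, boundary, params, settings,
                               stenosis_target, stenotic_length)
            cells[(v, d)] = cell
            if not cell.converged:
                failures.append(f"({v.value}, {d}%) did not converge")
    return SweepResult(cells=cells, variants=variants, degrees=degrees,
                       failures=tuple(failures))


def percentage_change_table(flow_table: pd.DataFrame,
                            reference: float | None = None) -> pd.DataFrame:
    """Percentage change of total flow against the reference cell.

    ``flow_table`` has degrees as rows and configurations as columns; the
    reference defaults to the (COMPLETE, 0 %) entry.  Entries are
    100·(Q − Qref)/Qref rounded to two decimals.
    """
    if reference is None:
        if "COMPLETE" not in flow_table.columns or 0.0 not in [
                float(i) for i in flow_table.index]:
            raise ValueError(
                "reference cell (COMPLETE, 0) absent; pass `reference`")
        ref_idx = [i for i in flow_table.index if float(i) == 0.0][0]
        reference = float(flow_table.at[ref_idx, "COMPLETE"])
    if not reference > 0:
        raise ValueError("reference total flow must be positive")
    return (100.0 * (flow_table - reference) / reference).round(2)


def find_reversal_point(degrees: np.ndarray | list[float],
                        flows: np.ndarray | list[float]) -> float | None:
    """Stenosis degree at which a signed flow series changes direction.

    Linear interpolation between the last sample of the initial sign and
    the first of the opposite sign; an exactly zero sample is itself the
    turning point.  Returns ``None`` for a series that never changes
    sign.  Degrees must be increasing; at least two samples required.
    """
    d = np.asarray(degrees, dtype=float)
    q = np.asarray(flows, dtype=float)
    if d.size != q.size or d.size < 2:
        raise ValueError("need >= 2 (degree, flow) samples")
    if np.any(np.diff(d) <= 0):
        raise ValueError("degrees must be strictly increasing")
    sign0 = np.sign(q[0])
    for i in range(q.size):
        s = np.sign(q[i])
        if s == 0.0:
            return float(d[i])
        if sign0 == 0.0:
            sign0 = s
            continue
        if s != sign0:
            d0, d1, q0, q1 = d[i - 1], d[i], q[i - 1], q[i]
            return float(d0 + (d1 - d0) * q0 / (q0 - q1))
    return None


def rank_configurations(sweep: SweepResult, degree: float) -> list[Variant]:
    """Variants ordered by descending total flow at one stenosis degree,
    ties broken alphabetically by variant name."""
    degree = float(degree)
    if degree not in sweep.degrees:
        raise ValueError(f"degree {degree} not sampled in the sweep")
    return sorted(sweep.variants,
                  key=lambda v: (-sweep.cells[(v, degree)].total_flow, v.value))


def published_total_flows() -> pd.DataFrame:
    """The packaged fixture of published total flow rates (ml/s) of the
    original imaging study, degrees as rows and configurations as
    columns — the input of the percentage-change reproduction."""
    with resources.files("cowflow.data").joinpath(
            "table1_total_flows.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    return table.set_index("degree").rename(index=float)
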