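"""The circle of Willis as a resistive network.

The circle is represented as a graph of cylindrical segments between
pressure nodes: three afferent roots (two internal carotids and the
merged vertebral supply), the ring itself (A1, P1, communicating
arteries, basilar), and six efferent outlets (paired MCA, A2, P2).
Anatomical variants remove one named ring segment; carotid stenosis is
imposed on the RICA by the NASCET diameter-reduction rule

    S = (1 - d_s / d_n) * 100 %.

The patient geometry behind the original imaging study is not published,
so a synthetic nominal dimension table (literature-plausible 1D-model
values, left–right symmetric) ships with the package and can be jittered
reproducibly to emulate anatomical variability.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "Variant",
    "VariantSpec",
    "StenosisSpec",
    "NetworkTopology",
    "CANONICAL_SEGMENTS",
    "build_complete_cow",
    "apply_variant",
    "stenosis_degree",
    "apply_stenosis",
    "synthetic_geometry",
    "nominal_geometry",
    "load_dimension_table",
]

# Wiring of the complete circle: id -> (from_node, to_node, klass).
# Orientation fixes the sign convention of reported flows: the ACoA runs
# left->right (positive flow feeds the right hemisphere) and each PCoA
# runs posterior->anterior (positive flow feeds the anterior circulation).
_WIRING: dict[str, tuple[str, str, str]] = {
    "RICA":  ("RICA_root", "RICA_end", "inlet"),
    "LICA":  ("LICA_root", "LICA_end", "inlet"),
    "RVA":   ("VA_root", "VB_conf", "inlet"),
    "LVA":   ("VA_root", "VB_conf", "inlet"),
    "BA":    ("VB_conf", "BA_top", "circle"),
    "RA1":   ("RICA_end", "RACA_jn", "circle"),
    "LA1":   ("LICA_end", "LACA_jn", "circle"),
    "ACoA":  ("LACA_jn", "RACA_jn", "circle"),
    "RP1":   ("BA_top", "RPOST_jn", "circle"),
    "LP1":   ("BA_top", "LPOST_jn", "circle"),
    "RPCoA": ("RPOST_jn", "RICA_end", "circle"),
    "LPCoA": ("LPOST_jn", "LICA_end", "circle"),
    "RMCA":  ("RICA_end", "RMCA_out", "efferent"),
    "LMCA":  ("LICA_end", "LMCA_out", "efferent"),
    "RA2":   ("RACA_jn", "RA2_out", "efferent"),
    "LA2":   ("LACA_jn", "LA2_out", "efferent"),
    "RP2":   ("RPOST_jn", "RP2_out", "efferent"),
    "LP2":   ("LPOST_jn", "LP2_out", "efferent"),
}

CANONICAL_SEGMENTS: tuple[str, ...] = tuple(_WIRING)

_INLET_NODES: tuple[str, ...] = ("RICA_root", "LICA_root", "VA_root")

# Efferent outlet node -> territory class carrying the outlet pressure.
_OUTLET_CLASS: dict[str, str] = {
    "RMCA_out": "MCA", "LMCA_out": "MCA",
    "RA2_out": "ACA", "LA2_out": "ACA",
    "RP2_out": "PCA", "LP2_out": "PCA",
}


@dataclass(frozen=True)
class Segment:
    """A cylindrical resistive element between two pressure nodes."""

    identifier: str
    from_node: str
    to_node: str
    length: float      # mm
    diameter: float    # mm
    klass: str         # inlet | circle | efferent

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.identifier}: length must be positive")
        if self.diameter <= 0:
            raise ValueError(f"{self.identifier}: diameter must be positive")
        if self.klass not in ("inlet", "circle", "efferent"):
            raise ValueError(f"{self.identifier}: unknown klass {self.klass!r}")


class Variant(str, Enum):
    """The anatomical configurations studied: the complete circle and the
    five common single-segment absences."""

    COMPLETE = "COMPLETE"
    ACOA_ABSENT = "ACOA_ABSENT"
    RA1_ABSENT = "RA1_ABSENT"
    LA1_ABSENT = "LA1_ABSENT"
    RPCOA_ABSENT = "RPCOA_ABSENT"
    LPCOA_ABSENT = "LPCOA_ABSENT"

    @property
    def removed_segment(self) -> str | None:
        return None if self is Variant.COMPLETE else {
            Variant.ACOA_ABSENT: "ACoA",
            Variant.RA1_ABSENT: "RA1",
            Variant.LA1_ABSENT: "LA1",
            Variant.RPCOA_ABSENT: "RPCoA",
            Variant.LPCOA_ABSENT: "LPCoA",
        }[self]


#: Alias matching the domain vocabulary: a variant spec is just the enum.
VariantSpec = Variant


@dataclass(frozen=True)
class StenosisSpec:
    """NASCET stenosis of one segment (default: right internal carotid).

    ``degree`` is percent diameter reduction in [0, 100];
    ``stenotic_length`` is the axial extent of the narrowed throat (mm),
    which must be shorter than the target segment.
    """

    target_segment: str = "RICA"
    degree: float = 0.0
    stenotic_length: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degree <= 100.0:
            raise ValueError(
                f"stenosis degree must lie in [0, 100], got {self.degree}")
        if self.stenotic_length <= 0:
            raise ValueError("stenotic length must be positive")


@dataclass(frozen=True)
class NetworkTopology:
    """An immutable vascular network.

    ``segments`` maps identifier to :class:`Segment`; ``inlet_nodes`` are
    the boundary nodes held at the inlet (perfusion) pressure and
    ``outlet_nodes`` maps each efferent boundary node to its territory
    class.  ``distal_resistance`` holds per-class lumped resistances
    (mmHg/(ml/s)) appended in series to the efferent segments by
    calibration; zero until calibrated.  ``flags`` records structural
    warnings (e.g. efferents cut off from every inlet).
    """

    segments: dict[str, Segment]
    inlet_nodes: tuple[str, ...] = _INLET_NODES
    outlet_nodes: dict[str, str] = field(
        default_factory=lambda: dict(_OUTLET_CLASS))
    distal_resistance: dict[str, float] = field(
        default_factory=lambda: {"ACA": 0.0, "MCA": 0.0, "PCA": 0.0})
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen_pairs: set[str] = set()
        for sid, seg in self.segments.items():
            if sid != seg.identifier:
                raise ValueError(f"segment key {sid!r} != id {seg.identifier!r}")
            if sid in seen_pairs:
                raise ValueError(f"duplicate segment identifier {sid}")
            seen_pairs.add(sid)

    # -- graph views ---------------------------------------------------
    def graph(self) -> nx.MultiGraph:
        """Undirected multigraph view (parallel vertebral arteries kept)."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes())
        for seg in self.segments.values():
            g.add_edge(seg.from_node, seg.to_node, key=seg.identifier)
        return g

    def nodes(self) -> list[str]:
        ns: set[str] = set(self.inlet_nodes) | set(self.outlet_nodes)
        for seg in self.segments.values():
            ns.update((seg.from_node, seg.to_node))
        return sorted(ns)

    def internal_nodes(self) -> list[str]:
        fixed = set(self.inlet_nodes) | set(self.outlet_nodes)
        return [n for n in self.nodes() if n not in fixed]

    def disconnected_efferents(self) -> list[str]:
        """Outlet nodes with no path to any inlet node."""
        g = self.graph()
        reachable: set[str] = set()
        for root in self.inlet_nodes:
            if root in g:
                reachable |= nx.node_connected_component(g, root)
        return sorted(n for n in self.outlet_nodes if n not in reachable)

    def with_distal_resistance(self, r: dict[str, float]) -> "NetworkTopology":
        return replace(self, distal_resistance=dict(r))

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "id": s.identifier, "from": s.from_node, "to": s.to_node,
            "length_mm": s.length, "diameter_mm": s.diameter, "klass": s.klass,
        } for s in self.segments.values()]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "segments": self.to_frame().to_dict(orient="records"),
            "inlet_nodes": list(self.inlet_nodes),
            "outlet_nodes": dict(self.outlet_nodes),
            "distal_resistance": dict(self.distal_resistance),
            "flags": list(self.flags),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------

def build_complete_cow(dimensions: pd.DataFrame) -> NetworkTopology:
    """Wire the complete 18-segment circle from a dimension table.

    ``dimensions`` needs columns ``id``, ``length_mm``, ``diameter_mm``
    covering every canonical segment; extra rows are rejected.
    """
    table = dimensions.set_index("id")
    missing = [s for s in CANONICAL_SEGMENTS if s not in table.index]
    if missing:
        raise ValueError(f"dimension table missing segments: {missing}")
    extra = [s for s in table.index if s not in CANONICAL_SEGMENTS]
    if extra:
        raise ValueError(f"dimension table has unknown segments: {extra}")
    segments = {}
    for sid in CANONICAL_SEGMENTS:
        frm, to, klass = _WIRING[sid]
        segments[sid] = Segment(
            identifier=sid, from_node=frm, to_node=to,
            length=float(table.at[sid, "length_mm"]),
            diameter=float(table.at[sid, "diameter_mm"]),
            klass=klass)
    return NetworkTopology(segments=segments)


def apply_variant(topology: NetworkTopology, spec: Variant) -> NetworkTopology:
    """Remove the variant's absent segment (identity for COMPLETE).

    If the removal cuts an efferent off from every inlet the topology is
    returned flagged, not rejected — the solver then reports zero flow
    there.
    """
    removed = Variant(spec).removed_segment
    if removed is None:
        return topology
    if removed not in topology.segments:
        raise ValueError(f"segment {removed} not present in topology")
    segments = {k: v for k, v in topology.segments.items() if k != removed}
    out = replace(topology, segments=segments)
    cut = out.disconnected_efferents()
    if cut:
        out = replace(out, flags=topology.flags + tuple(
            f"efferent {n} disconnected from all inlets" for n in cut))
    return out


def stenosis_degree(narrow_diameter: float, normal_diameter: float) -> float:
    """NASCET degree S = (1 - d_s/d_n) * 100, in percent."""
    if normal_diameter <= 0:
        raise ValueError("normal diameter must be positive")
    if narrow_diameter < 0 or narrow_diameter > normal_diameter:
        raise ValueError(
            f"narrow diameter must lie in [0, {normal_diameter}], "
            f"got {narrow_diameter}")
    return (1.0 - narrow_diameter / normal_diameter) * 100.0


def apply_stenosis(topology: NetworkTopology,
                   spec: StenosisSpec) -> NetworkTopology:
    """Impose a NASCET stenosis on the target segment.

    Degrees strictly between 0 and 100 split the segment in series into a
    healthy remainder and a narrowed throat of ``stenotic_length`` with
    diameter d_n*(1 - S/100); 100 % removes the segment entirely
    (occlusion); 0 % is the identity.
    """
    if spec.target_segment not in topology.segments:
        raise ValueError(f"segment {spec.target_segment} not in topology")
    if spec.target_segment.endswith("_sten"):
        raise ValueError("segment is already stenosed")
    target = topology.segments[spec.target_segment]
    if spec.degree == 0.0:
        return topology
    segments = {k: v for k, v in topology.segments.items()
                if k != spec.target_segment}
    if spec.degree == 100.0:
        out = replace(topology, segments=segments)
        cut = out.disconnected_efferents()
        if cut:
            out = replace(out, flags=topology.flags + tuple(
                f"efferent {n} disconnected from all inlets" for n in cut))
        return out
    if spec.stenotic_length >= target.length:
        raise ValueError(
            f"stenotic length {spec.stenotic_length} mm must be shorter than "
            f"the {target.identifier} ({target.length} mm)")
    mid = f"{target.identifier}_sten_jn"
    throat = f"{target.identifier}_sten"
    segments[throat] = Segment(
        identifier=throat, from_node=target.from_node, to_node=mid,
        length=spec.stenotic_length,
        diameter=target.diameter * (1.0 - spec.degree / 100.0),
        klass=target.klass)
    segments[target.identifier] = Segment(
        identifier=target.identifier, from_node=mid, to_node=target.to_node,
        length=target.length - spec.stenotic_length,
        diameter=target.diameter, klass=target.klass)
    return replace(topology, segments=segments)


# ---------------------------------------------------------------------
# Synthetic geometry
# ---------------------------------------------------------------------

def nominal_geometry() -> pd.DataFrame:
    """The packaged nominal dimension table (synthetic, left-right
    symmetric, literature-plausible 1D-model values; the original
    patient's CT geometry is not published)."""
    with resources.files("cowflow.data").joinpath(
            "nominal_geometry.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def synthetic_geometry(seed: int, jitter_fraction: float = 0.0) -> pd.DataFrame:
    """Nominal dimensions with seeded multiplicative jitter.

    Every length and diameter is scaled by an independent factor drawn
    uniformly from [1 - jitter, 1 + jitter]; jitter 0 returns the exact
    (symmetric) nominal table, and identical seeds give identical tables.
    """
    if not 0.0 <= jitter_fraction < 0.3:
        raise ValueError(
            f"jitter fraction must lie in [0, 0.3), got {jitter_fraction}")
    table = nominal_geometry()
    if jitter_fraction > 0.0:
        rng = np.random.default_rng(seed)
        n = len(table)
        table["length_mm"] *= rng.uniform(
            1 - jitter_fraction, 1 + jitter_fraction, size=n)
        table["diameter_mm"] *= rng.uniform(
            1 - jitter_fraction, 1 + jitter_fraction, size=n)
    return table


def load_dimension_table(path: str | Path) -> pd.DataFrame:
    """Read a dimension table (CSV with id,length_mm,diameter_mm)."""
    table = pd.read_csv(path)
    required = {"id", "length_mm", "diameter_mm"}
    if not required <= set(table.columns):
        raise ValueError(
            f"dimension table must have columns {sorted(required)}")
    return table
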