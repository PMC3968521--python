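"""Synthetic circle-of-Willis vascular network: generation, geometry queries, I/O.

The network is an idealized tube model: each vessel segment is a constant-radius
tube swept along a centerline polyline, segments meet at named nodes, and the
whole graph carries three feeding inlets (L_ICA, R_ICA, BA) and 21 named
terminal outlets grouped into perfusion territories (left/right MCA, ACA,
posterior = basilar branches + PCAs).  Coordinates are millimetres in a
right-handed frame: +x right, +y anterior, +z superior.

The generator stands in for a patient-specific MRI-derived geometry that is not
available: it preserves the topology of a complete circle of Willis (both
posterior communicating arteries and an anterior communicating artery), the
left/right asymmetries that drive embolus-routing results (a slightly larger
right ICA, six right vs four left MCA outlets, a T-shaped left and Y-shaped
right carotid termination), and vessel calibres in the 1-4 mm range typical of
the major cerebral arteries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Territory",
    "Role",
    "NodeKind",
    "point3",
    "VesselSegment",
    "NetworkNode",
    "VascularNetwork",
    "CoWVariantSpec",
    "NetworkError",
    "SchemaError",
    "generate_cow",
    "extend_inlets",
    "calibrate_terminals",
    "CalibrationResult",
    "route_length",
    "locate",
    "LocatedPoint",
    "write_network",
    "read_network",
    "write_vtk",
    "OUTLET_LABELS",
]

SCHEMA_VERSION = "1"

#: The 21 terminal outlet labels of the default network, grouped as in the
#: flow-division accounting tables.
OUTLET_LABELS: tuple[str, ...] = (
    "R_MCA_O1", "R_MCA_O2", "R_MCA_O3", "R_MCA_O4", "R_MCA_O5", "R_MCA_O6",
    "L_MCA_O1", "L_MCA_O2", "L_MCA_O3", "L_MCA_O4",
    "ACA_O1", "ACA_O2", "ACA_O3", "ACA_O4", "ACA_O5", "ACA_O6",
    "BAS_O1", "BAS_O2",
    "L_PCA_O", "R_PCA_O1", "R_PCA_O2",
)

INLET_LABELS: tuple[str, ...] = ("L_ICA", "R_ICA", "BA")


class NetworkError(ValueError):
    """A vascular network violates a structural invariant."""


class SchemaError(NetworkError):
    """A network file does not conform to the JSON schema."""


class Territory(str, Enum):
    MCA_R = "MCA_R"
    MCA_L = "MCA_L"
    ACA = "ACA"
    POSTERIOR = "POSTERIOR"
    FEEDING = "FEEDING"
    COMMUNICATING = "COMMUNICATING"


class Role(str, Enum):
    INLET = "inlet"
    INTERNAL = "internal"
    TERMINAL = "terminal"


class NodeKind(str, Enum):
    INLET = "inlet"
    JUNCTION = "junction"
    OUTLET = "outlet"


def point3(x: float, y: float, z: float) -> np.ndarray:
    """A 3-D point in millimetres as a float64 array; components must be finite."""
    p = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(p)):
        raise NetworkError(f"non-finite point components: {p!r}")
    return p


def _as_points(pts: Sequence[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise NetworkError("centerline must be an (n, 3) array of points")
    if not np.all(np.isfinite(arr)):
        raise NetworkError("centerline contains non-finite coordinates")
    return arr


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline, in the units of its coordinates."""
    diffs = np.diff(np.asarray(points, dtype=float), axis=0)
    return float(np.sum(np.linalg.norm(diffs, axis=1)))


@dataclass
class VesselSegment:
    """One vessel: a constant-radius tube along a centerline polyline (mm)."""

    id: str
    centerline: np.ndarray  # (n, 3) mm
    radius_mm: float
    proximal_node: str
    distal_node: str
    territory: Territory
    role: Role

    def __post_init__(self) -> None:
        self.centerline = _as_points(self.centerline)
        self.territory = Territory(self.territory)
        self.role = Role(self.role)
        if len(self.centerline) < 2:
            raise NetworkError(f"segment {self.id!r}: centerline needs >= 2 points")
        steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(steps <= 0.0):
            raise NetworkError(f"segment {self.id!r}: consecutive centerline points coincide")
        if not self.radius_mm > 0.0:
            raise NetworkError(f"segment {self.id!r}: radius must be positive")

    @property
    def length_mm(self) -> float:
        return polyline_length(self.centerline)

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm

    def copy(self) -> "VesselSegment":
        return VesselSegment(
            id=self.id,
            centerline=self.centerline.copy(),
            radius_mm=self.radius_mm,
            proximal_node=self.proximal_node,
            distal_node=self.distal_node,
            territory=self.territory,
            role=self.role,
        )


@dataclass
class NetworkNode:
    id: str
    position: np.ndarray  # mm
    kind: NodeKind

    def __post_init__(self) -> None:
        self.position = point3(*np.asarray(self.position, dtype=float))
        self.kind = NodeKind(self.kind)

    def copy(self) -> "NetworkNode":
        return NetworkNode(self.id, self.position.copy(), self.kind)


_ENDPOINT_TOL_MM = 1e-9


@dataclass
class VascularNetwork:
    """A connected tube network with named inlets and outlets."""

    nodes: list[NetworkNode]
    segments: list[VesselSegment]
    name: str = "network"

    def __post_init__(self) -> None:
        self._node_map = {n.id: n for n in self.nodes}
        self._seg_map = {s.id: s for s in self.segments}

    # -- lookups ----------------------------------------------------------
    def node(self, node_id: str) -> NetworkNode:
        try:
            return self._node_map[node_id]
        except KeyError:
            raise NetworkError(f"unknown node id {node_id!r}") from None

    def segment(self, seg_id: str) -> VesselSegment:
        try:
            return self._seg_map[seg_id]
        except KeyError:
            raise NetworkError(f"unknown segment id {seg_id!r}") from None

    def has_segment(self, seg_id: str) -> bool:
        return seg_id in self._seg_map

    @property
    def inlet_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.role is Role.INLET]

    @property
    def terminal_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.role is Role.TERMINAL]

    def outlet_ids(self) -> list[str]:
        return [s.id for s in self.terminal_segments]

    def inlet_ids(self) -> list[str]:
        return [s.id for s in self.inlet_segments]

    def outlet_node_of(self, seg_id: str) -> str:
        """The outlet node at the far end of a terminal segment."""
        seg = self.segment(seg_id)
        if seg.role is not Role.TERMINAL:
            raise NetworkError(f"segment {seg_id!r} is not terminal")
        return seg.distal_node

    def inlet_node_of(self, seg_id: str) -> str:
        seg = self.segment(seg_id)
        if seg.role is not Role.INLET:
            raise NetworkError(f"segment {seg_id!r} is not an inlet")
        return seg.proximal_node

    # -- graph view -------------------------------------------------------
    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind)
        for s in self.segments:
            g.add_edge(s.proximal_node, s.distal_node, key=s.id, length=s.length_mm)
        return g

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len({s.id for s in self.segments}) != len(self.segments):
            raise NetworkError("segment ids are not unique")
        if len({n.id for n in self.nodes}) != len(self.nodes):
            raise NetworkError("node ids are not unique")
        degree: dict[str, int] = {n.id: 0 for n in self.nodes}
        for s in self.segments:
            for node_id, end in ((s.proximal_node, s.centerline[0]), (s.distal_node, s.centerline[-1])):
                node = self.node(node_id)
                if np.linalg.norm(node.position - end) > _ENDPOINT_TOL_MM:
                    raise NetworkError(
                        f"segment {s.id!r} endpoint does not coincide with node {node_id!r}"
                    )
                degree[node_id] += 1
        for n in self.nodes:
            if n.kind in (NodeKind.INLET, NodeKind.OUTLET) and degree[n.id] != 1:
                raise NetworkError(f"{n.kind.value} node {n.id!r} must attach to exactly one segment")
            if n.kind is NodeKind.JUNCTION and degree[n.id] < 2:
                raise NetworkError(f"junction node {n.id!r} must attach to >= 2 segments")
        g = self.graph()
        if g.number_of_nodes() and not nx.is_connected(g):
            comps = sorted(nx.connected_components(g), key=len)
            raise NetworkError(f"network is disconnected; smallest island: {sorted(comps[0])}")

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            nodes=[n.copy() for n in self.nodes],
            segments=[s.copy() for s in self.segments],
            name=self.name,
        )

    def equals(self, other: "VascularNetwork") -> bool:
        """Field-by-field equality (exact coordinates and radii)."""
        if self.name != other.name:
            return False
        if [n.id for n in self.nodes] != [n.id for n in other.nodes]:
            return False
        if [s.id for s in self.segments] != [s.id for s in other.segments]:
            return False
        for a, b in zip(self.nodes, other.nodes):
            if a.kind is not b.kind or not np.array_equal(a.position, b.position):
                return False
        for s, t in zip(self.segments, other.segments):
            if (
                s.radius_mm != t.radius_mm
                or s.proximal_node != t.proximal_node
                or s.distal_node != t.distal_node
                or s.territory is not t.territory
                or s.role is not t.role
                or not np.array_equal(s.centerline, t.centerline)
            ):
                return False
        return True


@dataclass(frozen=True)
class CoWVariantSpec:
    """Which circle-of-Willis configuration to generate.

    variant: "complete" (full ring), "no_L_PCoA" (left posterior communicating
    artery absent) or "no_R_ACoA" (anterior communicating artery absent).
    diameter_scale multiplies every vessel radius; seed drives the small
    deterministic jitter applied to terminal branch lengths.
    """

    variant: str = "complete"
    diameter_scale: float = 1.0
    seed: int = 0

    VARIANTS = ("complete", "no_L_PCoA", "no_R_ACoA")

    def __post_init__(self) -> None:
        if self.variant not in self.VARIANTS:
            raise NetworkError(
                f"unknown variant {self.variant!r}; expected one of {self.VARIANTS}"
            )
        if not self.diameter_scale > 0:
            raise NetworkError("diameter_scale must be positive")


# ---------------------------------------------------------------------------
# Default geometry tables
# ---------------------------------------------------------------------------
# Node positions (mm).  Layout: basilar system posterior (-y), carotids
# lateral (+/-x), anterior cerebral tree anterior/superior (+y, +z).
_NODES: dict[str, tuple[tuple[float, float, float], str]] = {
    # inlets
    "L_ICA_in": ((-13.0, -2.0, -24.0), "inlet"),
    "R_ICA_in": ((13.0, -2.0, -24.0), "inlet"),
    "BA_in": ((0.0, -24.0, -22.0), "inlet"),
    # circle-of-Willis junctions
    "L_ICA_T": ((-13.0, 0.0, -6.0), "junction"),
    "R_ICA_T": ((13.0, 0.0, -6.0), "junction"),
    # the basilar tip sits slightly off the midline and the posterior
    # junctions are not mirror images: real basilar bifurcations are never
    # perfectly symmetric, and an exactly symmetric apex would be a
    # stagnation trap for particles riding the basilar axis
    "BA_mid": ((0.2, -23.0, -10.0), "junction"),
    "BA_top": ((0.7, -22.0, -3.6), "junction"),
    "L_PCA_J": ((-9.0, -20.0, -2.0), "junction"),
    "R_PCA_J": ((9.0, -20.5, -1.6), "junction"),
    "L_ACoA_n": ((-2.0, 16.0, -2.0), "junction"),
    "R_ACoA_n": ((2.0, 16.0, -2.0), "junction"),
    # MCA trees
    "L_MCA_bif": ((-34.0, 2.0, -4.0), "junction"),
    "L_M_sup": ((-42.0, 6.0, 2.0), "junction"),
    "L_M_inf": ((-42.0, -2.0, -8.0), "junction"),
    "R_MCA_bif": ((34.0, 2.0, -4.0), "junction"),
    "R_M_sup": ((42.0, 6.0, 2.0), "junction"),
    "R_M_inf": ((42.0, -2.0, -8.0), "junction"),
    # ACA trees
    "L_ACA_bif": ((-3.0, 26.0, 10.0), "junction"),
    "R_ACA_bif": ((3.0, 26.0, 10.0), "junction"),
    # posterior branch points
    "R_PCA_bif": ((16.0, -24.0, -1.0), "junction"),
    # outlet endpoints
    "R_MCA_O1_end": ((50.0, 10.0, 6.0), "outlet"),
    "R_MCA_O2_end": ((52.0, 6.0, 0.0), "outlet"),
    "R_MCA_O3_end": ((50.0, 2.0, 4.0), "outlet"),
    "R_MCA_O4_end": ((50.0, -4.0, -12.0), "outlet"),
    "R_MCA_O5_end": ((52.0, -8.0, -6.0), "outlet"),
    "R_MCA_O6_end": ((48.0, -10.0, -2.0), "outlet"),
    "L_MCA_O1_end": ((-50.0, 10.0, 6.0), "outlet"),
    "L_MCA_O2_end": ((-52.0, 4.0, 2.0), "outlet"),
    "L_MCA_O3_end": ((-50.0, -4.0, -10.0), "outlet"),
    "L_MCA_O4_end": ((-48.0, -8.0, -4.0), "outlet"),
    "ACA_O1_end": ((-8.0, 34.0, 18.0), "outlet"),
    "ACA_O2_end": ((-4.0, 30.0, 22.0), "outlet"),
    "ACA_O3_end": ((-2.0, 36.0, 14.0), "outlet"),
    "ACA_O4_end": ((8.0, 34.0, 18.0), "outlet"),
    "ACA_O5_end": ((4.0, 30.0, 22.0), "outlet"),
    "ACA_O6_end": ((2.0, 36.0, 14.0), "outlet"),
    "BAS_O1_end": ((-8.0, -28.0, -12.0), "outlet"),
    "BAS_O2_end": ((8.5, -27.0, -12.5), "outlet"),
    "L_PCA_O_end": ((-22.0, -26.0, 0.0), "outlet"),
    "R_PCA_O1_end": ((24.0, -30.0, 1.0), "outlet"),
    "R_PCA_O2_end": ((26.0, -22.0, 2.0), "outlet"),
}

# Segments: id -> (proximal, distal, radius_mm, territory, role, interior
# waypoints).  Trunk calibres sit inside the 1-4 mm diameter range of the
# major cerebral arteries; the right ICA is slightly larger than the left.
# The left carotid termination is T-shaped (ICA rises nearly vertically, MCA
# and A1 leave near-perpendicular); the right is Y-shaped (the ICA tangent is
# tilted so MCA and A1 each deviate smoothly) -- the local branching contrast
# that the routing results are sensitive to.
_SEGMENTS: list[tuple[str, str, str, float, str, str, list[tuple[float, float, float]]]] = [
    # feeding vessels
    ("L_ICA", "L_ICA_in", "L_ICA_T", 1.9, "FEEDING", "inlet",
     [(-15.0, -4.0, -14.0), (-12.4, -1.2, -10.4)]),
    ("R_ICA", "R_ICA_in", "R_ICA_T", 2.0, "FEEDING", "inlet",
     [(15.0, -4.0, -14.0), (13.5, -1.5, -12.0)]),
    ("BA", "BA_in", "BA_mid", 1.5, "FEEDING", "inlet", []),
    # basilar tip and superior branches
    ("BA_sup", "BA_mid", "BA_top", 1.4, "POSTERIOR", "internal", []),
    ("BAS_O1", "BA_mid", "BAS_O1_end", 0.8, "POSTERIOR", "terminal", []),
    ("BAS_O2", "BA_mid", "BAS_O2_end", 0.8, "POSTERIOR", "terminal", []),
    ("L_PCA_P1", "BA_top", "L_PCA_J", 1.1, "POSTERIOR", "internal",
     [(-1.3, -21.6, -2.5)]),
    ("R_PCA_P1", "BA_top", "R_PCA_J", 1.1, "POSTERIOR", "internal",
     [(2.6, -21.6, -2.3)]),
    ("L_PCA_O", "L_PCA_J", "L_PCA_O_end", 0.9, "POSTERIOR", "terminal", []),
    ("R_PCA_P2", "R_PCA_J", "R_PCA_bif", 1.0, "POSTERIOR", "internal", []),
    ("R_PCA_O1", "R_PCA_bif", "R_PCA_O1_end", 0.8, "POSTERIOR", "terminal", []),
    ("R_PCA_O2", "R_PCA_bif", "R_PCA_O2_end", 0.8, "POSTERIOR", "terminal", []),
    # communicating arteries
    ("L_PCoA", "L_ICA_T", "L_PCA_J", 0.7, "COMMUNICATING", "internal",
     [(-12.0, -10.0, -4.0)]),
    ("R_PCoA", "R_ICA_T", "R_PCA_J", 0.7, "COMMUNICATING", "internal",
     [(12.0, -10.0, -4.0)]),
    ("ACoA", "L_ACoA_n", "R_ACoA_n", 0.7, "COMMUNICATING", "internal", []),
    # middle cerebral trees
    ("L_MCA", "L_ICA_T", "L_MCA_bif", 1.5, "MCA_L", "internal",
     [(-14.5, 0.7, -5.0), (-20.0, 1.0, -5.0)]),
    ("L_MCA_sup", "L_MCA_bif", "L_M_sup", 1.2, "MCA_L", "internal", []),
    ("L_MCA_inf", "L_MCA_bif", "L_M_inf", 1.2, "MCA_L", "internal", []),
    ("L_MCA_O1", "L_M_sup", "L_MCA_O1_end", 0.8, "MCA_L", "terminal", []),
    ("L_MCA_O2", "L_M_sup", "L_MCA_O2_end", 0.8, "MCA_L", "terminal", []),
    ("L_MCA_O3", "L_M_inf", "L_MCA_O3_end", 0.8, "MCA_L", "terminal", []),
    ("L_MCA_O4", "L_M_inf", "L_MCA_O4_end", 0.8, "MCA_L", "terminal", []),
    ("R_MCA", "R_ICA_T", "R_MCA_bif", 1.5, "MCA_R", "internal",
     [(14.6, 1.0, -4.8), (20.0, 2.0, -5.0)]),
    ("R_MCA_sup", "R_MCA_bif", "R_M_sup", 1.2, "MCA_R", "internal", []),
    ("R_MCA_inf", "R_MCA_bif", "R_M_inf", 1.2, "MCA_R", "internal", []),
    ("R_MCA_O1", "R_M_sup", "R_MCA_O1_end", 0.75, "MCA_R", "terminal", []),
    ("R_MCA_O2", "R_M_sup", "R_MCA_O2_end", 0.75, "MCA_R", "terminal", []),
    ("R_MCA_O3", "R_M_sup", "R_MCA_O3_end", 0.75, "MCA_R", "terminal", []),
    ("R_MCA_O4", "R_M_inf", "R_MCA_O4_end", 0.75, "MCA_R", "terminal", []),
    ("R_MCA_O5", "R_M_inf", "R_MCA_O5_end", 0.75, "MCA_R", "terminal", []),
    ("R_MCA_O6", "R_M_inf", "R_MCA_O6_end", 0.75, "MCA_R", "terminal", []),
    # anterior cerebral trees
    ("L_ACA_A1", "L_ICA_T", "L_ACoA_n", 1.2, "ACA", "internal",
     [(-12.2, 1.6, -4.6)]),
    ("R_ACA_A1", "R_ICA_T", "R_ACoA_n", 1.2, "ACA", "internal",
     [(12.2, 1.6, -4.6)]),
    ("L_ACA_A2", "L_ACoA_n", "L_ACA_bif", 1.1, "ACA", "internal", []),
    ("R_ACA_A2", "R_ACoA_n", "R_ACA_bif", 1.1, "ACA", "internal", []),
    ("ACA_O1", "L_ACA_bif", "ACA_O1_end", 0.7, "ACA", "terminal", []),
    ("ACA_O2", "L_ACA_bif", "ACA_O2_end", 0.7, "ACA", "terminal", []),
    ("ACA_O3", "L_ACA_bif", "ACA_O3_end", 0.7, "ACA", "terminal", []),
    ("ACA_O4", "R_ACA_bif", "ACA_O4_end", 0.7, "ACA", "terminal", []),
    ("ACA_O5", "R_ACA_bif", "ACA_O5_end", 0.7, "ACA", "terminal", []),
    ("ACA_O6", "R_ACA_bif", "ACA_O6_end", 0.7, "ACA", "terminal", []),
]

_VARIANT_REMOVALS = {"complete": None, "no_L_PCoA": "L_PCoA", "no_R_ACoA": "ACoA"}


def generate_cow(spec: CoWVariantSpec = CoWVariantSpec()) -> VascularNetwork:
    """Generate the synthetic circle-of-Willis network for a variant spec.

    Deterministic: the same spec (including seed) always produces a
    bit-identical network.  The seed perturbs terminal branch lengths by a
    fraction of a millimetre (outlet endpoints slide along their own branch
    direction), leaving topology, radii and all trunk geometry untouched.
    """
    removed = _VARIANT_REMOVALS[spec.variant]
    rng = np.random.default_rng(spec.seed)

    nodes = {
        nid: NetworkNode(nid, point3(*pos), kind)
        for nid, (pos, kind) in _NODES.items()
    }
    segments: list[VesselSegment] = []
    for sid, prox, dist, r, terr, role, waypoints in _SEGMENTS:
        # draw jitter for every terminal in table order so that variant
        # removal does not shift the stream for the remaining vessels
        jitter = float(rng.uniform(-0.4, 0.4)) if role == "terminal" else 0.0
        if sid == removed:
            continue
        p0 = nodes[prox].position
        p1 = nodes[dist].position
        if role == "terminal" and jitter != 0.0:
            direction = p1 - p0
            direction = direction / np.linalg.norm(direction)
            p1 = p1 + jitter * direction
            nodes[dist] = NetworkNode(dist, p1, NodeKind.OUTLET)
        pts = [p0] + [point3(*w) for w in waypoints] + [p1]
        segments.append(
            VesselSegment(
                id=sid,
                centerline=np.vstack(pts),
                radius_mm=r * spec.diameter_scale,
                proximal_node=prox,
                distal_node=dist,
                territory=Territory(terr),
                role=Role(role),
            )
        )
    used = {s.proximal_node for s in segments} | {s.distal_node for s in segments}
    net = VascularNetwork(
        nodes=[n for nid, n in nodes.items() if nid in used],
        segments=segments,
        name=f"cow_{spec.variant}",
    )
    net.validate()
    return net


def extend_inlets(net: VascularNetwork, factor: float) -> VascularNetwork:
    """Prolong each inlet segment upstream by ``factor`` local diameters.

    The entry point slides back along the entry tangent by factor * (2r) as a
    straight run; every other segment is untouched.  Long straight inlet runs
    let an injected particle relax onto the local flow before the first bend.
    """
    if factor < 0:
        raise NetworkError("inlet extension factor must be >= 0")
    out = net.copy()
    if factor == 0:
        return out
    for seg in out.segments:
        if seg.role is not Role.INLET:
            continue
        tangent = seg.centerline[1] - seg.centerline[0]
        tangent = tangent / np.linalg.norm(tangent)
        new_start = seg.centerline[0] - factor * seg.diameter_mm * tangent
        seg.centerline = np.vstack([new_start, seg.centerline])
        node = out.node(seg.proximal_node)
        node.position = new_start.copy()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Terminal calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    network: VascularNetwork
    achieved: dict[str, float]  # group -> % of total outflow
    iterations: int
    converged: bool


class ConvergenceError(RuntimeError):
    """Terminal calibration failed to reach the target split."""

    def __init__(self, message: str, achieved: dict[str, float]):
        super().__init__(message)
        self.achieved = achieved


_GROUPS: dict[str, tuple[Territory, ...]] = {
    "ACA": (Territory.ACA,),
    "MCA": (Territory.MCA_L, Territory.MCA_R),
    "MCA_L": (Territory.MCA_L,),
    "MCA_R": (Territory.MCA_R,),
    "POSTERIOR": (Territory.POSTERIOR,),
    "PCA": (Territory.POSTERIOR,),
}


def _group_fractions(net: VascularNetwork, territory_pct: Mapping[str, float],
                     groups: Iterable[str]) -> dict[str, float]:
    out = {}
    for g in groups:
        out[g] = sum(territory_pct.get(t.value, 0.0) for t in _GROUPS[g])
    return out


def calibrate_terminals(
    net: VascularNetwork,
    fluid=None,
    bc=None,
    target_fractions: Mapping[str, float] | None = None,
    tol: float = 1.0,
    max_iter: int = 60,
) -> CalibrationResult:
    """Rescale terminal radii until territory outflow splits hit the targets.

    target_fractions maps group names ("ACA", "MCA", "POSTERIOR", or the
    individual MCA_L/MCA_R territories) to percent of total outflow and must
    sum to 100.  Only terminal-segment radii move (a fixed point on the
    quarter-power of the flow mismatch, since Poiseuille resistance scales as
    r^-4); trunk vessels are never rescaled.  Raises ConvergenceError with the
    last achieved fractions if the tolerance is not met within max_iter.
    """
    from . import hemodynamics as hd  # local import: avoids a module cycle

    if fluid is None:
        fluid = hd.FluidProperties()
    if target_fractions is None:
        target_fractions = {"ACA": 20.0, "MCA": 60.0, "POSTERIOR": 20.0}
    targets = {k: float(v) for k, v in target_fractions.items()}
    for g in targets:
        if g not in _GROUPS:
            raise NetworkError(f"unknown territory group {g!r} in calibration targets")
    if abs(sum(targets.values()) - 100.0) > 1e-6:
        raise NetworkError("calibration target fractions must sum to 100")

    work = net.copy()
    group_terms: dict[str, list[str]] = {}
    for g in targets:
        terms = [s.id for s in work.terminal_segments if s.territory in _GROUPS[g]]
        if not terms:
            raise NetworkError(f"territory group {g!r} has no terminal segments")
        group_terms[g] = terms

    achieved: dict[str, float] = {}
    for it in range(1, max_iter + 1):
        the_bc = bc if bc is not None else hd.BoundarySpec.default(work)
        sol = hd.solve_flow(work, fluid, the_bc)
        _, terr_pct = hd.outlet_fractions(work, sol)
        achieved = _group_fractions(work, terr_pct, targets)
        err = max(abs(achieved[g] - targets[g]) for g in targets)
        if err <= tol:
            work.validate()
            return CalibrationResult(work, achieved, it, True)
        for g, terms in group_terms.items():
            if achieved[g] <= 0:
                factor = 2.0
            else:
                factor = float(np.clip((targets[g] / achieved[g]) ** 0.25, 0.5, 2.0))
            for sid in terms:
                seg = work.segment(sid)
                seg.radius_mm = float(np.clip(seg.radius_mm * factor, 0.1, 2.0))
    raise ConvergenceError(
        f"terminal calibration did not converge in {max_iter} iterations; "
        f"last achieved fractions: {achieved}",
        achieved,
    )


# ---------------------------------------------------------------------------
# Geometry queries
# ---------------------------------------------------------------------------

def _resolve_route_node(net: VascularNetwork, ident: str) -> str:
    """Accept a node id, an inlet segment id, or a terminal segment id."""
    if ident in net._node_map:
        return ident
    seg = net.segment(ident)
    if seg.role is Role.INLET:
        return seg.proximal_node
    if seg.role is Role.TERMINAL:
        return seg.distal_node
    raise NetworkError(f"{ident!r} is an internal segment, not an inlet/outlet")


def route_length(net: VascularNetwork, inlet_id: str, outlet_id: str) -> float:
    """Centerline length (mm) of the shortest path from inlet to outlet.

    Ids may be node ids or inlet/terminal segment ids (outlet labels such as
    "R_MCA_O1" name terminal segments).
    """
    src = _resolve_route_node(net, inlet_id)
    dst = _resolve_route_node(net, outlet_id)
    g = net.graph()
    try:
        return float(nx.shortest_path_length(g, src, dst, weight="length"))
    except nx.NetworkXNoPath:
        raise NetworkError(f"no path between {inlet_id!r} and {outlet_id!r}") from None


@dataclass(frozen=True)
class LocatedPoint:
    segment_id: str
    axial_mm: float   # arc length along the centerline to the projection
    radial_mm: float  # distance from the centerline axis


def _segment_project(seg: VesselSegment, p: np.ndarray) -> tuple[float, float]:
    """(axial arc length, radial distance) of the closest centerline point."""
    pts = seg.centerline
    best = (math.inf, 0.0)
    arc = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        lab = float(np.linalg.norm(ab))
        t = float(np.clip(np.dot(p - a, ab) / (lab * lab), 0.0, 1.0))
        closest = a + t * ab
        d = float(np.linalg.norm(p - closest))
        if d < best[0]:
            best = (d, arc + t * lab)
        arc += lab
    return best[1], best[0]


def locate(net: VascularNetwork, p) -> LocatedPoint | None:
    """Find the lumen segment containing a point (mm), or None if outside.

    In junction overlap regions the segment whose axis is nearest wins.
    """
    p = np.asarray(p, dtype=float)
    best: LocatedPoint | None = None
    best_radial = math.inf
    for seg in net.segments:
        axial, radial = _segment_project(seg, p)
        if radial <= seg.radius_mm and radial < best_radial:
            best = LocatedPoint(seg.id, axial, radial)
            best_radial = radial
    return best


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _network_payload(net: VascularNetwork) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "name": net.name,
        "nodes": [
            {"id": n.id, "kind": n.kind.value, "xyz_mm": [float(v) for v in n.position]}
            for n in net.nodes
        ],
        "segments": [
            {
                "id": s.id,
                "proximal": s.proximal_node,
                "distal": s.distal_node,
                "radius_mm": float(s.radius_mm),
                "territory": s.territory.value,
                "role": s.role.value,
                "centerline_mm": [[float(v) for v in row] for row in s.centerline],
            }
            for s in net.segments
        ],
    }


def write_network(net: VascularNetwork, path) -> None:
    """Write a network to the JSON schema (coordinates in mm)."""
    with open(path, "w") as fh:
        json.dump(_network_payload(net), fh, indent=1, sort_keys=False)
        fh.write("\n")


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"network file: missing field {key!r} in {context}")
    return mapping[key]


def read_network(path) -> VascularNetwork:
    """Read a network JSON file; parse errors name the offending field."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"network file is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("network file: top level must be an object")
    version = _require(data, "schema_version", "top level")
    if str(version) != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r}")
    name = _require(data, "name", "top level")
    nodes = []
    for entry in _require(data, "nodes", "top level"):
        nodes.append(
            NetworkNode(
                id=str(_require(entry, "id", "node")),
                position=np.asarray(_require(entry, "xyz_mm", f"node {entry.get('id')!r}"), dtype=float),
                kind=NodeKind(_require(entry, "kind", f"node {entry.get('id')!r}")),
            )
        )
    segments = []
    for entry in _require(data, "segments", "top level"):
        sid = entry.get("id", "<missing id>")
        segments.append(
            VesselSegment(
                id=str(_require(entry, "id", "segment")),
                centerline=_as_points(_require(entry, "centerline_mm", f"segment {sid!r}")),
                radius_mm=float(_require(entry, "radius_mm", f"segment {sid!r}")),
                proximal_node=str(_require(entry, "proximal", f"segment {sid!r}")),
                distal_node=str(_require(entry, "distal", f"segment {sid!r}")),
                territory=Territory(_require(entry, "territory", f"segment {sid!r}")),
                role=Role(_require(entry, "role", f"segment {sid!r}")),
            )
        )
    net = VascularNetwork(nodes=nodes, segments=segments, name=str(name))
    net.validate()
    return net


def write_vtk(net: VascularNetwork, path) -> None:
    """Export centerlines as legacy-ASCII VTK polydata (for visualization)."""
    points: list[np.ndarray] = []
    lines: list[list[int]] = []
    radii: list[float] = []
    for seg in net.segments:
        start = len(points)
        points.extend(seg.centerline)
        lines.append(list(range(start, start + len(seg.centerline))))
        radii.extend([seg.radius_mm] * len(seg.centerline))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{net.name}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        size = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {size}\n")
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        fh.write(f"POINT_DATA {len(points)}\nSCALARS radius_mm float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.6f}\n")
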