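"""Reduced-order blood flow in the tube network, plus the continuous field.

The 3-D flow problem is collapsed to a Hagen-Poiseuille resistance network:
each segment contributes a resistance 8 mu L / (pi r^4), mass is conserved at
every node, inlet velocity boundary conditions become fixed volumetric
inflows Q = v pi r^2, and outlets carry either fixed pressures (default 0 Pa,
the paper-style outflow condition) or fixed flows with a single pressure
reference (the "M1" mode).  Inside each tube the velocity is reconstructed as
the analytic axisymmetric Poiseuille profile (no slip at the wall, centerline
speed twice the mean) and the pressure gradient is uniform; in junction
overlap regions adjacent tubes' fields are blended with inverse-distance-to-
axis weights.

Internally everything is SI (metres, Pa, m^3/s).  The public geometry API
takes points in millimetres, matching the vasculature module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .vasculature import (
    NetworkError,
    NodeKind,
    Role,
    Territory,
    VascularNetwork,
    VesselSegment,
)

__all__ = [
    "FluidProperties",
    "BoundarySpec",
    "FlowSolution",
    "segment_resistance",
    "solve_flow",
    "outlet_fractions",
    "velocity_at",
    "pressure_gradient_at",
    "wall_distance",
    "TubeField",
    "flow_to_frame",
    "fractions_to_frame",
]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid."""

    density: float = 1056.0       # kg/m^3
    viscosity: float = 3.2e-3     # Pa s (dynamic)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass
class BoundarySpec:
    """Inlet velocities, outlet pressures, and optional fixed outlet flows.

    Keys are segment ids: inlet segment ids for velocities, terminal segment
    ids for pressures/flows.  In fixed-flow (M1) mode every outlet except one
    pressure-reference outlet carries a prescribed volumetric flow.
    """

    inlet_velocities: dict[str, float]                  # m/s
    outlet_pressures: dict[str, float]                  # Pa
    fixed_outlet_flows: dict[str, float] | None = None  # m^3/s

    @classmethod
    def default(cls, net: VascularNetwork, inlet_velocity: float = 0.2) -> "BoundarySpec":
        """All inlets at one normal velocity, all outlets at 0 Pa."""
        return cls(
            inlet_velocities={s: inlet_velocity for s in net.inlet_ids()},
            outlet_pressures={s: 0.0 for s in net.outlet_ids()},
        )

    @classmethod
    def fixed_flow(
        cls,
        net: VascularNetwork,
        outlet_flows: Mapping[str, float],
        reference_outlet: str,
        inlet_velocity: float = 0.2,
        reference_pressure: float = 0.0,
    ) -> "BoundarySpec":
        """M1 mode: prescribe flows on all outlets except the reference one."""
        flows = {k: float(v) for k, v in outlet_flows.items() if k != reference_outlet}
        return cls(
            inlet_velocities={s: inlet_velocity for s in net.inlet_ids()},
            outlet_pressures={reference_outlet: reference_pressure},
            fixed_outlet_flows=flows,
        )

    def validate(self, net: VascularNetwork) -> None:
        inlets = set(net.inlet_ids())
        outlets = set(net.outlet_ids())
        if set(self.inlet_velocities) != inlets:
            raise NetworkError(
                f"inlet velocities must cover exactly the inlets {sorted(inlets)}"
            )
        fixed = set(self.fixed_outlet_flows or {})
        pressured = set(self.outlet_pressures)
        if fixed:
            if fixed | pressured != outlets or fixed & pressured:
                raise NetworkError(
                    "fixed-flow mode: every outlet needs exactly one of a fixed flow "
                    "or a reference pressure"
                )
            if len(pressured) != 1:
                raise NetworkError("fixed-flow mode requires a unique pressure-reference outlet")
        elif pressured != outlets:
            raise NetworkError(
                f"outlet pressures must cover exactly the outlets {sorted(outlets)}"
            )


@dataclass
class FlowSolution:
    """Nodal pressures and signed per-segment flows (positive prox -> dist)."""

    node_pressure: dict[str, float]        # Pa
    segment_flow: dict[str, float]         # m^3/s
    segment_mean_velocity: dict[str, float]  # m/s
    total_inflow: float                    # m^3/s

    def flow(self, seg_id: str) -> float:
        return self.segment_flow[seg_id]


def segment_resistance(seg: VesselSegment, fluid: FluidProperties) -> float:
    """Poiseuille resistance 8 mu L / (pi r^4) in Pa s / m^3."""
    length = seg.length_mm * MM
    radius = seg.radius_mm * MM
    if length <= 0:
        raise NetworkError(f"segment {seg.id!r} has zero length")
    return 8.0 * fluid.viscosity * length / (np.pi * radius**4)


def _inlet_inflow(seg: VesselSegment, v: float) -> float:
    r = seg.radius_mm * MM
    return v * np.pi * r * r


def solve_flow(net: VascularNetwork, fluid: FluidProperties, bc: BoundarySpec) -> FlowSolution:
    """Solve the nodal conservation system for pressures and segment flows."""
    bc.validate(net)
    g = net.graph()
    import networkx as nx

    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len)
        raise NetworkError(f"cannot solve a disconnected network; island: {sorted(comps[0])}")

    # Dirichlet pressures live on the outlet nodes of pressure-BC outlets.
    dirichlet: dict[str, float] = {
        net.outlet_node_of(seg_id): p for seg_id, p in bc.outlet_pressures.items()
    }
    # Source terms: inflow at inlet nodes, extraction at fixed-flow outlets.
    source: dict[str, float] = {}
    for seg_id, v in bc.inlet_velocities.items():
        node = net.inlet_node_of(seg_id)
        source[node] = source.get(node, 0.0) + _inlet_inflow(net.segment(seg_id), v)
    total_inflow = sum(source.values())
    for seg_id, q in (bc.fixed_outlet_flows or {}).items():
        node = net.outlet_node_of(seg_id)
        source[node] = source.get(node, 0.0) - q

    unknown = [n.id for n in net.nodes if n.id not in dirichlet]
    index = {nid: i for i, nid in enumerate(unknown)}
    n = len(unknown)
    A = sp.lil_matrix((n, n))
    b = np.zeros(n)
    for nid, s in source.items():
        if nid in index:
            b[index[nid]] += s
    conductance: dict[str, float] = {}
    for seg in net.segments:
        cond = 1.0 / segment_resistance(seg, fluid)
        conductance[seg.id] = cond
        u, w = seg.proximal_node, seg.distal_node
        for a_node, b_node in ((u, w), (w, u)):
            if a_node in index:
                i = index[a_node]
                A[i, i] += cond
                if b_node in index:
                    A[i, index[b_node]] -= cond
                else:
                    b[i] += cond * dirichlet[b_node]
    pressures = dict(dirichlet)
    if n:
        x = spla.spsolve(sp.csc_matrix(A), b)
        if not np.all(np.isfinite(x)):
            raise NetworkError("flow solve produced non-finite pressures (singular system)")
        pressures.update({nid: float(x[index[nid]]) for nid in unknown})

    seg_flow: dict[str, float] = {}
    seg_vel: dict[str, float] = {}
    for seg in net.segments:
        q = conductance[seg.id] * (pressures[seg.proximal_node] - pressures[seg.distal_node])
        r = seg.radius_mm * MM
        seg_flow[seg.id] = q
        seg_vel[seg.id] = q / (np.pi * r * r)
    sol = FlowSolution(pressures, seg_flow, seg_vel, total_inflow)
    _check_conservation(net, sol)
    return sol


def _check_conservation(net: VascularNetwork, sol: FlowSolution, rel: float = 1e-10) -> None:
    imbalance = node_imbalance(net, sol)
    worst = max(imbalance.values(), default=0.0)
    if worst > rel * max(sol.total_inflow, 1e-300):
        raise NetworkError(f"junction flow imbalance {worst:.3e} exceeds tolerance")


def node_imbalance(net: VascularNetwork, sol: FlowSolution) -> dict[str, float]:
    """Absolute net flow at each interior junction node (m^3/s)."""
    net_flow: dict[str, float] = {n.id: 0.0 for n in net.nodes}
    for seg in net.segments:
        q = sol.segment_flow[seg.id]
        net_flow[seg.proximal_node] -= q
        net_flow[seg.distal_node] += q
    return {
        n.id: abs(net_flow[n.id])
        for n in net.nodes
        if n.kind is NodeKind.JUNCTION
    }


def outlet_fractions(
    net: VascularNetwork, sol: FlowSolution
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-outlet and per-territory outflow as percent of total inflow."""
    if not isinstance(sol, FlowSolution):
        raise NetworkError("outlet_fractions requires a solved FlowSolution")
    total = sol.total_inflow
    if total <= 0:
        raise NetworkError("flow solution carries no inflow")
    per_outlet: dict[str, float] = {}
    per_territory: dict[str, float] = {
        t.value: 0.0
        for t in (Territory.MCA_R, Territory.MCA_L, Territory.ACA, Territory.POSTERIOR)
    }
    for seg in net.terminal_segments:
        q = sol.segment_flow[seg.id]  # positive toward the outlet node
        pct = 100.0 * q / total
        per_outlet[seg.id] = pct
        if seg.territory.value in per_territory:
            per_territory[seg.territory.value] += pct
    return per_outlet, per_territory


# ---------------------------------------------------------------------------
# Continuous field reconstruction
# ---------------------------------------------------------------------------

_BLEND_EPS = 0.01 * MM  # inverse-distance blending regularizer (0.01 mm)
_BLEND_POW = 3          # sharpness of the junction blend, w ~ 1/(eps + d)^p


class TubeField:
    """Vectorized evaluator of velocity, pressure gradient and wall geometry.

    Precomputes one flat array of centerline pieces (polyline sub-segments)
    over the whole network.  ``sample`` evaluates a batch of points (metres)
    and returns the blended Poiseuille velocity, the blended uniform pressure
    gradient, a signed distance to the tube-union wall (negative inside), the
    outward wall normal, and outlet/inlet crossing flags used by the particle
    integrator.
    """

    def __init__(self, net: VascularNetwork, sol: FlowSolution):
        self.net = net
        self.sol = sol
        p0, t_hat, length, radius, vmax_vec, grad_vec = [], [], [], [], [], []
        seg_of_piece: list[int] = []
        exit_outlet: list[int] = []   # outlet index if last piece of terminal
        inlet_first: list[bool] = []
        self.outlet_ids: list[str] = net.outlet_ids()
        outlet_index = {sid: i for i, sid in enumerate(self.outlet_ids)}
        self.segment_ids: list[str] = [s.id for s in net.segments]
        for si, seg in enumerate(net.segments):
            pts = seg.centerline * MM
            q = sol.segment_flow[seg.id]
            r = seg.radius_mm * MM
            vmean = sol.segment_mean_velocity[seg.id]
            total_len = seg.length_mm * MM
            dp_dl = 0.0
            if total_len > 0:
                dp_dl = (
                    sol.node_pressure[seg.distal_node] - sol.node_pressure[seg.proximal_node]
                ) / total_len  # gradient along prox->dist tangent (negative when q > 0)
            npieces = len(pts) - 1
            for k in range(npieces):
                a, b = pts[k], pts[k + 1]
                d = b - a
                lab = float(np.linalg.norm(d))
                t = d / lab
                p0.append(a)
                t_hat.append(t)
                length.append(lab)
                radius.append(r)
                # centerline velocity vector: 2 * vmean along prox->dist
                vmax_vec.append(2.0 * vmean * t)
                grad_vec.append(dp_dl * t)
                seg_of_piece.append(si)
                exit_outlet.append(
                    outlet_index[seg.id]
                    if (seg.role is Role.TERMINAL and k == npieces - 1)
                    else -1
                )
                inlet_first.append(seg.role is Role.INLET and k == 0)
        self.p0 = np.asarray(p0)
        self.t_hat = np.asarray(t_hat)
        self.length = np.asarray(length)
        self.radius = np.asarray(radius)
        self.vmax_vec = np.asarray(vmax_vec)
        self.grad_vec = np.asarray(grad_vec)
        self.seg_of_piece = np.asarray(seg_of_piece)
        self.exit_outlet = np.asarray(exit_outlet)
        self.inlet_first = np.asarray(inlet_first)

    def sample(self, points: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluate the field at an (N, 3) batch of positions in metres."""
        P = np.atleast_2d(points)
        D = P[:, None, :] - self.p0[None, :, :]            # (N, M, 3)
        proj = np.einsum("nmd,md->nm", D, self.t_hat)      # (N, M)
        projc = np.clip(proj, 0.0, self.length[None, :])
        closest = self.p0[None, :, :] + projc[..., None] * self.t_hat[None, :, :]
        dvec = P[:, None, :] - closest
        dist = np.sqrt(np.einsum("nmd,nmd->nm", dvec, dvec))
        phi_piece = dist - self.radius[None, :]
        j_star = np.argmin(phi_piece, axis=1)
        rows = np.arange(len(P))
        phi = phi_piece[rows, j_star]

        inside = dist <= self.radius[None, :]
        w = np.where(inside, 1.0 / (_BLEND_EPS + dist) ** _BLEND_POW, 0.0)
        wsum = w.sum(axis=1)
        safe = np.where(wsum > 0, wsum, 1.0)
        ratio2 = (dist / self.radius[None, :]) ** 2
        profile = np.where(inside, 1.0 - ratio2, 0.0)      # (N, M)
        u = np.einsum("nm,md->nd", w * profile, self.vmax_vec) / safe[:, None]
        gradp = np.einsum("nm,md->nd", w, self.grad_vec) / safe[:, None]

        # wall normal from the nearest piece (radial; spherical at end caps)
        nvec = dvec[rows, j_star]
        nnorm = np.linalg.norm(nvec, axis=1)
        normal = np.zeros_like(nvec)
        ok = nnorm > 0
        normal[ok] = nvec[ok] / nnorm[ok, None]

        # nearest wall among the *containing* tubes (distinct from phi, which
        # measures membership in the tube union)
        phi_in = np.where(inside, phi_piece, -np.inf)
        j_wall = np.argmax(phi_in, axis=1)
        wall_phi = phi_in[rows, j_wall]
        wvec = dvec[rows, j_wall]
        wnorm = np.linalg.norm(wvec, axis=1)
        wall_normal = np.zeros_like(wvec)
        ok_w = wnorm > 0
        wall_normal[ok_w] = wvec[ok_w] / wnorm[ok_w, None]

        # outlet-plane crossing: nearest piece is a terminal end and the
        # unclamped axial coordinate overshoots the piece
        exit_idx = np.full(len(P), -1, dtype=int)
        cand = self.exit_outlet[j_star]
        over = proj[rows, j_star] > self.length[j_star]
        exit_idx[(cand >= 0) & over] = cand[(cand >= 0) & over]
        # small margin so release-plane jitter noise never reads as upstream
        upstream = self.inlet_first[j_star] & (proj[rows, j_star] < -1e-6)

        return {
            "u": u,
            "gradp": gradp,
            "phi": phi,
            "normal": normal,
            "wall_phi": wall_phi,
            "wall_normal": wall_normal,
            "exit": exit_idx,
            "upstream": upstream,
            "nearest_segment": self.seg_of_piece[j_star],
        }

    def signed_distance(self, point: np.ndarray) -> float:
        """Signed distance (m) to the tube-union wall; negative inside."""
        return float(self.sample(point[None, :])["phi"][0])


_FIELD_CACHE: dict[tuple[int, int], TubeField] = {}


def _field_for(net: VascularNetwork, sol: FlowSolution) -> TubeField:
    key = (id(net), id(sol))
    fieldobj = _FIELD_CACHE.get(key)
    if fieldobj is None or fieldobj.net is not net or fieldobj.sol is not sol:
        fieldobj = TubeField(net, sol)
        _FIELD_CACHE.clear()
        _FIELD_CACHE[key] = fieldobj
    return fieldobj


def velocity_at(net: VascularNetwork, sol: FlowSolution, p_mm) -> np.ndarray:
    """Blended Poiseuille velocity (m/s) at a point given in millimetres."""
    fieldobj = _field_for(net, sol)
    point = np.asarray(p_mm, dtype=float) * MM
    s = fieldobj.sample(point[None, :])
    if s["phi"][0] > 0:
        raise NetworkError(f"point {p_mm!r} lies outside the lumen")
    return s["u"][0]


def pressure_gradient_at(net: VascularNetwork, sol: FlowSolution, p_mm) -> np.ndarray:
    """Blended pressure gradient (Pa/m) at a point given in millimetres."""
    fieldobj = _field_for(net, sol)
    point = np.asarray(p_mm, dtype=float) * MM
    s = fieldobj.sample(point[None, :])
    if s["phi"][0] > 0:
        raise NetworkError(f"point {p_mm!r} lies outside the lumen")
    return s["gradp"][0]


def wall_distance(net: VascularNetwork, sol: FlowSolution, p_mm) -> tuple[float, np.ndarray]:
    """Distance (mm) to the nearest tube wall and its outward unit normal."""
    fieldobj = _field_for(net, sol)
    point = np.asarray(p_mm, dtype=float) * MM
    s = fieldobj.sample(point[None, :])
    if s["phi"][0] > 0:
        raise NetworkError(f"point {p_mm!r} lies outside the lumen")
    return -s["wall_phi"][0] / MM, s["wall_normal"][0]


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def flow_to_frame(net: VascularNetwork, sol: FlowSolution) -> pd.DataFrame:
    """Segment flows and mean velocities as a DataFrame (CSV-ready)."""
    rows = [
        {
            "segment": seg.id,
            "territory": seg.territory.value,
            "role": seg.role.value,
            "flow_m3_s": sol.segment_flow[seg.id],
            "mean_velocity_m_s": sol.segment_mean_velocity[seg.id],
        }
        for seg in net.segments
    ]
    return pd.DataFrame(rows)


def fractions_to_frame(net: VascularNetwork, sol: FlowSolution) -> pd.DataFrame:
    """Per-outlet outflow percentages in the flow-division table layout."""
    per_outlet, _ = outlet_fractions(net, sol)
    rows = [
        {
            "outlet": sid,
            "territory": net.segment(sid).territory.value,
            "percent_of_inflow": per_outlet[sid],
        }
        for sid in net.outlet_ids()
    ]
    return pd.DataFrame(rows)
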