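"""Mirrored-domain Poiseuille flow solver.

Homogenization assumes a spatially periodic microstructure, which anatomical
networks are not. Periodicity is imposed by mirroring: the subnetwork volume
is reflected across its upper x, then y, then z faces, producing a domain of
doubled extents containing 8 flipped copies whose opposite outer faces are
mirror-identical — every node on a lateral face has an exact periodic
partner on the opposite face.

For a pressure gradient applied along one axis, Dirichlet pressures are set
on the two faces normal to that axis (p = L·∇p on the inflow face, 0 on the
outflow face), each lateral-face periodic pair is merged into a single
unknown (equal pressure, conserved flow), and Kirchhoff's current law with
Poiseuille conductances g = πr⁴/(8μl) yields a sparse SPD system for the
nodal pressures.

Units: positions/lengths μm, pressures Pa, viscosity mPa·s at the interface
(converted to Pa·s inside the conductance), flows μm³/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import Node, Segment, Subnetwork, VesselNetwork, face_tags_for_position
from .rheology import RheologyParams, segment_viscosity

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "HemodynamicState",
    "MirroredNetwork",
    "mirror_network",
    "assemble_and_solve",
    "surface_flux",
]

AXES = {"x": 0, "y": 1, "z": 2}

#: Radii below this (μm) are clamped for the conductance to avoid underflow.
MIN_RADIUS = 0.1


@dataclass
class SolverConfig:
    gradient_pa_per_um: float = 1.0
    solver_tol: float = 1e-10
    solver_max_iter: int = 10_000
    #: above this many unknowns, use an iterative (CG) solve
    direct_limit: int = 200_000


@dataclass
class HemodynamicState:
    """Flow solution for one applied gradient direction."""

    pressure: dict[int, float]            # node id -> Pa
    flow: dict[int, float]                # segment id -> μm³/s, signed node_a→node_b
    pressure_drop: dict[int, float]       # segment id -> Pa (p_a − p_b)
    viscosity: dict[int, float]           # segment id -> mPa·s
    hematocrit: dict[int, float]          # segment id -> discharge hematocrit
    gradient_direction: str               # "x" | "y" | "z"
    applied_gradient: float               # Pa/μm
    converged: bool = True

    def copy(self) -> "HemodynamicState":
        return HemodynamicState(
            dict(self.pressure), dict(self.flow), dict(self.pressure_drop),
            dict(self.viscosity), dict(self.hematocrit),
            self.gradient_direction, self.applied_gradient, self.converged,
        )


@dataclass
class MirroredNetwork:
    """A triply mirrored subnetwork on the doubled domain [2Wx, 2Wy, 2Wz]."""

    network: VesselNetwork
    origin_segment: dict[int, int]        # mirrored segment id -> source segment id
    origin_node: dict[int, int]           # mirrored node id -> source node id
    n_reflections: int = 3

    @property
    def box(self) -> np.ndarray:
        return self.network.box


def _reflect(net: VesselNetwork, ax: int, tol: float):
    """Reflect ``net`` across its upper face along axis ``ax``, merging plane nodes."""
    w = net.box[ax]
    new_box = net.box.copy()
    new_box[ax] = 2.0 * w
    nodes: dict[int, Node] = {}
    node_image: dict[int, int] = {}
    next_nid = max(net.nodes, default=-1) + 1
    for nid, node in net.nodes.items():
        nodes[nid] = Node(nid, node.position.copy())
        if abs(node.position[ax] - w) <= tol:
            node_image[nid] = nid  # lies on the mirror plane: merges with itself
        else:
            pos = node.position.copy()
            pos[ax] = 2.0 * w - pos[ax]
            nodes[next_nid] = Node(next_nid, pos)
            node_image[nid] = next_nid
            next_nid += 1

    segments: dict[int, Segment] = {}
    seg_image: dict[int, int] = {}
    next_sid = max(net.segments, default=-1) + 1
    for sid, seg in net.segments.items():
        segments[sid] = Segment(sid, seg.node_a, seg.node_b, seg.radius, seg.length)
        ia, ib = node_image[seg.node_a], node_image[seg.node_b]
        if ia == seg.node_a and ib == seg.node_b:
            seg_image[sid] = sid  # segment lies in the mirror plane
        else:
            segments[next_sid] = Segment(next_sid, ia, ib, seg.radius, seg.length)
            seg_image[sid] = next_sid
            next_sid += 1

    out = VesselNetwork(nodes, segments, new_box, net.provenance, net.face_tol)
    out.retag_faces()
    return out, node_image, seg_image


def mirror_network(sub: Subnetwork) -> MirroredNetwork:
    """Mirror a subnetwork across its upper x, y and z domain faces in turn.

    The subnetwork is first translated so its occupied domain starts at the
    origin; the mirrored domain then spans [0, 2W] per axis and contains 8
    flipped copies, with nodes coincident on the mirror planes merged.
    Applying the whole operation a second time (mirroring the mirrored
    network wrapped as a subnetwork) must leave the permeability tensor
    unchanged — the method's internal validation check.
    """
    lo, hi = sub.domain_bounds()
    net = sub.network.copy()
    for node in net.nodes.values():
        node.position -= lo
    net.box = np.maximum(hi - lo, net.face_tol)  # degenerate (flat) axes get tol width
    net.retag_faces()

    origin_node = {nid: nid for nid in net.nodes}
    origin_seg = {sid: sid for sid in net.segments}
    for ax in range(3):
        net, node_image, seg_image = _reflect(net, ax, net.face_tol)
        for nid in list(origin_node):
            img = node_image[nid]
            if img != nid:
                origin_node[img] = origin_node[nid]
        for sid in list(origin_seg):
            img = seg_image[sid]
            if img != sid:
                origin_seg[img] = origin_seg[sid]
    return MirroredNetwork(net, origin_seg, origin_node)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _face_nodes(net: VesselNetwork, ax: int, hi: bool, tol: float) -> list[int]:
    w = net.box[ax]
    target = w if hi else 0.0
    return [nid for nid, n in net.nodes.items() if abs(n.position[ax] - target) <= tol]


def _periodic_pairs(net: VesselNetwork, lateral_ax: int, tol: float):
    """Match lo-face nodes to hi-face nodes by their in-face coordinates."""
    lo_nodes = _face_nodes(net, lateral_ax, False, tol)
    hi_nodes = _face_nodes(net, lateral_ax, True, tol)
    other = [a for a in range(3) if a != lateral_ax]

    def key(nid):
        p = net.nodes[nid].position
        return tuple(np.round([p[a] for a in other], 6))

    hi_by_key = {}
    for nid in hi_nodes:
        hi_by_key.setdefault(key(nid), []).append(nid)
    pairs = []
    for nid in lo_nodes:
        partners = hi_by_key.get(key(nid), [])
        if len(partners) == 1:
            pairs.append((nid, partners[0]))
        elif not partners:
            logger.warning("lateral node %d on axis %d has no periodic partner", nid, lateral_ax)
        else:
            pairs.append((nid, partners[0]))
    return pairs


def conductance(radius: float, length: float, viscosity_mpas: float) -> float:
    """Poiseuille conductance g = πr⁴/(8μl) in μm³/(Pa·s)."""
    r = max(radius, MIN_RADIUS)
    mu = viscosity_mpas * 1e-3  # mPa·s -> Pa·s
    return math.pi * r**4 / (8.0 * mu * length)


def assemble_and_solve(
    mir: MirroredNetwork,
    direction: str,
    rheo: RheologyParams | None = None,
    solver: SolverConfig | None = None,
    hematocrit: dict[int, float] | None = None,
) -> HemodynamicState:
    """Solve the nodal-pressure system for one gradient direction.

    Dirichlet pressures p = L·∇p / 0 are imposed on the inflow/outflow
    faces normal to ``direction``; lateral periodic pairs are merged into
    single unknowns; interior nodes satisfy Kirchhoff's law. If the network
    does not span the two Dirichlet faces the result is a legitimate
    all-zero flow state, not an error. Per-segment viscosity comes from the
    rheology parameters and (optionally) a per-segment hematocrit map.
    """
    rheo = rheo or RheologyParams()
    solver = solver or SolverConfig()
    net = mir.network
    tol = net.face_tol
    d = AXES[direction]
    grad = solver.gradient_pa_per_um
    length_d = net.box[d]
    p_in = length_d * grad

    h0 = rheo.inlet_discharge_hematocrit
    hct = {sid: (hematocrit[sid] if hematocrit else h0) for sid in net.segments}
    visc = {sid: segment_viscosity(seg.radius, hct[sid], rheo) for sid, seg in net.segments.items()}
    g = {sid: conductance(seg.radius, seg.length, visc[sid]) for sid, seg in net.segments.items()}

    # Merge lateral periodic pairs (corner nodes chain across both axes).
    uf = _UnionFind(net.nodes)
    for ax in range(3):
        if ax == d:
            continue
        for a, b in _periodic_pairs(net, ax, tol):
            uf.union(a, b)

    dirichlet: dict[int, float] = {}
    for nid in _face_nodes(net, d, hi=False, tol=tol):
        dirichlet[uf.find(nid)] = p_in
    for nid in _face_nodes(net, d, hi=True, tol=tol):
        dirichlet[uf.find(nid)] = 0.0

    reps = sorted({uf.find(nid) for nid in net.nodes})
    unknown = [r for r in reps if r not in dirichlet]
    index = {r: i for i, r in enumerate(unknown)}
    n = len(unknown)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    for sid, seg in net.segments.items():
        ra, rb = uf.find(seg.node_a), uf.find(seg.node_b)
        if ra == rb:
            continue  # both endpoints merged into one unknown: no net contribution
        gs = g[sid]
        a_unknown, b_unknown = ra not in dirichlet, rb not in dirichlet
        if a_unknown:
            diag[index[ra]] += gs
        if b_unknown:
            diag[index[rb]] += gs
        if a_unknown and b_unknown:
            rows.append(index[ra]); cols.append(index[rb]); vals.append(-gs)
            rows.append(index[rb]); cols.append(index[ra]); vals.append(-gs)
        elif a_unknown:
            rhs[index[ra]] += gs * dirichlet[rb]
        elif b_unknown:
            rhs[index[rb]] += gs * dirichlet[ra]

    pressure_by_rep = dict(dirichlet)
    if n:
        # Pin components with no Dirichlet anchor (one diagonal bump each)
        # so the Laplacian block is nonsingular; they solve to p = 0.
        anchored = set()
        adj = nx.Graph()
        adj.add_nodes_from(range(n))
        for sid, seg in net.segments.items():
            ra, rb = uf.find(seg.node_a), uf.find(seg.node_b)
            if ra == rb:
                continue
            a_unknown, b_unknown = ra not in dirichlet, rb not in dirichlet
            if a_unknown and b_unknown:
                adj.add_edge(index[ra], index[rb])
            elif a_unknown:
                anchored.add(index[ra])
            elif b_unknown:
                anchored.add(index[rb])
        for comp in nx.connected_components(adj):
            if not comp & anchored:
                diag[min(comp)] += 1.0
        diag[diag == 0.0] = 1.0  # isolated merged nodes

        rows.extend(range(n)); cols.extend(range(n)); vals.extend(diag)
        a_mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        if n <= solver.direct_limit:
            p_vec = spla.spsolve(a_mat.tocsc(), rhs)
        else:
            p_vec, info = spla.cg(a_mat, rhs, rtol=solver.solver_tol,
                                  maxiter=solver.solver_max_iter)
            if info != 0:
                raise RuntimeError(f"iterative pressure solve failed (info={info})")
        for r, i in index.items():
            pressure_by_rep[r] = float(p_vec[i])

    pressure = {nid: pressure_by_rep[uf.find(nid)] for nid in net.nodes}
    flow, dp = {}, {}
    for sid, seg in net.segments.items():
        delta = pressure[seg.node_a] - pressure[seg.node_b]
        dp[sid] = delta
        flow[sid] = g[sid] * delta

    return HemodynamicState(pressure, flow, dp, visc, hct, direction, grad)


def surface_flux(mir: MirroredNetwork, state: HemodynamicState,
                 face_axis: str | None = None, hi: bool = True) -> float:
    """Net outward volumetric flux (μm³/s) through one face of the domain.

    Defaults to the outflow face of the solved gradient direction. For a
    segment with an endpoint on the face, flow directed toward that
    endpoint leaves the domain there; segments lying within the face
    contribute their two endpoints with opposite signs (zero net).
    """
    net = mir.network
    ax = AXES[face_axis or state.gradient_direction]
    tol = net.face_tol
    w = net.box[ax]
    target = w if hi else 0.0
    total = 0.0
    for sid, seg in net.segments.items():
        q = state.flow[sid]
        if abs(net.nodes[seg.node_b].position[ax] - target) <= tol:
            total += q
        if abs(net.nodes[seg.node_a].position[ax] - target) <= tol:
            total -= q
    return total if hi else -total
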