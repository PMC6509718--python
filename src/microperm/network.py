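"""Geometric-graph data model for 3D microvascular networks.

A vascular network is a collection of nodes (3D positions in micrometers)
joined by radius-bearing segments, embedded in a rectangular domain box.
Segments carry a geodesic length that may exceed the Euclidean endpoint
distance (tortuous centerlines). Nodes that lie on a domain face are tagged
so that boundary conditions and blind-end pruning can distinguish vessels
that genuinely reach the tissue border from interior dead ends.

Units: lengths and positions in μm throughout. Pressures are Pa internally
(mm Hg only at user interfaces), viscosity mPa·s at interfaces, flows μm³/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "FACE_NAMES",
    "Node",
    "Segment",
    "VesselNetwork",
    "Subnetwork",
    "NetworkValidationError",
    "EdgeListParseError",
    "segment_volume",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
]

#: Face names in axis order; "lo"/"hi" refer to the lower/upper box face.
FACE_NAMES = ("x_lo", "x_hi", "y_lo", "y_hi", "z_lo", "z_hi")

#: Default tolerance (μm) for considering a node to lie on a box face.
DEFAULT_FACE_TOL = 1.0

#: Tolerance slack (μm) allowed when checking length ≥ Euclidean distance.
LENGTH_TOL = 1e-6


class NetworkValidationError(ValueError):
    """A network violates a structural invariant (bad radius, dangling id...)."""


class EdgeListParseError(ValueError):
    """An edge-list file could not be parsed; the message names the line."""


@dataclass
class Node:
    id: int
    position: np.ndarray  # shape (3,), μm
    face_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise NetworkValidationError(f"node {self.id}: position must be a 3-vector")
        self.face_tags = frozenset(self.face_tags)


@dataclass
class Segment:
    id: int
    node_a: int
    node_b: int
    radius: float  # μm
    length: float  # μm, geodesic
    component_id: int | None = None

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise NetworkValidationError(f"segment {self.id}: self-loop at node {self.node_a}")
        if not self.radius > 0:
            raise NetworkValidationError(f"segment {self.id}: radius must be > 0, got {self.radius}")
        if not self.length > 0:
            raise NetworkValidationError(f"segment {self.id}: length must be > 0, got {self.length}")


def segment_volume(seg: Segment) -> float:
    """Cylinder volume π r² l of one segment, μm³."""
    return math.pi * seg.radius**2 * seg.length


def face_tags_for_position(pos: np.ndarray, box: np.ndarray, face_tol: float) -> frozenset[str]:
    """Faces of ``box`` within ``face_tol`` of ``pos`` (pure function of its inputs)."""
    tags = set()
    for ax, name in enumerate("xyz"):
        if pos[ax] <= face_tol:
            tags.add(f"{name}_lo")
        if pos[ax] >= box[ax] - face_tol:
            tags.add(f"{name}_hi")
    return frozenset(tags)


@dataclass
class VesselNetwork:
    """A vascular graph inside a rectangular domain ``box`` (μm extents)."""

    nodes: dict[int, Node] = field(default_factory=dict)
    segments: dict[int, Segment] = field(default_factory=dict)
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: str = ""
    face_tol: float = DEFAULT_FACE_TOL

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        node_ids,
        positions,
        seg_ids,
        node_a,
        node_b,
        radii,
        lengths=None,
        box=(0.0, 0.0, 0.0),
        provenance: str = "",
        face_tol: float = DEFAULT_FACE_TOL,
    ) -> "VesselNetwork":
        positions = np.asarray(positions, dtype=float)
        box = np.asarray(box, dtype=float)
        nodes = {
            int(nid): Node(int(nid), positions[k], face_tags_for_position(positions[k], box, face_tol))
            for k, nid in enumerate(node_ids)
        }
        segments = {}
        for k, sid in enumerate(seg_ids):
            a, b = int(node_a[k]), int(node_b[k])
            if lengths is None or lengths[k] is None or (isinstance(lengths[k], float) and math.isnan(lengths[k])):
                length = float(np.linalg.norm(nodes[a].position - nodes[b].position))
            else:
                length = float(lengths[k])
            segments[int(sid)] = Segment(int(sid), a, b, float(radii[k]), length)
        net = cls(nodes, segments, box, provenance, face_tol)
        net.validate()
        return net

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if not np.all(self.box > 0) and (self.nodes or self.segments):
            raise NetworkValidationError("box extents must be positive")
        for node in self.nodes.values():
            if np.any(node.position < -self.face_tol) or np.any(node.position > self.box + self.face_tol):
                raise NetworkValidationError(f"node {node.id}: position {node.position} outside box {self.box}")
        for seg in self.segments.values():
            for nid in (seg.node_a, seg.node_b):
                if nid not in self.nodes:
                    raise NetworkValidationError(f"segment {seg.id}: endpoint {nid} does not exist")
            d = float(np.linalg.norm(self.nodes[seg.node_a].position - self.nodes[seg.node_b].position))
            if seg.length < d - max(LENGTH_TOL, 1e-9 * d):
                raise NetworkValidationError(
                    f"segment {seg.id}: geodesic length {seg.length} < Euclidean distance {d}"
                )

    # -- derived quantities ------------------------------------------------

    def retag_faces(self) -> None:
        """Recompute every node's face tags from position, box and face_tol."""
        for node in self.nodes.values():
            node.face_tags = face_tags_for_position(node.position, self.box, self.face_tol)

    def degree(self) -> dict[int, int]:
        deg = {nid: 0 for nid in self.nodes}
        for seg in self.segments.values():
            deg[seg.node_a] += 1
            deg[seg.node_b] += 1
        return deg

    def total_volume(self) -> float:
        return sum(segment_volume(s) for s in self.segments.values())

    def to_graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments.values():
            g.add_edge(seg.node_a, seg.node_b, key=seg.id, segment_id=seg.id)
        return g

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of the axis-aligned bounding box of used nodes."""
        used = {s.node_a for s in self.segments.values()} | {s.node_b for s in self.segments.values()}
        if not used:
            return np.zeros(3), np.zeros(3)
        pos = np.array([self.nodes[n].position for n in used])
        return pos.min(axis=0), pos.max(axis=0)

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            {nid: Node(n.id, n.position.copy(), n.face_tags) for nid, n in self.nodes.items()},
            {sid: replace(s) for sid, s in self.segments.items()},
            self.box.copy(),
            self.provenance,
            self.face_tol,
        )

    def subgraph(self, segment_ids) -> "VesselNetwork":
        """Restriction to the given segments (nodes kept iff incident)."""
        segs = {sid: replace(self.segments[sid]) for sid in segment_ids}
        used = {s.node_a for s in segs.values()} | {s.node_b for s in segs.values()}
        nodes = {nid: Node(n.id, n.position.copy(), n.face_tags) for nid, n in self.nodes.items() if nid in used}
        return VesselNetwork(nodes, segs, self.box.copy(), self.provenance, self.face_tol)


@dataclass
class Subnetwork:
    """One fully connected component of a parent network, with pruning metadata.

    ``volume_initial`` is the component's cylinder volume when it was
    retained by the density filter (V_init); ``volume_pruned`` the volume
    that survives blind-end elimination (V_cc). Their ratio drives the
    fusion-stage rescaling of permeability tensors.

    ``domain_lo``/``domain_hi`` delimit the rectangular volume the
    subnetwork is considered to occupy: the full parent box for a
    subnetwork built from a whole network (``from_network``), else the
    component's axis-aligned node bounding box. Mirroring, surface areas
    and the REV size gate all refer to this domain.
    """

    network: VesselNetwork
    component_id: int
    volume_initial: float
    volume_pruned: float | None = None
    domain_lo: np.ndarray | None = None
    domain_hi: np.ndarray | None = None

    @classmethod
    def from_network(cls, net: VesselNetwork, component_id: int = 0) -> "Subnetwork":
        """Wrap a whole network as one subnetwork occupying its full box."""
        vol = net.total_volume()
        return cls(net, component_id, volume_initial=vol, volume_pruned=vol,
                   domain_lo=np.zeros(3), domain_hi=net.box.copy())

    def domain_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.domain_lo is not None and self.domain_hi is not None:
            return self.domain_lo, self.domain_hi
        return self.network.bbox()

    def bbox_extents(self) -> np.ndarray:
        lo, hi = self.domain_bounds()
        return hi - lo

    def volume_ratio(self) -> float:
        """V_pruned / V_init ∈ (0, 1]."""
        if not self.volume_initial > 0:
            raise ValueError("volume_initial must be positive")
        v = self.volume_pruned if self.volume_pruned is not None else self.network.total_volume()
        return v / self.volume_initial


# ---------------------------------------------------------------------------
# Edge-list I/O
#
# Dialect: comma-separated values with '#'-prefixed header records. The
# "# box Nx Ny Nz" record carries the domain extents. Column order:
# segment_id,node_a,node_b,xa,ya,za,xb,yb,zb,radius_um[,length_um]
# ---------------------------------------------------------------------------

_COLUMNS = "segment_id,node_a,node_b,xa,ya,za,xb,yb,zb,radius_um,length_um"


def read_edge_list(path, box=None, face_tol: float = DEFAULT_FACE_TOL) -> VesselNetwork:
    """Read a CSV edge list into a validated :class:`VesselNetwork`.

    Missing ``length_um`` entries are filled with the Euclidean endpoint
    distance. ``box`` may come from the "# box" header record or the
    argument (the argument wins if both are given).
    """
    header_box = None
    provenance = ""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("box"):
                    parts = body.split()
                    if len(parts) != 4:
                        raise EdgeListParseError(f"{path}:{lineno}: malformed box record: {line!r}")
                    header_box = np.array([float(p) for p in parts[1:]])
                elif body.startswith("provenance"):
                    provenance = body[len("provenance"):].strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == "segment_id":  # column header line
                continue
            if len(parts) not in (10, 11):
                raise EdgeListParseError(f"{path}:{lineno}: expected 10 or 11 fields, got {len(parts)}")
            try:
                sid, a, b = int(parts[0]), int(parts[1]), int(parts[2])
                coords = [float(p) for p in parts[3:9]]
                radius = float(parts[9])
                length = float(parts[10]) if len(parts) == 11 and parts[10] != "" else None
            except ValueError as exc:
                raise EdgeListParseError(f"{path}:{lineno}: {exc}") from None
            rows.append((lineno, sid, a, b, coords, radius, length))

    if box is None:
        box = header_box
    if box is None:
        raise EdgeListParseError(f"{path}: no '# box Nx Ny Nz' header and no box argument")
    box = np.asarray(box, dtype=float)

    nodes: dict[int, Node] = {}
    segments: dict[int, Segment] = {}
    for lineno, sid, a, b, coords, radius, length in rows:
        pa, pb = np.array(coords[:3]), np.array(coords[3:])
        for nid, p in ((a, pa), (b, pb)):
            if nid in nodes and not np.allclose(nodes[nid].position, p, atol=1e-9):
                raise EdgeListParseError(
                    f"{path}:{lineno}: node {nid} re-declared at a different position"
                )
            if nid not in nodes:
                if np.any(p < -face_tol) or np.any(p > box + face_tol):
                    raise NetworkValidationError(
                        f"{path}:{lineno}: node {nid} at {p} outside box {box}"
                    )
                nodes[nid] = Node(nid, p, face_tags_for_position(p, box, face_tol))
        if length is None:
            length = float(np.linalg.norm(pa - pb))
        if sid in segments:
            raise EdgeListParseError(f"{path}:{lineno}: duplicate segment id {sid}")
        try:
            segments[sid] = Segment(sid, a, b, radius, length)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"{path}:{lineno}: {exc}") from None

    net = VesselNetwork(nodes, segments, box, provenance, face_tol)
    net.validate()
    return net


def write_edge_list(net: VesselNetwork, path) -> None:
    """Write the documented CSV dialect; round-trips through read_edge_list."""
    with open(path, "w") as fh:
        fh.write(f"# box {float(net.box[0])!r} {float(net.box[1])!r} {float(net.box[2])!r}\n")
        if net.provenance:
            fh.write(f"# provenance {net.provenance}\n")
        fh.write(_COLUMNS + "\n")
        for sid in sorted(net.segments):
            s = net.segments[sid]
            pa = net.nodes[s.node_a].position
            pb = net.nodes[s.node_b].position
            fields = [str(sid), str(s.node_a), str(s.node_b)]
            fields += [repr(float(v)) for v in (*pa, *pb)]
            fields += [repr(float(s.radius)), repr(float(s.length))]
            fh.write(",".join(fields) + "\n")


def write_graphml(net: VesselNetwork, path) -> None:
    g = nx.MultiGraph(box_x=float(net.box[0]), box_y=float(net.box[1]),
                      box_z=float(net.box[2]), provenance=net.provenance)
    for nid, node in net.nodes.items():
        g.add_node(nid, x=float(node.position[0]), y=float(node.position[1]),
                   z=float(node.position[2]))
    for sid, s in net.segments.items():
        # node_a/node_b recorded explicitly: MultiGraph edges are unordered
        g.add_edge(s.node_a, s.node_b, key=sid, segment_id=sid,
                   node_a=int(s.node_a), node_b=int(s.node_b),
                   radius_um=float(s.radius), length_um=float(s.length))
    nx.write_graphml(g, path)


def read_graphml(path, face_tol: float = DEFAULT_FACE_TOL) -> VesselNetwork:
    g = nx.read_graphml(path, node_type=int, force_multigraph=True)
    box = np.array([g.graph["box_x"], g.graph["box_y"], g.graph["box_z"]])
    nodes = {
        int(nid): Node(int(nid), np.array([d["x"], d["y"], d["z"]]),
                       face_tags_for_position(np.array([d["x"], d["y"], d["z"]]), box, face_tol))
        for nid, d in g.nodes(data=True)
    }
    segments = {}
    for a, b, d in g.edges(data=True):
        sid = int(d["segment_id"])
        na, nb = int(d.get("node_a", a)), int(d.get("node_b", b))
        segments[sid] = Segment(sid, na, nb, float(d["radius_um"]), float(d["length_um"]))
    net = VesselNetwork(nodes, segments, box, g.graph.get("provenance", ""), face_tol)
    net.validate()
    return net
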