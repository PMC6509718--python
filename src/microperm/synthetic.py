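"""Seeded generators for synthetic microvascular networks.

Two families of fixtures:

* Closed-form fixtures (single tube, parallel tubes, cubic lattice) whose
  permeability tensors are known analytically and anchor the numerical
  pipeline. The lattice is staggered at half-pitch offsets so that the
  mirrored lattice is exactly spatially periodic (one tube per s²
  cross-section, no tube inside a face plane) and the diagonal matches the
  unit-cell value πr⁴/(8μs²).

* Capillary-bed emulations: a jittered cubic lattice with log-normal radii
  (median ≈ 4 μm, σ_log ≈ 0.3, capillary-dominated), a deleted-segment
  fraction creating blind ends, and a detached corner block providing a
  secondary connected component — the fragmentation anatomical confocal
  reconstructions exhibit. An MI-like perturbation enlarges a random
  fraction of vessels and deletes a fraction of the smallest ones
  (the larger-vessels / capillary-loss phenotype of the infarcted bed).

All generators are deterministic under an explicit seed and their outputs
pass network validation and round-trip through the edge-list I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Node, Segment, VesselNetwork, face_tags_for_position

__all__ = [
    "SyntheticSpec",
    "make_single_tube",
    "make_parallel_tubes",
    "make_cubic_lattice",
    "make_random_capillary",
    "perturb_mi_like",
]

@dataclass
class SyntheticSpec:
    """Parameters of a random capillary-bed emulation."""

    box: tuple[float, float, float] = (200.0, 200.0, 100.0)
    spacing: float = 25.0            # μm, lattice pitch before jitter
    radius_median: float = 4.0       # μm, log-normal median
    radius_sigma_log: float = 0.3    # log-space standard deviation
    jitter: float = 5.0              # μm, uniform node displacement amplitude
    blind_end_fraction: float = 0.1  # fraction of segments deleted at random
    corner_block: float = 0.2        # fraction of each extent detached as a second component
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.blind_end_fraction, self.corner_block):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def make_single_tube(box=(100.0, 100.0, 100.0), radius: float = 4.0) -> VesselNetwork:
    """One axial segment spanning the x faces through the box center."""
    box = np.asarray(box, dtype=float)
    if not radius < min(box) / 2:
        raise ValueError("radius must be smaller than half the smallest box side")
    yc, zc = box[1] / 2, box[2] / 2
    return VesselNetwork.from_arrays(
        node_ids=[0, 1],
        positions=[[0.0, yc, zc], [box[0], yc, zc]],
        seg_ids=[0], node_a=[0], node_b=[1], radii=[radius],
        box=box, provenance="synthetic single tube",
    )


def make_parallel_tubes(box=(100.0, 100.0, 100.0), radius: float = 4.0,
                        n_tubes: int = 2) -> VesselNetwork:
    """``n_tubes`` disjoint axial tubes spanning the x faces, spread along y."""
    box = np.asarray(box, dtype=float)
    ys = np.linspace(box[1] / (n_tubes + 1), n_tubes * box[1] / (n_tubes + 1), n_tubes)
    node_ids, positions, seg_ids, na, nb = [], [], [], [], []
    for t, y in enumerate(ys):
        node_ids += [2 * t, 2 * t + 1]
        positions += [[0.0, y, box[2] / 2], [box[0], y, box[2] / 2]]
        seg_ids.append(t)
        na.append(2 * t)
        nb.append(2 * t + 1)
    return VesselNetwork.from_arrays(node_ids, positions, seg_ids, na, nb,
                                     radii=[radius] * n_tubes, box=box,
                                     provenance="synthetic parallel tubes")


def make_cubic_lattice(box=(200.0, 200.0, 200.0), spacing: float = 50.0,
                       radius: float = 4.0) -> VesselNetwork:
    """Staggered 3D grid with one tube per ``spacing``² cross-section.

    ``spacing`` must divide every box extent. Grid planes sit at half-pitch
    offsets (s/2, 3s/2, …, L−s/2) with stub segments extending each line to
    the two faces, so every face is reached by tube *endpoints* but no tube
    lies inside a face. The mirrored lattice is then exactly spatially
    periodic with tube density 1/s² in every direction, and the tensor
    diagonal equals the unit-cell value πr⁴/(8μs²) up to solver round-off.
    All radii are equal.
    """
    box = np.asarray(box, dtype=float)
    counts = box / spacing
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("spacing must divide every box extent")
    n = np.round(counts).astype(int)  # grid planes per axis (one per cell)

    def nid(i, j, k):
        return (i * n[1] + j) * n[2] + k

    node_ids, positions = [], []
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                node_ids.append(nid(i, j, k))
                positions.append([(i + 0.5) * spacing, (j + 0.5) * spacing,
                                  (k + 0.5) * spacing])
    next_nid = n[0] * n[1] * n[2]

    seg_ids, na, nb, radii = [], [], [], []

    def add_seg(a, b):
        seg_ids.append(len(seg_ids))
        na.append(a)
        nb.append(b)
        radii.append(radius)

    for ax in range(3):
        step = [(1, 0, 0), (0, 1, 0), (0, 0, 1)][ax]
        for i in range(n[0]):
            for j in range(n[1]):
                for k in range(n[2]):
                    ii, jj, kk = i + step[0], j + step[1], k + step[2]
                    if ii < n[0] and jj < n[1] and kk < n[2]:
                        add_seg(nid(i, j, k), nid(ii, jj, kk))
                    idx = (i, j, k)[ax]
                    if idx == 0:  # stub to the lower face
                        pos = positions[nid(i, j, k)].copy()
                        pos[ax] = 0.0
                        node_ids.append(next_nid)
                        positions.append(pos)
                        add_seg(next_nid, nid(i, j, k))
                        next_nid += 1
                    if idx == n[ax] - 1:  # stub to the upper face
                        pos = positions[nid(i, j, k)].copy()
                        pos[ax] = box[ax]
                        node_ids.append(next_nid)
                        positions.append(pos)
                        add_seg(nid(i, j, k), next_nid)
                        next_nid += 1
    return VesselNetwork.from_arrays(node_ids, positions, seg_ids, na, nb, radii,
                                     box=box, provenance="synthetic cubic lattice")


def _spans_x(net: VesselNetwork) -> bool:
    """True if some connected component touches both x faces of the box."""
    g = net.to_graph()
    lo = {nid for nid, node in net.nodes.items() if "x_lo" in node.face_tags}
    hi = {nid for nid, node in net.nodes.items() if "x_hi" in node.face_tags}
    for comp in nx.connected_components(g):
        if comp & lo and comp & hi:
            return True
    return False


def make_random_capillary(spec: SyntheticSpec) -> VesselNetwork:
    """Perturbed-lattice capillary bed: jitter, log-normal radii, blind ends.

    Starting from a cubic lattice, interior nodes are jittered, radii are
    drawn log-normal, a fraction of segments is deleted at random (creating
    blind ends), and the segments crossing into a corner block are cut so
    the block becomes a secondary connected component. Regenerates with a
    shifted seed (up to 10 attempts) if no component spans the x faces.
    """
    for attempt in range(10):
        rng = np.random.default_rng(spec.seed + 1_000_003 * attempt)
        net = make_cubic_lattice(spec.box, spec.spacing, radius=spec.radius_median)
        box = net.box
        # jitter interior coordinates only: face nodes stay on their faces
        for node in net.nodes.values():
            for ax in range(3):
                if node.position[ax] <= net.face_tol or node.position[ax] >= box[ax] - net.face_tol:
                    continue
                delta = rng.uniform(-spec.jitter, spec.jitter)
                node.position[ax] = float(np.clip(node.position[ax] + delta,
                                                  net.face_tol * 1.5,
                                                  box[ax] - net.face_tol * 1.5))
        net.retag_faces()
        mu_log = np.log(spec.radius_median)
        for sid in sorted(net.segments):
            seg = net.segments[sid]
            seg.radius = float(rng.lognormal(mu_log, spec.radius_sigma_log))
            seg.length = float(np.linalg.norm(net.nodes[seg.node_a].position
                                              - net.nodes[seg.node_b].position))

        # detach a corner block as a secondary component
        corner = box * spec.corner_block
        if spec.corner_block > 0:
            def in_corner(nid_):
                return bool(np.all(net.nodes[nid_].position <= corner + 1e-9))
            crossing = [sid for sid, s in net.segments.items()
                        if in_corner(s.node_a) != in_corner(s.node_b)]
            for sid in crossing:
                del net.segments[sid]

        # deletions that provably leave blind ends: strip randomly chosen
        # interior nodes down to degree 1 until the budget is spent
        budget = int(spec.blind_end_fraction * len(net.segments))
        interior = [nid for nid, node in net.nodes.items() if not node.face_tags]
        rng.shuffle(interior)
        for nid_ in interior:
            if budget <= 0:
                break
            incident = sorted(sid for sid, s in net.segments.items()
                              if nid_ in (s.node_a, s.node_b))
            if len(incident) < 2:
                continue
            doomed = incident[: len(incident) - 1]
            for sid in doomed[:budget]:
                del net.segments[sid]
            budget -= len(doomed)

        used = {s.node_a for s in net.segments.values()} | {s.node_b for s in net.segments.values()}
        net.nodes = {nid: n for nid, n in net.nodes.items() if nid in used}
        net.provenance = f"synthetic capillary bed seed={spec.seed}"
        if _spans_x(net):
            net.validate()
            return net
    raise RuntimeError("could not generate a spanning capillary network in 10 attempts")


def perturb_mi_like(net: VesselNetwork, enlarge_fraction: float = 0.2,
                    enlarge_factor: float = 1.5, disconnect_fraction: float = 0.1,
                    seed: int = 0) -> VesselNetwork:
    """Infarct-like remodeling: enlarge some vessels, lose small capillaries.

    A seeded random ``enlarge_fraction`` of segments get radius ×
    ``enlarge_factor``; a seeded random ``disconnect_fraction`` is deleted,
    drawn from the below-median-radius half (capillary loss). With both
    fractions zero this is the identity.
    """
    out = net.copy()
    rng = np.random.default_rng(seed)
    seg_ids = sorted(out.segments)
    if enlarge_fraction > 0:
        n_pick = int(round(enlarge_fraction * len(seg_ids)))
        for idx in rng.choice(len(seg_ids), size=n_pick, replace=False):
            out.segments[seg_ids[idx]].radius *= enlarge_factor
    if disconnect_fraction > 0:
        radii = np.array([out.segments[sid].radius for sid in seg_ids])
        eligible = [sid for sid, r in zip(seg_ids, radii) if r <= np.median(radii)]
        n_del = min(int(round(disconnect_fraction * len(seg_ids))), len(eligible))
        for idx in rng.choice(len(eligible), size=n_del, replace=False):
            del out.segments[eligible[idx]]
        used = {s.node_a for s in out.segments.values()} | {s.node_b for s in out.segments.values()}
        out.nodes = {nid: n for nid, n in out.nodes.items() if nid in used}
    out.provenance = net.provenance + " + MI-like perturbation"
    return out
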