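"""Turn raw anatomical networks into solver-ready subnetworks.

Anatomical microvascular reconstructions arrive fragmented (multiple
connected components, possibly pathology-related disconnections that must
be preserved) and carry blind ends — branches attached at only one junction
that never reach the tissue border. The continuum flow model requires fully
connected networks without blind ends, so the pipeline is:

    label components → density filter (≥15% of vascular volume) →
    elongate near-border end branches onto the border →
    iteratively prune interior blind ends → REV size gate (x–y ≥ 170 μm)

"Vascular density" is implemented as the cylinder-volume fraction Σπr²l,
the graph analogue of image vascular density. No gap-closing is attempted:
disconnections may be pathology related and are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import Subnetwork, VesselNetwork, segment_volume

__all__ = [
    "PreprocessReport",
    "label_components",
    "filter_by_density",
    "elongate_border_ends",
    "prune_blind_ends",
    "rev_gate",
    "volume_ratio",
    "preprocess",
    "DENSITY_THRESHOLD",
    "ELONGATION_EPSILON",
    "REV_CUTOFF",
]

DENSITY_THRESHOLD = 0.15  # retain components with ≥ 15% of total vascular volume
ELONGATION_EPSILON = 5.0  # μm; end branches this close to a border are extended onto it
REV_CUTOFF = 170.0        # μm; minimum x and y bbox side for a representative volume


@dataclass
class PreprocessReport:
    """Per-stage bookkeeping of one preprocessing run."""

    density_fractions: dict[int, float] = field(default_factory=dict)
    retained_components: list[int] = field(default_factory=list)
    elongated_nodes: dict[int, int] = field(default_factory=dict)      # component -> count
    pruned_segments: dict[int, int] = field(default_factory=dict)      # component -> count
    volume_initial: dict[int, float] = field(default_factory=dict)
    volume_pruned: dict[int, float] = field(default_factory=dict)
    rev_pass: dict[int, bool] = field(default_factory=dict)
    empty_after_pruning: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "density_fractions": {str(k): v for k, v in self.density_fractions.items()},
            "retained_components": self.retained_components,
            "elongated_nodes": {str(k): v for k, v in self.elongated_nodes.items()},
            "pruned_segments": {str(k): v for k, v in self.pruned_segments.items()},
            "volume_initial_um3": {str(k): v for k, v in self.volume_initial.items()},
            "volume_pruned_um3": {str(k): v for k, v in self.volume_pruned.items()},
            "rev_pass": {str(k): v for k, v in self.rev_pass.items()},
            "empty_after_pruning": self.empty_after_pruning,
        }


def label_components(net: VesselNetwork) -> VesselNetwork:
    """Assign dense component ids ordered by descending vascular volume.

    Two segments share a component id iff their endpoints are joined by a
    node path. Ties in volume break by smallest segment id for determinism.
    """
    out = net.copy()
    g = out.to_graph()
    comps = []
    for nodeset in nx.connected_components(g):
        seg_ids = sorted(
            sid for sid, s in out.segments.items() if s.node_a in nodeset
        )
        if not seg_ids:
            continue  # isolated node
        vol = sum(segment_volume(out.segments[sid]) for sid in seg_ids)
        comps.append((vol, seg_ids))
    comps.sort(key=lambda c: (-c[0], c[1][0]))
    for cid, (_, seg_ids) in enumerate(comps):
        for sid in seg_ids:
            out.segments[sid].component_id = cid
    return out


def filter_by_density(net: VesselNetwork, threshold: float = DENSITY_THRESHOLD,
                      report: PreprocessReport | None = None) -> list[Subnetwork]:
    """Retain components holding at least ``threshold`` of total vascular volume.

    The threshold is inclusive ("at least 15%"). Each retained component
    becomes a :class:`Subnetwork` carrying its retained volume as V_init.
    """
    total = net.total_volume()
    if total == 0:
        return []
    by_comp: dict[int, list[int]] = {}
    for sid, seg in net.segments.items():
        if seg.component_id is None:
            raise ValueError("components must be labeled before density filtering")
        by_comp.setdefault(seg.component_id, []).append(sid)
    subs = []
    for cid in sorted(by_comp):
        vol = sum(segment_volume(net.segments[sid]) for sid in by_comp[cid])
        frac = vol / total
        if report is not None:
            report.density_fractions[cid] = frac
        if frac >= threshold:
            sub_net = net.subgraph(by_comp[cid])
            subs.append(Subnetwork(sub_net, cid, volume_initial=vol))
            if report is not None:
                report.retained_components.append(cid)
                report.volume_initial[cid] = vol
    return subs


def elongate_border_ends(sub: Subnetwork, epsilon: float = ELONGATION_EPSILON,
                         report: PreprocessReport | None = None) -> Subnetwork:
    """Extend near-border end branches onto the border so they are not pruned.

    Every degree-1 node whose perpendicular distance to a domain face is
    within ``epsilon`` is translated onto the nearest such face along the
    face normal; its incident segment's length grows by the displacement and
    the node is face-tagged. Ties between faces break toward the lower axis
    index (x before y before z).
    """
    net = sub.network.copy()
    box = net.box
    deg = net.degree()
    n_moved = 0
    for nid, d in deg.items():
        if d != 1:
            continue
        node = net.nodes[nid]
        # candidate faces within epsilon: (distance, axis, is_hi)
        cands = []
        for ax in range(3):
            lo_dist = node.position[ax]
            hi_dist = box[ax] - node.position[ax]
            if lo_dist <= epsilon:
                cands.append((lo_dist, ax, False))
            if hi_dist <= epsilon:
                cands.append((hi_dist, ax, True))
        if not cands:
            continue
        cands.sort(key=lambda c: (c[0], c[1]))
        dist, ax, is_hi = cands[0]
        if dist <= net.face_tol:
            continue  # already effectively on the face; retagging handles it
        node.position[ax] = box[ax] if is_hi else 0.0
        seg = next(s for s in net.segments.values() if nid in (s.node_a, s.node_b))
        seg.length += dist
        n_moved += 1
    net.retag_faces()
    if report is not None:
        report.elongated_nodes[sub.component_id] = n_moved
    return Subnetwork(net, sub.component_id, sub.volume_initial, sub.volume_pruned)


def prune_blind_ends(sub: Subnetwork, report: PreprocessReport | None = None) -> Subnetwork:
    """Iteratively remove segments hanging off interior degree-1 nodes.

    Blind ends are assumed to be sprouts or imaging artifacts that carry no
    flow. Removal cascades: pruning one branch may expose another interior
    end node. Face-tagged degree-1 nodes (vessels reaching the border) are
    never pruned. Idempotent. Sets ``volume_pruned`` on the result.
    """
    net = sub.network.copy()
    n_pruned = 0
    while True:
        deg = net.degree()
        doomed = [
            sid for sid, s in net.segments.items()
            if (deg[s.node_a] == 1 and not net.nodes[s.node_a].face_tags)
            or (deg[s.node_b] == 1 and not net.nodes[s.node_b].face_tags)
        ]
        if not doomed:
            break
        for sid in doomed:
            del net.segments[sid]
        n_pruned += len(doomed)
        used = {s.node_a for s in net.segments.values()} | {s.node_b for s in net.segments.values()}
        net.nodes = {nid: n for nid, n in net.nodes.items() if nid in used}
    if report is not None:
        report.pruned_segments[sub.component_id] = n_pruned
        report.volume_pruned[sub.component_id] = net.total_volume()
        if not net.segments:
            report.empty_after_pruning.append(sub.component_id)
    out = Subnetwork(net, sub.component_id, sub.volume_initial, volume_pruned=net.total_volume())
    if net.segments:
        _assign_domain(out)
    return out


def _assign_domain(sub: Subnetwork) -> None:
    """Fix the occupied domain to the post-pruning node bounding box.

    An axis along which the component is geometrically flat (a line or
    plane has no cross-section of its own) falls back to the full parent
    extent: the vessel is taken to drain the image volume it sits in.
    """
    lo, hi = sub.network.bbox()
    lo, hi = lo.copy(), hi.copy()
    for ax in range(3):
        if hi[ax] - lo[ax] < sub.network.face_tol:
            lo[ax], hi[ax] = 0.0, sub.network.box[ax]
    sub.domain_lo, sub.domain_hi = lo, hi


def rev_gate(sub: Subnetwork, cutoff: float = REV_CUTOFF,
             report: PreprocessReport | None = None) -> bool:
    """True iff the post-pruning bbox spans ≥ ``cutoff`` μm along both x and y.

    Below this side length the homogenized tensor is not size-converged and
    would be unreliable; such subnetworks are excluded from fusion. The gate
    is inclusive and applies to x and y only (sample thickness along z is
    far below the cutoff).
    """
    ext = sub.bbox_extents()
    ok = bool(ext[0] >= cutoff and ext[1] >= cutoff)
    if report is not None:
        report.rev_pass[sub.component_id] = ok
    return ok


def volume_ratio(sub: Subnetwork) -> float:
    """V_pruned / V_init of a subnetwork, in (0, 1]."""
    return sub.volume_ratio()


def preprocess(
    net: VesselNetwork,
    threshold: float = DENSITY_THRESHOLD,
    epsilon: float = ELONGATION_EPSILON,
    rev_cutoff: float = REV_CUTOFF,
    apply_rev_gate: bool = True,
) -> tuple[list[Subnetwork], PreprocessReport]:
    """Full pipeline: label → filter → elongate → prune → REV gate.

    Returns the REV-passing, non-empty subnetworks and the stage report.
    """
    report = PreprocessReport()
    labeled = label_components(net)
    subs = filter_by_density(labeled, threshold, report)
    out = []
    for sub in subs:
        sub = elongate_border_ends(sub, epsilon, report)
        sub = prune_blind_ends(sub, report)
        if not sub.network.segments:
            continue
        passes = rev_gate(sub, rev_cutoff, report)
        if passes or not apply_rev_gate:
            out.append(sub)
    return out, report
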