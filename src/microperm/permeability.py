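"""Darcy permeability tensors of microvascular networks.

The tensor K relates the tissue-scale Darcy flux to the applied pressure
gradient. Each row i is obtained by applying a unit pressure gradient along
axis i across the mirrored domain and measuring the net volumetric flux
through the outflow face of each axis j:

    k_ij = (Σ_m q_m^j) / (S_j · ∇p^i)

with S_j the outflow surface area and q_m^j the Poiseuille flows of the
vessels crossing it. Diagonal entries are through-flow conductivities,
off-diagonals cross-flow. Internally k is carried in μm²/(Pa·s) and
reported in mm³·s/kg (1 μm²/(Pa·s) = 10⁻³ mm³·s/kg).

Tensors of the individual connected subnetworks of a volume are fused by a
surface-weighted average (flows of distinct subnetworks are independent and
add), with pairwise-overlap-corrected weights, and optionally rescaled by
V_init/V_pruned to compensate for the vascular volume lost to blind-end
elimination. Because confocal volume orientation is arbitrary, the axes are
finally sorted so k11 ≥ k22 ≥ k33.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import (
    AXES,
    HemodynamicState,
    MirroredNetwork,
    SolverConfig,
    assemble_and_solve,
    mirror_network,
    surface_flux,
)
from .network import Subnetwork, VesselNetwork
from .preprocess import REV_CUTOFF, preprocess
from .rheology import RheologyParams, update_hematocrit

__all__ = [
    "PermeabilityTensor",
    "FusionRecord",
    "UM2_PER_PAS_TO_MM3_S_PER_KG",
    "tensor_from_mirrored",
    "tensor_for_subnetwork",
    "tensor_with_phase_separation",
    "fuse_tensors",
    "sort_tensor",
    "rev_scan",
]

#: 1 μm²/(Pa·s) expressed in mm³·s/kg.
UM2_PER_PAS_TO_MM3_S_PER_KG = 1e-3

_DIRS = ("x", "y", "z")


@dataclass
class PermeabilityTensor:
    """3×3 conductivity tensor in mm³·s/kg with sorting metadata."""

    values: np.ndarray                      # (3, 3), mm³·s/kg
    sorted: bool = False
    permutation: tuple[int, int, int] = (0, 1, 2)
    hct_mode: str = "constant_hct"
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3, 3):
            raise ValueError("permeability tensor must be 3×3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("permeability tensor entries must be finite")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def __getitem__(self, idx):
        return self.values[idx]


@dataclass
class FusionRecord:
    """Per-subnetwork bookkeeping of one fusion: surfaces, weights, scales."""

    surfaces: dict[int, np.ndarray] = field(default_factory=dict)   # cc -> S_j, μm², j=x,y,z
    denominator: np.ndarray | None = None                           # overlap-corrected, per j
    weights: dict[int, np.ndarray] = field(default_factory=dict)    # cc -> w_j
    scales: dict[int, float] = field(default_factory=dict)          # cc -> V_init/V_pruned


def _tensor_from_states(mir: MirroredNetwork, states: dict[str, HemodynamicState],
                        hct_mode: str, converged: bool) -> PermeabilityTensor:
    box = mir.box
    k = np.zeros((3, 3))
    for i, di in enumerate(_DIRS):
        state = states[di]
        grad = state.applied_gradient
        for j, dj in enumerate(_DIRS):
            s_j = float(np.prod([box[a] for a in range(3) if a != j]))
            flux = surface_flux(mir, state, face_axis=dj, hi=True)
            k[i, j] = flux / (s_j * grad)
    return PermeabilityTensor(k * UM2_PER_PAS_TO_MM3_S_PER_KG,
                              hct_mode=hct_mode, converged=converged)


def tensor_from_mirrored(mir: MirroredNetwork, rheo: RheologyParams | None = None,
                         solver: SolverConfig | None = None) -> PermeabilityTensor:
    """Unsorted tensor of an already-mirrored network (constant-hematocrit)."""
    rheo = rheo or RheologyParams()
    solver = solver or SolverConfig()
    states = {d: assemble_and_solve(mir, d, rheo, solver) for d in _DIRS}
    return _tensor_from_states(mir, states, "constant_hct", True)


def tensor_for_subnetwork(sub: Subnetwork, rheo: RheologyParams | None = None,
                          solver: SolverConfig | None = None) -> PermeabilityTensor:
    """Mirror a preprocessed subnetwork and compute its unsorted tensor.

    In constant-hematocrit mode each segment's viscosity follows the
    in-vitro viscosity law at the inlet hematocrit (or the fixed Newtonian
    value if one is configured). Directions the network does not span come
    out as zero rows.
    """
    rheo = rheo or RheologyParams()
    if rheo.mode == "phase_separation":
        return tensor_with_phase_separation(sub, rheo, solver)
    return tensor_from_mirrored(mirror_network(sub), rheo, solver)


def tensor_with_phase_separation(sub: Subnetwork, rheo: RheologyParams | None = None,
                                 solver: SolverConfig | None = None) -> PermeabilityTensor:
    """Tensor with heterogeneous hematocrit from the phase-separation law.

    Per gradient direction, the flow solve and the damped hematocrit
    propagation are alternated — viscosity is recomputed from each
    segment's hematocrit every pass — until the largest hematocrit change
    falls below ``hct_tol`` or ``max_iter`` passes elapse (the last iterate
    is then returned flagged non-converged).
    """
    rheo = rheo or RheologyParams()
    solver = solver or SolverConfig()
    if rheo.mode != "phase_separation":
        raise ValueError("rheology mode must be 'phase_separation'")
    mir = mirror_network(sub)
    states: dict[str, HemodynamicState] = {}
    all_converged = True
    for d in _DIRS:
        hct = {sid: rheo.inlet_discharge_hematocrit for sid in mir.network.segments}
        state = assemble_and_solve(mir, d, rheo, solver, hematocrit=hct)
        converged = False
        for _ in range(rheo.max_iter):
            new_state = update_hematocrit(mir, state, rheo)
            delta = max(
                abs(new_state.hematocrit[sid] - state.hematocrit[sid])
                for sid in state.hematocrit
            ) if state.hematocrit else 0.0
            state = assemble_and_solve(mir, d, rheo, solver, hematocrit=new_state.hematocrit)
            if delta < rheo.hct_tol:
                converged = True
                break
        state.converged = converged
        all_converged &= converged
        states[d] = state
    return _tensor_from_states(mir, states, "phase_separation", all_converged)


def _projected_overlap(lo_a, hi_a, lo_b, hi_b, j: int) -> float:
    """Overlap area of two boxes projected onto the plane normal to axis j."""
    area = 1.0
    for a in range(3):
        if a == j:
            continue
        lo = max(lo_a[a], lo_b[a])
        hi = min(hi_a[a], hi_b[a])
        area *= max(0.0, hi - lo)
    return area


def fuse_tensors(records: list[tuple[Subnetwork, PermeabilityTensor]],
                 apply_scale: bool = True) -> tuple[PermeabilityTensor, FusionRecord]:
    """Surface-weighted fusion of subnetwork tensors into the volume tensor.

    k_ij(I) = Σ_cc w_j(cc) · [V_init/V_pruned](cc) · k_ij(cc), where
    w_j(cc) = S_j(cc) / (Σ S_j − Σ pairwise projected overlaps). With
    ``apply_scale`` False the blind-end volume-loss rescaling is skipped.
    All inputs must be unsorted tensors of the same hematocrit mode.
    """
    if not records:
        raise ValueError("fuse_tensors requires at least one record")
    modes = {t.hct_mode for _, t in records}
    if len(modes) > 1:
        raise ValueError("cannot fuse tensors of mixed hematocrit modes")
    if any(t.sorted for _, t in records):
        raise ValueError("fuse unsorted tensors; sort the fused result")

    rec = FusionRecord()
    bounds = {}
    for sub, _ in records:
        lo, hi = sub.domain_bounds()
        bounds[sub.component_id] = (lo, hi)
        rec.surfaces[sub.component_id] = np.array([
            float(np.prod([(hi - lo)[a] for a in range(3) if a != j])) for j in range(3)
        ])

    denom = np.zeros(3)
    for j in range(3):
        denom[j] = sum(s[j] for s in rec.surfaces.values())
        ids = sorted(bounds)
        for n_i in range(len(ids)):
            for k_i in range(n_i + 1, len(ids)):
                lo_a, hi_a = bounds[ids[n_i]]
                lo_b, hi_b = bounds[ids[k_i]]
                denom[j] -= _projected_overlap(lo_a, hi_a, lo_b, hi_b, j)
    if np.any(denom <= 0):
        raise ValueError("fusion denominator must be positive in every direction")
    rec.denominator = denom

    fused = np.zeros((3, 3))
    for sub, tensor in records:
        w = rec.surfaces[sub.component_id] / denom
        rec.weights[sub.component_id] = w
        scale = sub.volume_ratio()
        rec.scales[sub.component_id] = 1.0 / scale
        factor = (1.0 / scale) if apply_scale else 1.0
        fused += (w[np.newaxis, :] * factor) * tensor.values
    return PermeabilityTensor(fused, hct_mode=modes.pop()), rec


def sort_tensor(t: PermeabilityTensor) -> PermeabilityTensor:
    """Sort axes so the diagonal is descending (max-, medium-, min-flow).

    A simultaneous row+column permutation P·K·Pᵀ: off-diagonal (i, j) moves
    to (σ(i), σ(j)), preserving eigenvalues. Ties keep x, y, z order.
    """
    diag = np.diag(t.values)
    perm = tuple(int(i) for i in np.argsort(-diag, kind="stable"))
    p = np.eye(3)[list(perm)]
    values = p @ t.values @ p.T
    return PermeabilityTensor(values, sorted=True, permutation=perm,
                              hct_mode=t.hct_mode, converged=t.converged)


def _clip_to_box(net: VesselNetwork, lo: np.ndarray, hi: np.ndarray) -> VesselNetwork:
    """Restrict a network to an axis-aligned box, cutting crossing vessels.

    The graph analogue of decomposing an image volume into subvolumes:
    a segment crossing the box boundary is cut at the crossing point
    (parametric clip of the chord), leaving a new endpoint exactly on the
    box face; its geodesic length scales with the retained chord fraction.
    Coordinates are re-expressed relative to the box corner.
    """
    from .network import Node, Segment

    nodes: dict[int, Node] = {}
    segments: dict[int, Segment] = {}
    next_nid = max(net.nodes, default=-1) + 1
    eps = 1e-9

    def keep_node(nid):
        if nid not in nodes:
            src = net.nodes[nid]
            nodes[nid] = Node(nid, src.position - lo)
        return nid

    for sid, seg in net.segments.items():
        pa = net.nodes[seg.node_a].position
        pb = net.nodes[seg.node_b].position
        d = pb - pa
        t0, t1 = 0.0, 1.0
        for ax in range(3):  # Liang–Barsky interval clip
            if abs(d[ax]) < 1e-15:
                if pa[ax] < lo[ax] - eps or pa[ax] > hi[ax] + eps:
                    t0, t1 = 1.0, 0.0
                    break
                continue
            ta = (lo[ax] - pa[ax]) / d[ax]
            tb = (hi[ax] - pa[ax]) / d[ax]
            ta, tb = min(ta, tb), max(ta, tb)
            t0, t1 = max(t0, ta), min(t1, tb)
        if t1 - t0 <= eps:
            continue
        if t0 <= eps and t1 >= 1.0 - eps:
            a, b = keep_node(seg.node_a), keep_node(seg.node_b)
            length = seg.length
        else:
            if t0 <= eps:
                a = keep_node(seg.node_a)
            else:
                nodes[next_nid] = Node(next_nid, pa + t0 * d - lo)
                a, next_nid = next_nid, next_nid + 1
            if t1 >= 1.0 - eps:
                b = keep_node(seg.node_b)
            else:
                nodes[next_nid] = Node(next_nid, pb - (1.0 - t1) * d - lo)
                b, next_nid = next_nid, next_nid + 1
            length = seg.length * (t1 - t0)
        segments[sid] = Segment(sid, a, b, seg.radius, length)

    out = VesselNetwork(nodes, segments, hi - lo, net.provenance, net.face_tol)
    for node in out.nodes.values():
        node.position = np.clip(node.position, 0.0, out.box)
    out.retag_faces()
    return out


def rev_scan(net: VesselNetwork, unit_sizes: list[float],
             rheo: RheologyParams | None = None,
             solver: SolverConfig | None = None,
             rev_cutoff: float = REV_CUTOFF) -> list[dict]:
    """Tensor versus unit size: the representative-elementary-volume scan.

    The domain is partitioned along x–y into square units of each requested
    side (z is kept whole — sample thickness is far below any unit size);
    vessels crossing a unit border are cut at the border, exactly as
    decomposing an image volume cuts vessels at subvolume faces. The full
    per-unit pipeline (component filtering, elongation, pruning, REV gate,
    fusion) runs in each unit; units with nothing retained are counted as
    excluded. Returns one record per unit size with the per-unit sorted
    tensors and their median diagonal.
    """
    results = []
    for size in unit_sizes:
        nx_units = max(1, int(net.box[0] // size))
        ny_units = max(1, int(net.box[1] // size))
        unit_tensors = []
        excluded = 0
        for ix in range(nx_units):
            for iy in range(ny_units):
                lo = np.array([ix * size, iy * size, 0.0])
                hi = np.minimum(lo + np.array([size, size, net.box[2]]), net.box)
                unit_net = _clip_to_box(net, lo, hi)
                if not unit_net.segments:
                    excluded += 1
                    continue
                subs, _ = preprocess(unit_net, rev_cutoff=rev_cutoff)
                if not subs:
                    excluded += 1
                    continue
                tensors = [(s, tensor_for_subnetwork(s, rheo, solver)) for s in subs]
                fused, _ = fuse_tensors(tensors)
                unit_tensors.append(sort_tensor(fused))
        median = (
            np.median(np.array([t.diagonal for t in unit_tensors]), axis=0)
            if unit_tensors else None
        )
        results.append({
            "unit_size_um": float(size),
            "n_units": nx_units * ny_units,
            "n_excluded": excluded,
            "tensors": unit_tensors,
            "median_diagonal": median,
        })
    return results
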