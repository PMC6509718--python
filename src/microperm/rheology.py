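"""Blood rheology: apparent viscosity and red-cell phase separation.

Blood is not a simple fluid at the capillary scale. Its apparent viscosity
depends strongly on vessel diameter and hematocrit (the Fåhræus–Lindqvist
effect, with a minimum near 7 μm), and red cells partition unevenly at
diverging bifurcations (phase separation / plasma skimming), so hematocrit
is heterogeneous across a network. Both effects are described by the
empirical laws of Pries and co-workers, fitted to in-vitro data:

* the diameter/hematocrit-dependent relative apparent viscosity law, and
* the logit-form bifurcation law giving the erythrocyte flux fraction
  entering each daughter branch as a function of its blood-flow fraction,
  the diameter ratio, the feed diameter and the feed discharge hematocrit,
  with a zero-flux cutoff X0 below which a daughter receives plasma only.

``update_hematocrit`` propagates discharge hematocrit through a solved flow
field: segments are visited in topological order of flow direction (flow
runs down pressure, so the oriented flow graph is acyclic up to ties),
converging nodes mix by RBC-flux conservation, and diverging bifurcations
apply the phase-separation law. The update is damped for use inside the
viscosity/flow fixed-point iteration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "RheologyParams",
    "relative_viscosity_invitro",
    "segment_viscosity",
    "phase_separation_fractions",
    "update_hematocrit",
]


@dataclass
class RheologyParams:
    """Rheological configuration.

    plasma_viscosity : mPa·s. Multiplies the relative viscosity law.
    inlet_discharge_hematocrit : discharge hematocrit assigned to boundary
        inflows (and to every segment in constant-hct mode).
    mode : "constant_hct" (uniform hematocrit, Pries viscosity at that
        hematocrit) or "phase_separation" (iterated heterogeneous
        hematocrit).
    fixed_viscosity : mPa·s or None. When set, every segment gets this
        viscosity regardless of diameter and hematocrit — the Newtonian
        reference used by the closed-form fixtures.
    damping, max_iter, hct_tol : parameters of the damped hematocrit
        fixed-point iteration.
    """

    plasma_viscosity: float = 1.2
    inlet_discharge_hematocrit: float = 0.4
    mode: str = "constant_hct"
    fixed_viscosity: float | None = None
    damping: float = 0.5
    max_iter: int = 100
    hct_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.inlet_discharge_hematocrit <= 1.0:
            raise ValueError("hematocrit must lie in [0, 1]")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")
        if not self.plasma_viscosity > 0:
            raise ValueError("plasma viscosity must be positive")
        if self.mode not in ("constant_hct", "phase_separation"):
            raise ValueError(f"unknown rheology mode {self.mode!r}")


def relative_viscosity_invitro(diameter: float, discharge_hct: float) -> float:
    """Relative apparent blood viscosity in a tube (in-vitro law).

    Parameters are the tube diameter in μm and the discharge hematocrit.
    Returns the apparent viscosity relative to the suspending medium:
    1.0 at zero hematocrit, minimum near d ≈ 7 μm at fixed hematocrit,
    rising steeply below ~5 μm and saturating at large diameters.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not 0.0 <= discharge_hct <= 1.0:
        raise ValueError("hematocrit must lie in [0, 1]")
    d = float(diameter)
    mu45 = 220.0 * math.exp(-1.3 * d) + 3.2 - 2.44 * math.exp(-0.06 * d**0.645)
    dterm = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + math.exp(-0.075 * d)) * (-1.0 + dterm) + dterm
    if discharge_hct == 0.0:
        return 1.0
    num = (1.0 - discharge_hct) ** c - 1.0
    den = (1.0 - 0.45) ** c - 1.0
    return 1.0 + (mu45 - 1.0) * num / den


def segment_viscosity(radius: float, discharge_hct: float, params: RheologyParams) -> float:
    """Apparent viscosity (mPa·s) of a segment of given radius (μm)."""
    if params.fixed_viscosity is not None:
        return params.fixed_viscosity
    return params.plasma_viscosity * relative_viscosity_invitro(2.0 * radius, discharge_hct)


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def phase_separation_fractions(
    feed_diameter: float,
    feed_hct: float,
    daughter_diameters: tuple[float, float],
    daughter_flow_fractions: tuple[float, float],
) -> tuple[float, float]:
    """Erythrocyte flux fractions of the two daughters of a bifurcation.

    ``daughter_flow_fractions`` are the daughters' blood-flow fractions
    (must sum to 1). Returns RBC flux fractions summing to 1. A daughter
    whose flow fraction is at or below the cutoff X0 receives zero RBC
    flux; at or above 1 − X0 it receives all of it. The law is its own
    mirror image under swapping the daughters, so it is evaluated once for
    daughter α and complemented for β.
    """
    fqb_a, fqb_b = daughter_flow_fractions
    if not math.isclose(fqb_a + fqb_b, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("daughter flow fractions must sum to 1")
    d_a, d_b = daughter_diameters
    x0 = 0.964 * (1.0 - feed_hct) / feed_diameter
    if 1.0 - 2.0 * x0 <= 0.0:
        # degenerate feed (cutoffs overlap): split RBCs with the flow
        return fqb_a, fqb_b
    if fqb_a <= x0:
        return 0.0, 1.0
    if fqb_a >= 1.0 - x0:
        return 1.0, 0.0
    ratio_sq = (d_a / d_b) ** 2
    a_coef = -13.29 * ((ratio_sq - 1.0) / (ratio_sq + 1.0)) * (1.0 - feed_hct) / feed_diameter
    b_coef = 1.0 + 6.98 * (1.0 - feed_hct) / feed_diameter
    x = (fqb_a - x0) / (1.0 - 2.0 * x0)
    logit_fqe = a_coef + b_coef * _logit(x)
    fqe_a = 1.0 / (1.0 + math.exp(-logit_fqe))
    return fqe_a, 1.0 - fqe_a


def update_hematocrit(mirrored, state, params: RheologyParams):
    """One damped hematocrit propagation pass over a solved flow field.

    ``mirrored`` is a :class:`~microperm.flow.MirroredNetwork` (or any
    object with a ``network`` attribute), ``state`` a solved
    :class:`~microperm.flow.HemodynamicState`. Returns a new state with
    updated per-segment discharge hematocrit; flow and pressures are
    carried over unchanged. In constant-hct mode this is the identity.
    """
    net = mirrored.network
    new_state = state.copy()
    if params.mode == "constant_hct":
        return new_state

    h_old = state.hematocrit
    flows = state.flow
    qmax = max((abs(q) for q in flows.values()), default=0.0)
    q_eps = 1e-12 * qmax

    # Orient segments by flow: upstream node -> downstream node.
    dig = nx.DiGraph()
    dig.add_nodes_from(net.nodes)
    seg_dir = {}
    for sid, seg in net.segments.items():
        q = flows[sid]
        if abs(q) <= q_eps:
            continue
        u, v = (seg.node_a, seg.node_b) if q > 0 else (seg.node_b, seg.node_a)
        seg_dir[sid] = (u, v)
        dig.add_edge(u, v)

    try:
        order = list(nx.topological_sort(dig))
    except nx.NetworkXUnfeasible:  # numerically tied pressures can close a loop
        logger.warning("flow orientation is cyclic; processing nodes by descending throughflow")
        through = {
            nid: sum(abs(flows[sid]) for sid, (u, v) in seg_dir.items() if u == nid or v == nid)
            for nid in net.nodes
        }
        order = sorted(net.nodes, key=lambda nid: -through[nid])

    incoming: dict[int, list[int]] = {nid: [] for nid in net.nodes}
    outgoing: dict[int, list[int]] = {nid: [] for nid in net.nodes}
    for sid, (u, v) in seg_dir.items():
        outgoing[u].append(sid)
        incoming[v].append(sid)

    h_raw = dict(h_old)  # zero-flow segments keep their previous hematocrit
    for nid in order:
        outs = sorted(outgoing[nid])
        if not outs:
            continue
        ins = sorted(incoming[nid])
        if ins:
            q_in = sum(abs(flows[s]) for s in ins)
            rbc_in = sum(abs(flows[s]) * h_raw[s] for s in ins)
            h_node = rbc_in / q_in if q_in > 0 else params.inlet_discharge_hematocrit
        else:
            h_node = params.inlet_discharge_hematocrit  # boundary inflow
        q_out = sum(abs(flows[s]) for s in outs)
        if len(outs) == 1:
            h_raw[outs[0]] = min(1.0, h_node)
        elif len(outs) == 2 and ins:
            parent = max(ins, key=lambda s: abs(flows[s]))
            d_f = 2.0 * net.segments[parent].radius
            sa, sb = outs
            fqb_a = abs(flows[sa]) / q_out
            fqe_a, _ = phase_separation_fractions(
                d_f, h_node,
                (2.0 * net.segments[sa].radius, 2.0 * net.segments[sb].radius),
                (fqb_a, 1.0 - fqb_a),
            )
            phi = q_out * h_node  # total RBC flux to distribute
            e_a = min(fqe_a * phi, abs(flows[sa]))  # clamp keeps H ≤ 1 ...
            e_b = min(phi - e_a, abs(flows[sb]))    # ... excess spills to the sibling
            e_a = phi - e_b
            h_raw[sa] = e_a / abs(flows[sa]) if abs(flows[sa]) > 0 else h_node
            h_raw[sb] = e_b / abs(flows[sb]) if abs(flows[sb]) > 0 else h_node
        else:
            # trifurcations (or parentless splits): RBCs follow the flow
            for s in outs:
                h_raw[s] = min(1.0, h_node)

    lam = params.damping
    new_state.hematocrit = {
        sid: min(1.0, max(0.0, (1.0 - lam) * h_old[sid] + lam * h_raw[sid]))
        for sid in h_old
    }
    return new_state
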