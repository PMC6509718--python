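"""Vascular remodeling scenarios and their effect on the permeability tensor.

Five scenario families probe how structural interventions change the
microvascular conductivity of a subnetwork:

1. dilation of every vessel diameter by 10/20/30%;
2. dilation of a random 10/20/30% subset of vessels by 30%;
3. constriction of every vessel by 10/20/30%;
4. constriction of a random 10/20/30% subset of vessels by 20%;
5. pruning of the 10/20/30% of vessels with the smallest radii
   (followed by blind-end pruning of the dangling remnants).

A sixth mode applies a diameter-dependent vasodilation profile: the
smallest microvessels (diameter 0.4 μm) dilate by the full peak fraction
and the response falls linearly to zero at 20 μm, reflecting the inverse
diameter dependence of vasomotor response. Subset choices are uniformly
random without replacement under an explicit seed, so a scenario is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import Subnetwork
from .permeability import PermeabilityTensor
from .preprocess import prune_blind_ends

__all__ = [
    "RemodelingScenario",
    "diameter_dependent_factor",
    "apply_scenario",
    "percent_change",
]

MODES = (
    "dilate_all",
    "dilate_subset",
    "dilate_diameter_dependent",
    "constrict_all",
    "constrict_subset",
    "prune_smallest",
)


@dataclass
class RemodelingScenario:
    mode: str
    magnitude: float                 # diameter change fraction (or peak, or prune fraction)
    subset_fraction: float | None = None
    seed: int = 0
    d_min: float = 0.4               # μm, diameter of maximal vasodilation response
    d_max: float = 20.0              # μm, diameter of zero vasodilation response

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown remodeling mode {self.mode!r}")
        if not 0.0 < self.magnitude < 1.0:
            raise ValueError("magnitude must lie in (0, 1)")
        if self.mode in ("dilate_subset", "constrict_subset"):
            if self.subset_fraction is None or not 0.0 < self.subset_fraction <= 1.0:
                raise ValueError("subset_fraction must lie in (0, 1] for subset modes")


def diameter_dependent_factor(d: float, f_max: float,
                              d_min: float = 0.4, d_max: float = 20.0) -> float:
    """Linear vasodilation profile: f_max at d ≤ d_min, zero at d ≥ d_max."""
    if not f_max > 0:
        raise ValueError("f_max must be positive")
    d_c = min(max(d, d_min), d_max)
    return f_max * (d_max - d_c) / (d_max - d_min)


def apply_scenario(sub: Subnetwork, sc: RemodelingScenario) -> Subnetwork:
    """Return a modified copy of the subnetwork under one scenario.

    Pruning removes the ⌊fraction·n⌋ smallest-radius segments (ties break
    by segment id) and then re-runs blind-end pruning so no dangling
    remnants survive; it may legitimately disconnect all face-to-face
    paths, in which case the downstream tensor row is zero.
    """
    net = sub.network.copy()
    seg_ids = sorted(net.segments)
    rng = np.random.default_rng(sc.seed)

    if sc.mode == "dilate_all":
        for s in net.segments.values():
            s.radius *= 1.0 + sc.magnitude
    elif sc.mode == "constrict_all":
        for s in net.segments.values():
            s.radius *= 1.0 - sc.magnitude
    elif sc.mode in ("dilate_subset", "constrict_subset"):
        n_pick = int(round(sc.subset_fraction * len(seg_ids)))
        chosen = rng.choice(len(seg_ids), size=n_pick, replace=False)
        sign = 1.0 if sc.mode == "dilate_subset" else -1.0
        for idx in chosen:
            net.segments[seg_ids[idx]].radius *= 1.0 + sign * sc.magnitude
    elif sc.mode == "dilate_diameter_dependent":
        for s in net.segments.values():
            f = diameter_dependent_factor(2.0 * s.radius, sc.magnitude, sc.d_min, sc.d_max)
            s.radius *= 1.0 + f
    elif sc.mode == "prune_smallest":
        n_drop = int(sc.magnitude * len(seg_ids))
        order = sorted(seg_ids, key=lambda sid: (net.segments[sid].radius, sid))
        for sid in order[:n_drop]:
            del net.segments[sid]
        used = {s.node_a for s in net.segments.values()} | {s.node_b for s in net.segments.values()}
        net.nodes = {nid: n for nid, n in net.nodes.items() if nid in used}

    out = Subnetwork(net, sub.component_id, sub.volume_initial, sub.volume_pruned,
                     None if sub.domain_lo is None else sub.domain_lo.copy(),
                     None if sub.domain_hi is None else sub.domain_hi.copy())
    if sc.mode == "prune_smallest":
        out = replace(prune_blind_ends(out),
                      volume_initial=sub.volume_initial,
                      domain_lo=out.domain_lo, domain_hi=out.domain_hi)
    return out


def percent_change(before: PermeabilityTensor, after: PermeabilityTensor) -> tuple:
    """Percent change of the three sorted diagonal elements.

    Returns (Δk11, Δk22, Δk33) in percent; an element whose baseline is
    zero is reported as None (undefined relative change).
    """
    if not (before.sorted and after.sorted):
        raise ValueError("percent_change expects sorted tensors")
    out = []
    for i in range(3):
        b, a = before.values[i, i], after.values[i, i]
        out.append(None if b == 0 else 100.0 * (a - b) / b)
    return tuple(out)
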