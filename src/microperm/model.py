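"""Model/Results front end for the permeability pipeline.

:class:`PermeabilityModel` is built from a vascular network plus
configuration; :meth:`~PermeabilityModel.fit` executes the full pipeline —
component labeling, density filtering, border-end elongation, blind-end
pruning, REV gating, mirroring, the per-direction pressure solves, tensor
fusion and axis sorting — and returns a :class:`PermeabilityResults`
carrying the sorted tensor, the per-subnetwork tensors, the fusion record
and the preprocessing report, with methods for perfusion (MBF, AV pressure
drop) and remodeling simulations hanging off it.

    >>> net = make_single_tube(box=(100, 100, 100), radius=4)
    >>> model = PermeabilityModel(net, rheology=RheologyParams(fixed_viscosity=1.0),
    ...                           apply_rev_gate=False)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .flow import SolverConfig
from .network import Subnetwork, VesselNetwork, read_edge_list
from .permeability import (
    FusionRecord,
    PermeabilityTensor,
    fuse_tensors,
    sort_tensor,
    tensor_for_subnetwork,
)
from .perfusion import PerfusionParams, dp_from_mbf, mbf_from_k
from .preprocess import (
    DENSITY_THRESHOLD,
    ELONGATION_EPSILON,
    REV_CUTOFF,
    PreprocessReport,
    preprocess,
)
from .remodeling import RemodelingScenario, apply_scenario, percent_change
from .rheology import RheologyParams

__all__ = ["PermeabilityModel", "PermeabilityResults"]


class PermeabilityModel:
    """Continuum-flow permeability model of a microvascular network.

    Parameters
    ----------
    network : VesselNetwork
        The vascular graph, with box extents in μm.
    rheology : RheologyParams, optional
        Viscosity/hematocrit configuration. The default applies the
        in-vitro viscosity law at a uniform discharge hematocrit of 0.4.
    solver : SolverConfig, optional
        Applied gradient and linear-solver settings.
    density_threshold, elongation_epsilon, rev_cutoff, apply_rev_gate
        Preprocessing controls (defaults: 0.15, 5 μm, 170 μm, on).
    preprocessed : bool
        If True, ``network`` is taken as one solver-ready subnetwork
        occupying its full box and preprocessing is skipped.
    """

    def __init__(
        self,
        network: VesselNetwork,
        rheology: RheologyParams | None = None,
        solver: SolverConfig | None = None,
        density_threshold: float = DENSITY_THRESHOLD,
        elongation_epsilon: float = ELONGATION_EPSILON,
        rev_cutoff: float = REV_CUTOFF,
        apply_rev_gate: bool = True,
        preprocessed: bool = False,
    ) -> None:
        self.network = network
        self.rheology = rheology or RheologyParams()
        self.solver = solver or SolverConfig()
        self.density_threshold = density_threshold
        self.elongation_epsilon = elongation_epsilon
        self.rev_cutoff = rev_cutoff
        self.apply_rev_gate = apply_rev_gate
        self.preprocessed = preprocessed

    @classmethod
    def from_edge_list(cls, path, box=None, **kwargs) -> "PermeabilityModel":
        return cls(read_edge_list(path, box=box), **kwargs)

    def config_dict(self) -> dict:
        return {
            "rheology": asdict(self.rheology),
            "solver": asdict(self.solver),
            "density_threshold": self.density_threshold,
            "elongation_epsilon_um": self.elongation_epsilon,
            "rev_cutoff_um": self.rev_cutoff,
            "apply_rev_gate": self.apply_rev_gate,
            "version": __version__,
        }

    def fit(self, apply_scale: bool = True) -> "PermeabilityResults":
        """Run the pipeline and return the fitted results.

        ``apply_scale`` toggles the V_init/V_pruned rescaling that
        compensates for blind-end volume loss during fusion.
        """
        if self.preprocessed:
            subs = [Subnetwork.from_network(self.network)]
            report = PreprocessReport(
                density_fractions={0: 1.0}, retained_components=[0],
                volume_initial={0: subs[0].volume_initial},
                volume_pruned={0: subs[0].volume_initial},
            )
        else:
            subs, report = preprocess(
                self.network,
                threshold=self.density_threshold,
                epsilon=self.elongation_epsilon,
                rev_cutoff=self.rev_cutoff,
                apply_rev_gate=self.apply_rev_gate,
            )
        records = [(sub, tensor_for_subnetwork(sub, self.rheology, self.solver))
                   for sub in subs]
        if records:
            fused, fusion = fuse_tensors(records, apply_scale=apply_scale)
            tensor = sort_tensor(fused)
        else:
            fused = fusion = tensor = None
        return PermeabilityResults(self, tensor, fused, records, fusion, report,
                                   apply_scale)


@dataclass
class PermeabilityResults:
    """Fitted permeability tensor of a network plus derived hemodynamics."""

    model: PermeabilityModel
    tensor: PermeabilityTensor | None          # sorted, mm³·s/kg
    tensor_unsorted: PermeabilityTensor | None
    subnetwork_tensors: list[tuple[Subnetwork, PermeabilityTensor]]
    fusion: FusionRecord | None
    report: PreprocessReport
    scaled: bool = True

    @property
    def excluded(self) -> bool:
        """True when every subnetwork was filtered out (no tensor)."""
        return self.tensor is None

    def _diag(self, i: int) -> float:
        if self.tensor is None:
            raise ValueError("no tensor: every subnetwork was excluded")
        return float(self.tensor.values[i, i])

    @property
    def k11(self) -> float:
        return self._diag(0)

    @property
    def k22(self) -> float:
        return self._diag(1)

    @property
    def k33(self) -> float:
        return self._diag(2)

    # -- perfusion ---------------------------------------------------------

    def mbf(self, params: PerfusionParams | None = None, element: int = 1) -> float:
        """Myocardial blood flow (mL/min per 100 g) from k_11/k_22/k_33."""
        return mbf_from_k(self._diag(element - 1), params)

    def pressure_drop(self, measured_mbf: float,
                      params: PerfusionParams | None = None, element: int = 1) -> float:
        """AV pressure drop (mm Hg) consistent with a measured MBF."""
        return dp_from_mbf(measured_mbf, self._diag(element - 1), params)

    # -- remodeling --------------------------------------------------------

    def simulate_remodeling(self, scenario: RemodelingScenario,
                            component: int = 0) -> dict:
        """Apply a remodeling scenario to one subnetwork and recompute.

        Returns the before/after sorted tensors of that subnetwork and the
        percent change of each sorted diagonal element.
        """
        matches = [(s, t) for s, t in self.subnetwork_tensors if s.component_id == component]
        if not matches:
            raise ValueError(f"no retained subnetwork with component id {component}")
        sub, before_unsorted = matches[0]
        remodeled = apply_scenario(sub, scenario)
        after_unsorted = tensor_for_subnetwork(remodeled, self.model.rheology,
                                               self.model.solver)
        before = sort_tensor(before_unsorted)
        after = sort_tensor(after_unsorted)
        return {
            "scenario": asdict(scenario),
            "before": before,
            "after": after,
            "percent_change": percent_change(before, after),
        }

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "config": self.model.config_dict(),
            "scaled": self.scaled,
            "preprocess_report": self.report.to_dict(),
            "excluded": self.excluded,
        }
        if self.tensor is not None:
            out["tensor_mm3_s_per_kg"] = self.tensor.values.tolist()
            out["tensor_permutation"] = list(self.tensor.permutation)
            out["k_diagonal"] = [self.k11, self.k22, self.k33]
            out["subnetworks"] = [
                {
                    "component_id": sub.component_id,
                    "volume_ratio": sub.volume_ratio(),
                    "tensor_mm3_s_per_kg": t.values.tolist(),
                }
                for sub, t in self.subnetwork_tensors
            ]
        else:
            out["exclusion_reasons"] = {
                "rev_fail": [cid for cid, ok in self.report.rev_pass.items() if not ok],
                "empty_after_pruning": self.report.empty_after_pruning,
                "below_density_threshold": [
                    cid for cid, frac in self.report.density_fractions.items()
                    if cid not in self.report.retained_components
                ],
            }
        return out

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self, perfusion: PerfusionParams | None = None) -> str:
        """Human-readable fit summary in the spirit of a regression table."""
        lines = ["Permeability model results", "=" * 54]
        n_seg = len(self.model.network.segments)
        lines.append(f"segments: {n_seg:6d}    nodes: {len(self.model.network.nodes):6d}")
        lines.append(f"retained subnetworks: {len(self.subnetwork_tensors)}"
                     f"    hct mode: {self.model.rheology.mode}")
        lines.append(f"blind-end volume rescaling: {'on' if self.scaled else 'off'}")
        if self.excluded:
            lines.append("all subnetworks excluded (density / pruning / REV gate)")
            return "\n".join(lines)
        lines.append("-" * 54)
        lines.append("sorted permeability tensor K [mm^3*s/kg]:")
        for row in self.tensor.values:
            lines.append("  " + "  ".join(f"{v: .6e}" for v in row))
        p = perfusion or PerfusionParams()
        lines.append("-" * 54)
        lines.append(f"perfusion at dp = {p.delta_p} mm Hg, path = {p.path_length:.0f} um,"
                     f" rho = {p.rho_g_cm3} g/cm^3:")
        for i, name in enumerate(("k11", "k22", "k33")):
            lines.append(f"  MBF_{name} = {mbf_from_k(self._diag(i), p):8.2f} mL/min/100g"
                         f"   ({name} = {self._diag(i):.4e})")
        return "\n".join(lines)
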