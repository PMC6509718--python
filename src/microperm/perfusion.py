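"""Myocardial blood flow and arteriole–venule pressure drop from k.

Assuming the Darcy velocity is parallel to a principal flow direction, the
perfusion of a region follows from a diagonal tensor element k_ii, the
pressure drop Δp along an arteriole-to-venule path of length l, and the
myocardial density ρ:

    MBF [mL/min per 100 g] = k_ii · Δp · 0.133×10⁻³ · 60 · 100 / (ρ · l²)

with k_ii in mm³·s/kg, Δp in mm Hg, l in μm and ρ in the matching
kg/μm³-scaled unit (1.05 g/cm³ ↔ 1.05×10⁻⁹); 0.133×10⁻³ converts mm Hg to
kg/(μm·s²), 60 converts seconds to minutes and 100 scales to 100 g of
tissue. The relation is linear in both k_ii and Δp, and inverts exactly to
estimate the AV pressure drop from an MBF measured by MRI.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PerfusionParams", "mbf_from_k", "dp_from_mbf", "MMHG_TO_EQ3", "PATH_LENGTHS_UM"]

#: mm Hg -> kg/(μm·s²) conversion constant of the MBF formula.
MMHG_TO_EQ3 = 0.133e-3

#: AV path lengths (μm) reported for the pig: mean − SD, mean, mean + SD.
PATH_LENGTHS_UM = (349.0, 512.0, 675.0)


@dataclass
class PerfusionParams:
    """AV pressure drop (mm Hg), path length (μm) and density (g/cm³)."""

    delta_p: float = 19.5          # physiological AV pressure drop, mm Hg
    path_length: float = 512.0     # AV path length, μm (pig mean)
    rho_g_cm3: float = 1.05        # myocardial density

    def __post_init__(self) -> None:
        if self.delta_p <= 0 or self.path_length <= 0 or self.rho_g_cm3 <= 0:
            raise ValueError("perfusion parameters must be positive")

    @property
    def rho(self) -> float:
        """Density in the kg/μm³-scaled unit the MBF formula expects."""
        return self.rho_g_cm3 * 1e-9


def mbf_from_k(k_ii: float, p: PerfusionParams | None = None) -> float:
    """Myocardial blood flow (mL/min per 100 g) from a tensor diagonal element.

    ``k_ii`` in mm³·s/kg; must be ≥ 0. Linear in ``k_ii`` and in the
    pressure drop.
    """
    p = p or PerfusionParams()
    if k_ii < 0:
        raise ValueError("k_ii must be non-negative")
    return k_ii * p.delta_p * MMHG_TO_EQ3 * 60.0 * 100.0 / (p.rho * p.path_length**2)


def dp_from_mbf(mbf: float, k_ii: float, p: PerfusionParams | None = None) -> float:
    """AV pressure drop (mm Hg) that reproduces a measured MBF. Exact inverse
    of :func:`mbf_from_k` in Δp; requires k_ii > 0."""
    p = p or PerfusionParams()
    if not k_ii > 0:
        raise ValueError("k_ii must be positive to invert for the pressure drop")
    return mbf * p.rho * p.path_length**2 / (k_ii * MMHG_TO_EQ3 * 60.0 * 100.0)
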