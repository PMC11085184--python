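"""Scalar model of the STEM probe-forming column.

The probe waist is budgeted from four quadrature terms at aperture
semi-angle α: diffraction σ_d = 0.61λ/α, spherical aberration
σ_s = C_s·α³/4, chromatic aberration σ_c = C_c·α·(ΔE/E), and emittance
σ_emit = ε_geo/α.  δ_th (without the emittance term) is the theoretical
minimum the lenses allow; the α-scan optimiser finds the aperture that
minimises it.  Source demagnification bookkeeping maps the ~0.5 μm source
to the ~1 nm probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .xsec import Kinematics

__all__ = [
    "ColumnParams",
    "WaistBudget",
    "waist_budget",
    "optimize_aperture",
    "demagnified_probe",
    "geometric_emittance_nm",
]


@dataclass(frozen=True)
class ColumnParams:
    """Scalar column parameters (lengths in metres where aberrations are
    quoted, emittance in pm·rad)."""

    spherical_aberration_m: float = 0.16      # Cs
    chromatic_aberration_m: float = 0.018     # Cc
    energy_spread: float = 3.3e-5             # ΔE/E
    geometric_emittance_pm: float = 2.0       # ε_geo
    normalized_emittance_pm: float = 10.0     # ε_n = γ0·ε_geo
    source_rms_size_um: float = 0.5
    demagnifications: tuple[float, float] = (20.0, 25.0)
    aperture_angle_mrad: float = 1.0


@dataclass(frozen=True)
class WaistBudget:
    """Waist-size components at one aperture angle, nm."""

    alpha_mrad: float
    sigma_d_nm: float
    sigma_s_nm: float
    sigma_c_nm: float
    sigma_emit_nm: float

    @property
    def delta_th_nm(self) -> float:
        """Theoretical minimum (no emittance): √(σd²+σs²+σc²)."""
        return float(np.sqrt(
            self.sigma_d_nm**2 + self.sigma_s_nm**2 + self.sigma_c_nm**2
        ))

    @property
    def sigma_waist_nm(self) -> float:
        return float(np.sqrt(self.delta_th_nm**2 + self.sigma_emit_nm**2))


def _wavelength_nm(kin: Union[Kinematics, float]) -> float:
    # accept a Kinematics or a bare wavelength in pm
    if isinstance(kin, Kinematics):
        return kin.wavelength_nm
    return float(kin) * 1e-3


def waist_budget(
    col: ColumnParams, kin: Union[Kinematics, float],
    alpha_mrad: Optional[float] = None,
) -> WaistBudget:
    """Evaluate the four waist components at aperture angle α.

    ``kin`` may be a :class:`~mevstem.xsec.Kinematics` or a wavelength in
    pm.  α defaults to the column's configured aperture angle.
    """
    alpha_mrad = col.aperture_angle_mrad if alpha_mrad is None else alpha_mrad
    if not alpha_mrad > 0:
        raise ValueError("aperture angle must be positive")
    alpha = alpha_mrad * 1e-3  # rad
    lam_nm = _wavelength_nm(kin)
    sigma_d = 0.61 * lam_nm / alpha
    sigma_s = col.spherical_aberration_m * 1e9 * alpha**3 / 4.0
    sigma_c = col.chromatic_aberration_m * 1e9 * alpha * col.energy_spread
    sigma_emit = col.geometric_emittance_pm * 1e-3 / alpha
    return WaistBudget(alpha_mrad, sigma_d, sigma_s, sigma_c, sigma_emit)


def optimize_aperture(
    col: ColumnParams, kin: Union[Kinematics, float],
    alpha_grid_mrad: Optional[Sequence[float]] = None,
) -> tuple[float, WaistBudget]:
    """Grid α minimising δ_th, with the budget at the optimum."""
    if alpha_grid_mrad is None:
        alpha_grid_mrad = np.arange(0.05, 3.0001, 0.01)
    grid = np.asarray(list(alpha_grid_mrad), dtype=float)
    if grid.size == 0:
        raise ValueError("aperture grid must be non-empty")
    budgets = [waist_budget(col, kin, a) for a in grid]
    i = int(np.argmin([b.delta_th_nm for b in budgets]))
    return float(grid[i]), budgets[i]


def demagnified_probe(
    col: ColumnParams, kin: Optional[Kinematics] = None
) -> tuple[float, float]:
    """(probe RMS size nm, convergence angle mrad) after demagnification.

    Size = source size / (product of demagnifications); the convergence
    angle follows from the emittance, α = ε_geo/size.
    """
    dm = float(np.prod(col.demagnifications))
    if dm == 0:
        raise ValueError("demagnification must be non-zero")
    size_nm = col.source_rms_size_um * 1e3 / dm
    # ε_geo[pm·rad]·1e-3 = nm·rad; /size[nm] = rad; ·1e3 = mrad
    alpha_mrad = col.geometric_emittance_pm / size_nm
    if abs(size_nm - 1.0) > 0.2:
        import warnings
        warnings.warn(
            f"demagnified probe size {size_nm:.3g} nm deviates from the "
            "nominal 1 nm by more than 20%", stacklevel=2,
        )
    return size_nm, alpha_mrad


def geometric_emittance_nm(normalized_emittance_pm: float,
                           lorentz_factor: float) -> float:
    """ε_geo = ε_n/γ0, returned in pm·rad."""
    return normalized_emittance_pm / lorentz_factor
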