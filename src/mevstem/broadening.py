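"""Analytic resolution budget for a focused probe in a thick sample.

The transverse beam size at depth t is the quadrature sum of three terms:

    σ_tot(t)² = σ_AB(t)² + σ_EC² + σ_SB(t)²

* σ_AB = |t − tf|·α — angular broadening away from the focal plane;
* σ_EC ≈ 1 nm — the emittance/diffraction/aberration waist contribution
  (see :mod:`mevstem.optics` for where the constant comes from);
* σ_SB = a·exp(b·t/MFP) + c — scattering broadening, an exponential whose
  rate b is proportional to the effective critical angle and whose
  constants are calibrated against the Monte Carlo transport.

The module also provides the least-squares calibration of (a, b, c) against
MC depth profiles and the minimum-energy search for a target beam-size
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .xsec import AMORPHOUS_ICE, Material, characteristic_angles, kinematics

__all__ = [
    "SBFitParams",
    "ResolutionBudget",
    "SBFitInput",
    "sigma_ab",
    "sigma_sb",
    "sigma_tot_profile",
    "fit_sb_params",
    "optimal_energy_for_thickness",
    "DEFAULT_ENERGY_GRID_EV",
    "published_fit_params",
    "FitFailure",
]

#: Energy grid of the published optimisation study, eV.
DEFAULT_ENERGY_GRID_EV = (3e6, 10e6, 15e6, 20e6, 30e6, 100e6)


class FitFailure(RuntimeError):
    """Raised when the scattering-broadening calibration does not converge;
    carries the residuals of the last iterate."""

    def __init__(self, message: str, residuals: np.ndarray):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class SBFitParams:
    """Constants of the exponential scattering-broadening law
    σ_SB = a·exp(b·t/MFP) + c."""

    a_nm: float
    b: float
    c_nm: float
    k: Optional[float] = None  # proportionality b = k·θeff(rad), if constrained

    def __post_init__(self) -> None:
        if not (self.a_nm > 0 and self.b > 0):
            raise ValueError("require a > 0 and b > 0")


def published_fit_params(theta_eff_mrad: float) -> SBFitParams:
    """The published calibration a≈1 nm, b≈10³·θeff(rad), c≈0."""
    return SBFitParams(a_nm=1.0, b=1e3 * theta_eff_mrad * 1e-3, c_nm=0.0, k=1e3)


def sigma_ab(t_um, tf_um: float, alpha_mrad: float,
             thickness_um: Optional[float] = None) -> np.ndarray:
    """Angular broadening |t − tf|·α, nm (μm·mrad = nm)."""
    t = np.asarray(t_um, dtype=float)
    if thickness_um is not None:
        if np.any(t < 0) or np.any(t > thickness_um) or not (
            0.0 <= tf_um <= thickness_um
        ):
            raise ValueError("t and tf must lie in [0, thickness]")
    return np.abs(t - tf_um) * alpha_mrad


def sigma_sb(t_um, fit: SBFitParams, mfp_um: float = 1.0) -> np.ndarray:
    """Scattering broadening a·exp(b·t/MFP) + c, nm."""
    if not mfp_um > 0:
        raise ValueError("mean free path must be positive")
    t = np.asarray(t_um, dtype=float)
    return fit.a_nm * np.exp(fit.b * t / mfp_um) + fit.c_nm


@dataclass
class ResolutionBudget:
    """σ_AB/σ_EC/σ_SB/σ_tot depth curves for one (energy, T, tf, α)."""

    depths_um: np.ndarray
    sigma_ab_nm: np.ndarray
    sigma_ec_nm: float
    sigma_sb_nm: np.ndarray
    sigma_tot_nm: np.ndarray
    energy_ev: float
    thickness_um: float
    focus_depth_um: float
    alpha_mrad: float
    fit: SBFitParams

    @property
    def max_sigma_tot_nm(self) -> float:
        """The resolution proxy: the maximum beam size along the depth."""
        return float(np.max(self.sigma_tot_nm))


_theta_eff_cache: dict[tuple[float, str], float] = {}


def _theta_eff_mrad(energy_ev: float, material: Material) -> float:
    key = (float(energy_ev), material.name)
    if key not in _theta_eff_cache:
        _theta_eff_cache[key] = characteristic_angles(
            kinematics(energy_ev), material
        ).theta_eff_mrad
    return _theta_eff_cache[key]


def sigma_tot_profile(
    energy_ev: float,
    thickness_um: float,
    focus_depth_um: float,
    alpha_mrad: float = 1.0,
    fit: Optional[SBFitParams] = None,
    sigma_ec_nm: float = 1.0,
    material: Material = AMORPHOUS_ICE,
    n_points: int = 1000,
) -> ResolutionBudget:
    """Full analytic depth curve on a uniform grid over [0, T].

    When ``fit`` is omitted the published calibration with b = 10³·θeff of
    the requested energy is used.
    """
    if not 0.0 <= focus_depth_um <= thickness_um:
        raise ValueError("focus depth must lie within the sample")
    if fit is None:
        fit = published_fit_params(_theta_eff_mrad(energy_ev, material))
    t = np.linspace(0.0, thickness_um, n_points)
    s_ab = sigma_ab(t, focus_depth_um, alpha_mrad, thickness_um)
    s_sb = sigma_sb(t, fit, material.inelastic_mfp_um)
    s_tot = np.sqrt(s_ab**2 + sigma_ec_nm**2 + s_sb**2)
    return ResolutionBudget(
        depths_um=t,
        sigma_ab_nm=s_ab,
        sigma_ec_nm=sigma_ec_nm,
        sigma_sb_nm=s_sb,
        sigma_tot_nm=s_tot,
        energy_ev=energy_ev,
        thickness_um=thickness_um,
        focus_depth_um=focus_depth_um,
        alpha_mrad=alpha_mrad,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# calibration against the Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class SBFitInput:
    """One MC depth curve entering the calibration.

    ``r68_nm`` is the measured beam radius; the ballistic part
    (σ_AB and σ_EC) is subtracted in quadrature to isolate σ_SB.
    """

    depths_um: np.ndarray
    r68_nm: np.ndarray
    theta_eff_mrad: float
    focus_depth_um: float = 0.0
    alpha_mrad: float = 1.0
    window_um: float = np.inf  # closed upper bound on fitted thickness

    def residual_sb(self, sigma_ec_nm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(depths, √max(r68² − σ_AB² − σ_EC², 0)) within the window."""
        t = np.asarray(self.depths_um, dtype=float)
        r = np.asarray(self.r68_nm, dtype=float)
        keep = t <= self.window_um + 1e-12
        t, r = t[keep], r[keep]
        s_ab = sigma_ab(t, self.focus_depth_um, self.alpha_mrad)
        resid_sq = r**2 - s_ab**2 - sigma_ec_nm**2
        return t, np.sqrt(np.clip(resid_sq, 0.0, None))


def fit_sb_params(
    inputs: Sequence[SBFitInput],
    sigma_ec_nm: float = 1.0,
    mfp_um: float = 1.0,
    constrain_b: bool = True,
    share_ac: bool = True,
) -> list[SBFitParams]:
    """Least-squares calibration of σ_SB = a·exp(b·t/MFP) + c.

    With ``constrain_b`` the growth rates are tied to the effective
    critical angle, b_j = k·θeff_j, with a single k (and, when
    ``share_ac``, a and c) shared across the input curves — the constraint
    used for the published constants.  Returns one :class:`SBFitParams`
    per input curve.
    """
    if len(inputs) == 0:
        raise ValueError("need at least one profile")
    data = [inp.residual_sb(sigma_ec_nm) for inp in inputs]
    th_eff = np.array([inp.theta_eff_mrad * 1e-3 for inp in inputs])  # rad

    if not share_ac and len(inputs) > 1:
        return [
            fit_sb_params([inp], sigma_ec_nm, mfp_um, constrain_b, True)[0]
            for inp in inputs
        ]

    def unpack(p):
        if constrain_b:
            a, c, k = p
            bs = k * th_eff
        else:
            a, c = p[0], p[1]
            bs = np.asarray(p[2:])
            k = None
        return a, c, bs, k

    def resid(p):
        a, c, bs, _ = unpack(p)
        out = []
        for (t, y), b in zip(data, bs):
            out.append(a * np.exp(b * t / mfp_um) + c - y)
        return np.concatenate(out)

    if constrain_b:
        x0 = np.array([1.0, 0.0, 1e3])
        lb = [1e-6, -np.inf, 1e-6]
        ub = [np.inf, np.inf, np.inf]
    else:
        x0 = np.concatenate([[1.0, 0.0], 1e3 * th_eff])
        lb = [1e-6, -np.inf] + [1e-6] * len(inputs)
        ub = np.inf
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
    if not sol.success:
        raise FitFailure("scattering-broadening fit did not converge", sol.fun)
    a, c, bs, k = unpack(sol.x)
    return [SBFitParams(a_nm=a, b=float(b), c_nm=c, k=k) for b in bs]


# ---------------------------------------------------------------------------
# energy optimisation
# ---------------------------------------------------------------------------

def optimal_energy_for_thickness(
    thickness_um: float,
    tolerance_nm: float = 10.0,
    energy_grid_ev: Sequence[float] = DEFAULT_ENERGY_GRID_EV,
    alpha_mrad: float = 1.0,
    sigma_ec_nm: float = 1.0,
    material: Material = AMORPHOUS_ICE,
) -> Optional[float]:
    """Minimum grid energy whose max-over-depth σ_tot (probe focused at
    T/2) stays within ``tolerance_nm``; ``None`` if no grid energy does."""
    grid = sorted(float(e) for e in energy_grid_ev)
    if len(grid) == 0:
        raise ValueError("energy grid must be non-empty")
    for e in grid:
        budget = sigma_tot_profile(
            e, thickness_um, thickness_um / 2.0, alpha_mrad,
            sigma_ec_nm=sigma_ec_nm, material=material,
        )
        if budget.max_sigma_tot_nm <= tolerance_nm:
            return e
    return None
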