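"""Dose-limited resolution under the Rose criterion.

The finest feature resolvable at a radiation-damage-limited fluence is

    δ = 2·SNR / (C·√(DQE·F·Dc))

with SNR the required signal-to-noise ratio (Rose: ≥3), C the image
contrast, DQE the detector quantum efficiency, F the fraction of incident
electrons collected by the detector, and Dc the electron fluence in e⁻/Å²
(per image; a cryo-tomography tilt series totals ~100 e⁻/Å² over ~50
images, i.e. ~2 e⁻/Å² each).  δ comes out in Å and is returned in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DoseParams",
    "dose_limited_resolution",
    "contrast_from_density",
    "dlr_vs_thickness",
    "PER_IMAGE_FLUENCE",
    "TILT_SERIES_FLUENCE",
]

#: Typical cryo-ET per-image fluence, e⁻/Å² (the default here).
PER_IMAGE_FLUENCE = 2.0
#: Typical total tilt-series fluence, e⁻/Å².
TILT_SERIES_FLUENCE = 100.0


@dataclass(frozen=True)
class DoseParams:
    """Inputs of the dose-limited-resolution estimate."""

    contrast: float
    snr: float = 3.0
    dqe: float = 0.5
    detector_fraction: float = 1.0
    fluence_e_per_A2: float = PER_IMAGE_FLUENCE

    def __post_init__(self) -> None:
        if not self.contrast > 0:
            raise ValueError("contrast must be positive")
        if not 0.0 < self.dqe <= 1.0:
            raise ValueError("DQE must lie in (0, 1]")
        if not 0.0 < self.detector_fraction <= 1.0:
            raise ValueError("detector fraction must lie in (0, 1]")
        if not self.fluence_e_per_A2 > 0:
            raise ValueError("fluence must be positive")


def dose_limited_resolution(p: DoseParams) -> float:
    """δ = 2·SNR/(C·√(DQE·F·Dc)), nm."""
    delta_A = 2.0 * p.snr / (
        p.contrast
        * np.sqrt(p.dqe * p.detector_fraction * p.fluence_e_per_A2)
    )
    return delta_A * 0.1  # Å → nm


def contrast_from_density(feature_density: float,
                          background_density: float) -> float:
    """|ρ_feature − ρ_background| / ρ_background."""
    if not background_density > 0:
        raise ValueError("background density must be positive")
    return abs(feature_density - background_density) / background_density


def dlr_vs_thickness(
    thicknesses_um: Sequence[float],
    detector_fraction_curve: Callable[[float], float],
    contrasts: tuple[float, float] = (0.1, 0.4),
    snr: float = 3.0,
    dqe: float = 0.5,
    fluence_e_per_A2: float = PER_IMAGE_FLUENCE,
) -> dict[str, np.ndarray]:
    """Upper-/lower-bound DLR curves over a thickness range.

    The upper bound uses the smaller contrast (faint organelles, C≈0.1),
    the lower bound the larger one (nucleus against ice, C≈0.4); the
    detector fraction F(T) couples in the transport result.
    """
    c_ub, c_lb = min(contrasts), max(contrasts)
    t = np.asarray(list(thicknesses_um), dtype=float)
    out: dict[str, np.ndarray] = {"thickness_um": t}
    for name, c in (("upper_bound_nm", c_ub), ("lower_bound_nm", c_lb)):
        vals = [
            dose_limited_resolution(DoseParams(
                contrast=c, snr=snr, dqe=dqe,
                detector_fraction=detector_fraction_curve(float(ti)),
                fluence_e_per_A2=fluence_e_per_A2,
            ))
            for ti in t
        ]
        out[name] = np.asarray(vals)
    return out
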