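"""Oil-droplet filtering and effective cone spectral sensitivities.

Avian single cones carry carotenoid oil droplets acting as long-pass cut-on
filters in front of the visual pigment.  Transparent T-type droplets (SWS1
cones) transmit fully; C-, Y- and R-type droplets (SWS2, Rh2, LW cones) are
modelled as logistic cut-ons T(λ) = 1/(1+exp(−k(λ−λ_mid))) with 50%
transmission at λ_mid.  The effective sensitivity of a cone is the
pointwise product pigment absorbance × droplet transmission, renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ParameterError
from .spectra import (
    Spectrum,
    TemplateParams,
    cutoff_wavelength,
    default_grid,
    govardovskii_absorbance,
    normalize_peak,
)

__all__ = [
    "DropletParams",
    "EffectiveConeSensitivity",
    "c_type_lambda_mid",
    "droplet_transmission",
    "effective_sensitivity",
    "perception_range",
    "BLACK_GROUSE_LAMBDA_MAX",
    "default_droplets",
]

#: Measured λ_max of the four black grouse cone pigments (nm).
BLACK_GROUSE_LAMBDA_MAX: dict[str, float] = {
    "SWS1": 393.0,
    "SWS2": 436.0,
    "Rh2": 482.0,
    "LW": 545.0,
}

#: Galliform droplet cut-on mid-wavelengths (nm) for Y and R types.
Y_LAMBDA_MID = 523.0
R_LAMBDA_MID = 586.0

#: Logistic slopes (per nm): moderate values per droplet type.
K_SWS2 = 0.15
K_RH2_LW = 0.12


@dataclass(frozen=True)
class DropletParams:
    """One cone's oil-droplet filter.

    T-type droplets have no cut-on (transmission ≡ 1); the other types need
    a λ_mid in [380, 650] nm and a positive slope.
    """

    droplet_type: str  # T | C | Y | R
    lambda_mid_nm: float | None = None
    slope_k_per_nm: float | None = None

    def __post_init__(self) -> None:
        if self.droplet_type not in ("T", "C", "Y", "R"):
            raise ParameterError("droplet_type must be one of T, C, Y, R")
        if self.droplet_type == "T":
            return
        if self.lambda_mid_nm is None or not (380.0 <= self.lambda_mid_nm <= 650.0):
            raise ParameterError("cut-on droplets need lambda_mid in [380, 650] nm")
        if self.slope_k_per_nm is None or self.slope_k_per_nm <= 0:
            raise ParameterError("cut-on droplets need slope_k > 0")


@dataclass(frozen=True)
class EffectiveConeSensitivity:
    """Pigment × droplet product with peak and 5% cut-off wavelengths."""

    cone_name: str
    sensitivity: Spectrum
    peak_nm: float
    lower_cutoff_nm: float | None
    upper_cutoff_nm: float


def c_type_lambda_mid(sws2_lambda_max: float) -> float:
    """Empirical C-type droplet λ_mid from the SWS2 pigment λ_max.

    C_mid = 0.82·λ_max + 75, the galliform microspectrophotometric relation.
    """
    if not (420.0 <= sws2_lambda_max <= 470.0):
        raise ParameterError("SWS2 lambda_max expected in [420, 470] nm")
    return 0.82 * sws2_lambda_max + 75.0


def droplet_transmission(params: DropletParams, grid: Iterable[float]) -> Spectrum:
    """Droplet transmission on a grid: all-ones for T, logistic cut-on else."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    if params.droplet_type == "T":
        return Spectrum(grid, np.ones_like(grid))
    t = 1.0 / (1.0 + np.exp(-params.slope_k_per_nm * (grid - params.lambda_mid_nm)))
    return Spectrum(grid, t)


def effective_sensitivity(
    opsin_lambda_max: float,
    droplet: DropletParams,
    grid: Iterable[float] | None = None,
    cone_name: str = "",
    include_beta_band: bool = True,
    cutoff_level: float = 0.05,
) -> EffectiveConeSensitivity:
    """Effective cone sensitivity: pigment absorbance × droplet transmission.

    The stored sensitivity spectrum is renormalised to peak 1.  The 5%
    cut-offs, however, are located on the *attenuated* product (the
    pigment-normalised absorbance times transmission, whose peak is below 1
    for cut-on droplets): referencing the level to the unfiltered pigment
    peak keeps the long-wavelength limb unchanged by droplet filtering, as
    the exponentially decaying pigment limb alone sets the upper limit of
    cone sensitivity.  The short-limb cut-off may not exist within the grid
    (β-band absorbance can stay above the level); it is then ``None``.
    """
    grid = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    pigment = govardovskii_absorbance(
        TemplateParams(opsin_lambda_max, include_beta_band), grid
    )
    filt = droplet_transmission(droplet, grid)
    attenuated = Spectrum(grid, pigment.values * filt.values)
    product = normalize_peak(attenuated)
    peak = product.peak_wavelength_nm
    upper = cutoff_wavelength(attenuated, cutoff_level, "long")
    try:
        lower: float | None = cutoff_wavelength(attenuated, cutoff_level, "short")
    except Exception:
        lower = None
    return EffectiveConeSensitivity(
        cone_name=cone_name or droplet.droplet_type,
        sensitivity=product,
        peak_nm=peak,
        lower_cutoff_nm=lower,
        upper_cutoff_nm=upper,
    )


def default_droplets(lambda_max: Mapping[str, float] | None = None) -> dict[str, DropletParams]:
    """Species-default droplet set keyed by cone name.

    C-type λ_mid follows the empirical SWS2 relation; Y and R use the
    galliform defaults 523 and 586 nm.
    """
    lm = dict(BLACK_GROUSE_LAMBDA_MAX if lambda_max is None else lambda_max)
    return {
        "SWS1": DropletParams("T"),
        "SWS2": DropletParams("C", c_type_lambda_mid(lm["SWS2"]), K_SWS2),
        "Rh2": DropletParams("Y", Y_LAMBDA_MID, K_RH2_LW),
        "LW": DropletParams("R", R_LAMBDA_MID, K_RH2_LW),
    }


def perception_range(
    cone_lambda_max: Mapping[str, float],
    droplets: Mapping[str, DropletParams] | None = None,
    grid: Iterable[float] | None = None,
    include_beta_band: bool = True,
    level: float = 0.05,
) -> tuple[float, float]:
    """Whole-eye perception range from the SWS1 and LW pigment limbs.

    Lower bound: short-limb 5% cut-off of the SWS1 pigment absorbance (its
    T-type droplet transmits fully, so the pigment alone governs).  Upper
    bound: long-limb 5% cut-off of the LW pigment absorbance — droplet
    filtering does not alter the long-wavelength limb.  If the short limb
    never falls to the level within the grid, the grid's lower edge is
    returned as the (uncrossed) bound.
    """
    for cone in ("SWS1", "SWS2", "Rh2", "LW"):
        if cone not in cone_lambda_max:
            raise ParameterError(f"missing cone {cone}")
    grid = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    sws1 = govardovskii_absorbance(
        TemplateParams(cone_lambda_max["SWS1"], include_beta_band), grid
    )
    lw = govardovskii_absorbance(
        TemplateParams(cone_lambda_max["LW"], include_beta_band), grid
    )
    try:
        lower = cutoff_wavelength(sws1, level, "short")
    except Exception:
        lower = float(grid.min())
    upper = cutoff_wavelength(lw, level, "long")
    return lower, upper
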