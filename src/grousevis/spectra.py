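"""Wavelength-indexed spectra and the A1 visual-pigment template.

The :class:`Spectrum` container carries every kind of curve used in the
package (absorbance, oil-droplet transmission, reflectance) as a strictly
increasing wavelength grid in nanometres with matched finite values.

The visual-pigment template implemented here is the standard A1
(11-cis-retinal) nomogram: a main α-band whose shape is a function of
x = λ_max/λ only, plus an optional short-wavelength β-band modelled as a
Gaussian whose position and width scale with λ_max.  Evaluated on a grid it
yields the relative absorbance of a pigment with a given λ_max, normalised
to 1 at the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, OutOfRangeError, ParameterError

__all__ = [
    "Spectrum",
    "TemplateParams",
    "govardovskii_absorbance",
    "cutoff_wavelength",
    "normalize_peak",
    "resample",
    "default_grid",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: Wavelength bounds (nm) within which any grid must live.
WAVELENGTH_MIN = 250.0
WAVELENGTH_MAX = 900.0

#: λ_max validity range (nm): the avian single-cone span with margin.
LAMBDA_MAX_MIN = 330.0
LAMBDA_MAX_MAX = 620.0

# A1 α-band constants (x = λ_max/λ parametrisation).
_ALPHA_A = 69.7
_ALPHA_B = 28.0
_ALPHA_C = -14.9
_ALPHA_D = 0.674
_ALPHA_b = 0.922
_ALPHA_c = 1.104

# β-band: Gaussian with λ_max-dependent position, width and fixed amplitude.
_BETA_AMPLITUDE = 0.26


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: strictly increasing wavelengths (nm) + values.

    Reflectance and transmission values must be non-negative; raw absorbance
    may carry small negative baseline noise, which is preserved on input and
    handled by preprocessing downstream.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ParameterError("wavelengths and values must be matched 1-D sequences")
        if wl.size < 2:
            raise ParameterError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise ParameterError(
                f"wavelengths must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        if not np.all(np.isfinite(vals)):
            raise ParameterError("spectrum values must all be finite")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def peak_wavelength_nm(self) -> float:
        """Wavelength of the maximum value (lowest wavelength on ties)."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at one wavelength (no extrapolation)."""
        wl = self.wavelengths_nm
        if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
            raise OutOfRangeError(
                f"{wavelength_nm} nm outside spectrum range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength_nm, wl, self.values))


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of the A1 pigment template."""

    lambda_max_nm: float
    include_beta_band: bool = True

    def __post_init__(self) -> None:
        if not (LAMBDA_MAX_MIN <= self.lambda_max_nm <= LAMBDA_MAX_MAX):
            raise ParameterError(
                f"lambda_max {self.lambda_max_nm} nm outside "
                f"[{LAMBDA_MAX_MIN}, {LAMBDA_MAX_MAX}] nm"
            )


def default_grid(start: float = 300.0, stop: float = 800.0, step: float = 0.1) -> np.ndarray:
    """The default evaluation grid for peak/cutoff location (0.1 nm)."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def _template_values(lambda_max: float, grid: np.ndarray, include_beta: bool) -> np.ndarray:
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_ALPHA_A * (a - x))
        + np.exp(_ALPHA_B * (_ALPHA_b - x))
        + np.exp(_ALPHA_C * (_ALPHA_c - x))
        + _ALPHA_D
    )
    if not include_beta:
        return alpha
    beta_peak = 189.0 + 0.315 * lambda_max
    beta_width = -40.5 + 0.195 * lambda_max
    beta = _BETA_AMPLITUDE * np.exp(-(((grid - beta_peak) / beta_width) ** 2))
    return alpha + beta


def govardovskii_absorbance(params: TemplateParams, grid: Iterable[float]) -> Spectrum:
    """Evaluate the A1 pigment template on a grid, peak-normalised to 1.

    The α-band is unimodal around λ_max; with ``include_beta_band`` a short-
    wavelength shoulder is added before normalisation.
    """
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    if grid.min() < WAVELENGTH_MIN or grid.max() > WAVELENGTH_MAX:
        raise ParameterError("template grid must lie within [250, 900] nm")
    vals = _template_values(params.lambda_max_nm, grid, params.include_beta_band)
    return normalize_peak(Spectrum(grid, vals))


def normalize_peak(spec: Spectrum) -> Spectrum:
    """Scale a spectrum so its maximum equals 1 (shape-preserving)."""
    peak = float(np.max(spec.values))
    if peak <= 0:
        raise DegenerateInputError("cannot peak-normalize a spectrum with max <= 0")
    return Spectrum(spec.wavelengths_nm, spec.values / peak)


def resample(spec: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid (no extrapolation)."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    wl = spec.wavelengths_nm
    if grid.min() < wl[0] or grid.max() > wl[-1]:
        raise OutOfRangeError(
            f"requested grid [{grid.min()}, {grid.max()}] extends beyond "
            f"spectrum range [{wl[0]}, {wl[-1]}]"
        )
    return Spectrum(grid, np.interp(grid, wl, spec.values))


def cutoff_wavelength(
    spec: Spectrum, level: float, side: Literal["short", "long"]
) -> float:
    """Wavelength where a peak-normalised spectrum falls to ``level``.

    Moving away from the peak on the requested side, returns the first
    crossing of ``level``, located by linear interpolation between the
    bracketing grid points.  ``level=1`` returns the peak itself.
    """
    if not (0 < level <= 1):
        raise ParameterError("level must be in (0, 1]")
    if side not in ("short", "long"):
        raise ParameterError("side must be 'short' or 'long'")
    wl = spec.wavelengths_nm
    vals = spec.values
    ipeak = int(np.argmax(vals))
    if level == 1.0:
        return float(wl[ipeak])
    if side == "long":
        w_arm, v_arm = wl[ipeak:], vals[ipeak:]
    else:
        w_arm, v_arm = wl[: ipeak + 1][::-1], vals[: ipeak + 1][::-1]
    below = np.nonzero(v_arm <= level)[0]
    if below.size == 0:
        raise OutOfRangeError(
            f"spectrum never falls to {level} on the {side} side within the grid"
        )
    j = int(below[0])
    if j == 0:  # peak itself already at/below level — degenerate
        return float(w_arm[0])
    w0, w1 = w_arm[j - 1], w_arm[j]
    v0, v1 = v_arm[j - 1], v_arm[j]
    return float(w0 + (level - v0) * (w1 - w0) / (v1 - v0))


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read the two-column ``wavelength_nm,value`` dialect (``#`` comments)."""
    df = pd.read_csv(path, comment="#")
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns wavelength_nm,value")
    df = df.sort_values("wavelength_nm")
    return Spectrum(df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float))


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths_nm, "value": spec.values}
    ).to_csv(path, index=False)
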