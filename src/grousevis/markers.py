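"""Reflectance-based achromatic contrast analysis of anti-collision markers.

Each marker device combines several reflective materials.  A material's
reflectance spectrum (300–780 nm at 1 nm, percent; fluorescent elements may
exceed 100%) is reduced to its mean reflectance, and the internal contrast
between two materials is the Michelson contrast of their means,
|R₁−R₂|/(R₁+R₂).  A contrast is detectable to the bird when its inverse
does not exceed the species' peak contrast sensitivity (1/C_m ≤ 16.67 for
the black grouse, boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoverageError, DegenerateInputError, ParameterError
from .spectra import Spectrum

__all__ = [
    "ReflectanceRecord",
    "ContrastMatrix",
    "mean_reflectance",
    "pairwise_michelson",
    "classify_detectable",
    "contrast_matrix",
    "read_reflectance_csv",
    "write_pairs_csv",
    "PEAK_CONTRAST_SENSITIVITY",
]

#: Species peak contrast sensitivity: 1/C_m at threshold.
PEAK_CONTRAST_SENSITIVITY = 16.67

REFLECTANCE_RANGE = (300.0, 780.0)


@dataclass(frozen=True)
class ReflectanceRecord:
    marker_name: str
    material_name: str
    component: str  # diffuse | diffuse_plus_specular
    spectrum: Spectrum

    def __post_init__(self) -> None:
        if self.component not in ("diffuse", "diffuse_plus_specular"):
            raise ParameterError("component must be diffuse|diffuse_plus_specular")
        if np.any(self.spectrum.values < 0):
            raise ParameterError("reflectance values must be non-negative")


@dataclass(frozen=True)
class ContrastMatrix:
    """Pairwise Michelson contrasts between one marker's materials."""

    marker_name: str
    materials: tuple[str, ...]
    mean_reflectances: tuple[float, ...]
    cm: np.ndarray
    inverse_cm: np.ndarray
    detectable: np.ndarray
    threshold_sensitivity: float

    def pairs(self) -> pd.DataFrame:
        """Tidy upper-triangle pairs table (heatmap twin)."""
        rows = []
        n = len(self.materials)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "marker": self.marker_name,
                        "material_a": self.materials[i],
                        "material_b": self.materials[j],
                        "cm": self.cm[i, j],
                        "inverse_cm": self.inverse_cm[i, j],
                        "detectable": bool(self.detectable[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def mean_reflectance(
    spec: Spectrum, wavelength_range: tuple[float, float] = REFLECTANCE_RANGE
) -> float:
    """Arithmetic mean reflectance over grid points inside the range."""
    lo, hi = wavelength_range
    wl = spec.wavelengths_nm
    if wl[0] > lo or wl[-1] < hi:
        raise CoverageError(
            f"spectrum [{wl[0]}, {wl[-1]}] does not cover [{lo}, {hi}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    return float(np.mean(spec.values[mask]))


def pairwise_michelson(r1: float, r2: float) -> float:
    """Michelson contrast |R₁−R₂|/(R₁+R₂) of two mean reflectances."""
    if r1 < 0 or r2 < 0:
        raise ParameterError("reflectances must be non-negative")
    if r1 + r2 == 0:
        raise DegenerateInputError("contrast undefined when both reflectances are 0")
    return abs(r1 - r2) / (r1 + r2)


def classify_detectable(
    cm: float, peak_sensitivity: float = PEAK_CONTRAST_SENSITIVITY
) -> bool:
    """Detectable iff 1/C_m ≤ peak sensitivity (boundary inclusive)."""
    if cm < 0 or cm > 1:
        raise ParameterError("Michelson contrast must be in [0, 1]")
    if cm == 0:
        return False  # zero contrast is undetectable by definition
    return 1.0 / cm <= peak_sensitivity


def contrast_matrix(
    records: Sequence[ReflectanceRecord],
    component: str = "diffuse",
    threshold: float = PEAK_CONTRAST_SENSITIVITY,
) -> ContrastMatrix:
    """Pairwise contrast matrix for one marker's materials.

    Records are filtered to one reflectance component; single-material
    markers (e.g. transparent floats) are rejected.
    """
    recs = [r for r in records if r.component == component]
    markers = {r.marker_name for r in recs}
    if len(markers) > 1:
        raise ParameterError("records must belong to a single marker")
    if len(recs) < 2:
        raise ParameterError(
            "contrast analysis needs at least 2 materials for the marker"
        )
    materials = tuple(r.material_name for r in recs)
    if len(set(materials)) != len(materials):
        raise ParameterError("duplicate material names in one component set")
    means = tuple(mean_reflectance(r.spectrum) for r in recs)
    n = len(recs)
    cm = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                cm[i, j] = pairwise_michelson(means[i], means[j])
    with np.errstate(divide="ignore"):
        inverse = np.where(cm > 0, 1.0 / np.where(cm > 0, cm, 1.0), np.inf)
    np.fill_diagonal(inverse, np.inf)
    detectable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j:
                detectable[i, j] = classify_detectable(cm[i, j], threshold)
    return ContrastMatrix(
        marker_name=next(iter(markers)),
        materials=materials,
        mean_reflectances=means,
        cm=cm,
        inverse_cm=inverse,
        detectable=detectable,
        threshold_sensitivity=threshold,
    )


def read_reflectance_csv(path: str | Path) -> list[ReflectanceRecord]:
    """Read the long dialect `marker,material,component,wavelength_nm,reflectance_pct`."""
    df = pd.read_csv(path, comment="#")
    needed = {"marker", "material", "component", "wavelength_nm", "reflectance_pct"}
    if not needed.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns {sorted(needed)}")
    out = []
    for (marker, material, component), grp in df.groupby(
        ["marker", "material", "component"], sort=True
    ):
        grp = grp.sort_values("wavelength_nm")
        out.append(
            ReflectanceRecord(
                marker_name=str(marker),
                material_name=str(material),
                component=str(component),
                spectrum=Spectrum(
                    grp["wavelength_nm"].to_numpy(float),
                    grp["reflectance_pct"].to_numpy(float),
                ),
            )
        )
    return out


def write_pairs_csv(matrices: Sequence[ContrastMatrix], path: str | Path) -> None:
    pd.concat([m.pairs() for m in matrices], ignore_index=True).to_csv(path, index=False)
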