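"""Visual-field maps from ophthalmoscopic perimeter measurements.

Retinal field boundaries are measured on a perimeter with the eyes rotated
fully forwards (converged; bounds the binocular overlap) and backwards
(diverged; bounds the blind sector behind the head).  Azimuths follow the
latitude–longitude convention with the equator in the median sagittal
plane; here azimuths are measured from the bill-forward direction, positive
toward the measured eye's side, so a converged boundary that crosses the
median plane has a positive *margin* beyond it.

Because the perimeter sits at a finite radius while the eyes are laterally
offset from the head centre, raw readings are corrected to a hypothetical
viewing point at infinity by explicit planar geometry per elevation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "FieldBoundaryMeasurement",
    "VisualFieldMap",
    "correct_to_infinity",
    "invert_infinity_correction",
    "interpolate_blocked_elevation",
    "horizontal_summary",
    "vertical_extent",
    "build_field_map",
    "read_boundaries_csv",
    "write_field_map_csv",
]


@dataclass(frozen=True)
class FieldBoundaryMeasurement:
    """One perimeter reading of a retinal field boundary."""

    eye: str  # left | right
    elevation_deg: float
    azimuth_deg: float  # margin relative to the median sagittal plane
    kind: str  # converged | diverged

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ParameterError("eye must be left|right")
        if self.kind not in ("converged", "diverged"):
            raise ParameterError("kind must be converged|diverged")
        if not (-90.0 <= self.elevation_deg <= 90.0):
            raise ParameterError("elevation must be in [-90, 90] deg")


@dataclass(frozen=True)
class VisualFieldMap:
    """Binocular widths by elevation plus the horizontal-plane sectors."""

    binocular_width_by_elevation: dict[float, float]
    interpolated_elevations: tuple[float, ...]
    lateral_width_deg: float
    binocular_width_horizontal_deg: float
    cyclopean_width_deg: float
    blind_width_deg: float
    vertical_binocular_extent_deg: float
    max_overlap_deg: float
    max_overlap_elevation_deg: float

    def __post_init__(self) -> None:
        if abs(self.cyclopean_width_deg + self.blind_width_deg - 360.0) > 1e-9:
            raise ParameterError("cyclopean + blind must equal 360 deg")
        if min(self.lateral_width_deg, self.binocular_width_horizontal_deg,
               self.blind_width_deg) < 0:
            raise ParameterError("sector widths must be non-negative")


def correct_to_infinity(
    measured_azimuth_deg: float, eye_separation_mm: float, perimeter_radius_mm: float
) -> float:
    """Correct a perimeter azimuth to a viewing point at infinity.

    The perimeter point sits at radius R and azimuth φ from the head
    centre; the eye is laterally offset e/2 toward the measured side.  The
    corrected azimuth is the direction of the ray from the eye to the
    point: atan2(R·sinφ − e/2, R·cosφ).  It converges to φ as R→∞ or e→0.
    """
    e = eye_separation_mm
    R = perimeter_radius_mm
    if e < 0 or R <= 0 or R <= e / 2:
        raise ParameterError("need perimeter radius > eye separation / 2 >= 0")
    phi = math.radians(measured_azimuth_deg)
    x = R * math.sin(phi) - e / 2.0
    y = R * math.cos(phi)
    return math.degrees(math.atan2(x, y))


def invert_infinity_correction(
    corrected_azimuth_deg: float, eye_separation_mm: float, perimeter_radius_mm: float
) -> float:
    """Map an eye-ray azimuth back to the perimeter reading (round-trip check).

    Intersects the ray from the offset eye with the perimeter circle of
    radius R about the head centre and returns that point's azimuth.
    """
    e = eye_separation_mm
    R = perimeter_radius_mm
    if e < 0 or R <= 0 or R <= e / 2:
        raise ParameterError("need perimeter radius > eye separation / 2 >= 0")
    psi = math.radians(corrected_azimuth_deg)
    # |(e/2 + t sinψ, t cosψ)| = R  →  t² + t·e·sinψ + e²/4 − R² = 0
    half = e / 2.0
    disc = (e * math.sin(psi)) ** 2 - 4.0 * (half * half - R * R)
    t = (-e * math.sin(psi) + math.sqrt(disc)) / 2.0
    x = half + t * math.sin(psi)
    y = t * math.cos(psi)
    return math.degrees(math.atan2(x, y))


def interpolate_blocked_elevation(width_above_deg: float, width_below_deg: float) -> float:
    """Mean of the binocular widths immediately above and below a blocked row."""
    if width_above_deg is None or width_below_deg is None:
        raise ParameterError("both neighbouring widths are required")
    if width_above_deg < 0 or width_below_deg < 0:
        raise ParameterError("widths must be non-negative")
    return (width_above_deg + width_below_deg) / 2.0


def horizontal_summary(binocular_deg: float, lateral_each_deg: float) -> tuple[float, float]:
    """Horizontal-plane decomposition: (cyclopean, blind) sectors."""
    if binocular_deg < 0 or lateral_each_deg < 0:
        raise ParameterError("widths must be non-negative")
    cyclopean = binocular_deg + 2.0 * lateral_each_deg
    if cyclopean > 360.0:
        raise ParameterError(f"sector sum {cyclopean} deg exceeds 360 deg")
    return cyclopean, 360.0 - cyclopean


def vertical_extent(upper_limit_deg: float, lower_limit_deg: float) -> float:
    """Vertical binocular extent: degrees above + below the bill-tip direction."""
    if upper_limit_deg < 0 or lower_limit_deg < 0:
        raise ParameterError("limits must be non-negative")
    return upper_limit_deg + lower_limit_deg


def build_field_map(
    measurements: Iterable[FieldBoundaryMeasurement],
    horizontal_elevation_deg: float = 0.0,
    eye_separation_mm: float | None = None,
    perimeter_radius_mm: float | None = None,
) -> VisualFieldMap:
    """Assemble a field map from converged/diverged boundary measurements.

    Per elevation, the binocular width is the sum of the two eyes'
    converged margins beyond the median plane (clipped at 0); elevations
    with a missing eye are interpolated from the neighbouring rows.  In the
    horizontal plane the diverged margins bound the blind sector and each
    eye's lateral field is its monocular extent minus the binocular sector.
    When apparatus geometry is given, margins are corrected to infinity
    first.
    """
    meas = list(measurements)
    if not meas:
        raise ParameterError("no measurements supplied")

    def margin(m: FieldBoundaryMeasurement) -> float:
        if eye_separation_mm is not None and perimeter_radius_mm is not None:
            return correct_to_infinity(m.azimuth_deg, eye_separation_mm, perimeter_radius_mm)
        return m.azimuth_deg

    conv: dict[float, dict[str, float]] = {}
    div: dict[float, dict[str, float]] = {}
    for m in meas:
        store = conv if m.kind == "converged" else div
        store.setdefault(m.elevation_deg, {})[m.eye] = margin(m)

    elevations = sorted(conv)
    widths: dict[float, float] = {}
    missing: list[float] = []
    for elev in elevations:
        eyes = conv[elev]
        if "left" in eyes and "right" in eyes:
            widths[elev] = max(0.0, eyes["left"] + eyes["right"])
        else:
            missing.append(elev)
    # blocked rows: elevations absent from the 10-deg ladder (or with a
    # missing eye) whose immediate neighbours are both present
    if len(widths) >= 2:
        known = sorted(widths)
        step = min(b - a for a, b in zip(known, known[1:]))
        for a, b in zip(known, known[1:]):
            gap = a + step
            if abs(b - a - 2 * step) < 1e-9 and gap not in widths:
                missing.append(gap)
    interpolated: list[float] = []
    for elev in sorted(set(missing)):
        below = [e for e in widths if e < elev]
        above = [e for e in widths if e > elev]
        if below and above:
            widths[elev] = interpolate_blocked_elevation(
                widths[min(above)], widths[max(below)]
            )
            interpolated.append(elev)
    widths = dict(sorted(widths.items()))
    if not widths:
        raise ParameterError("no elevation has usable binocular boundaries")

    if horizontal_elevation_deg not in widths:
        raise ParameterError("horizontal plane elevation missing from the map")
    binoc_h = widths[horizontal_elevation_deg]

    div_h = div.get(horizontal_elevation_deg, {})
    if "left" not in div_h or "right" not in div_h:
        raise ParameterError("horizontal-plane diverged boundaries required")
    blind = max(0.0, div_h["left"] + div_h["right"])
    # each eye's monocular horizontal extent spans from its converged margin
    # (beyond the median plane in front) to 180 deg minus its diverged
    # rear margin; the lateral sector is that extent minus the binocular one
    conv_h = conv[horizontal_elevation_deg]
    extents = {
        eye: conv_h[eye] + 180.0 - div_h[eye] for eye in ("left", "right")
    }
    lateral = float(np.mean([extents[e] - binoc_h for e in ("left", "right")]))
    cyclopean, blind_out = horizontal_summary(binoc_h, lateral)

    positive = [e for e, w in widths.items() if w > 0]
    vert = (max(positive) - min(positive)) if positive else 0.0
    max_w = max(widths.values())
    max_elev = min(e for e, w in widths.items() if w == max_w)

    return VisualFieldMap(
        binocular_width_by_elevation=widths,
        interpolated_elevations=tuple(interpolated),
        lateral_width_deg=lateral,
        binocular_width_horizontal_deg=binoc_h,
        cyclopean_width_deg=cyclopean,
        blind_width_deg=blind_out,
        vertical_binocular_extent_deg=vert,
        max_overlap_deg=max_w,
        max_overlap_elevation_deg=max_elev,
    )


def read_boundaries_csv(path: str | Path) -> list[FieldBoundaryMeasurement]:
    df = pd.read_csv(path, comment="#")
    needed = {"eye", "elevation_deg", "azimuth_deg", "kind"}
    if not needed.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns {sorted(needed)}")
    return [
        FieldBoundaryMeasurement(
            eye=str(r.eye),
            elevation_deg=float(r.elevation_deg),
            azimuth_deg=float(r.azimuth_deg),
            kind=str(r.kind),
        )
        for r in df.itertuples()
    ]


def write_field_map_csv(fmap: VisualFieldMap, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "elevation_deg": elev,
                "binocular_width_deg": w,
                "interpolated_flag": elev in fmap.interpolated_elevations,
            }
            for elev, w in fmap.binocular_width_by_elevation.items()
        ]
    ).to_csv(path, index=False)
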