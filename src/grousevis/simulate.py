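"""Seeded generators of synthetic inputs for every analysis stage.

Each generator emulates the statistical structure one pipeline stage
assumes: replicate pigment absorbance curves (template + Gaussian
measurement noise), optocollic-reflex trial tables from a deterministic
observer with an optional lapse rate, smooth sum-of-Gaussian reflectance
profiles, and perimeter boundary measurements with optional blocked
elevations.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ParameterError
from .fields import FieldBoundaryMeasurement
from .markers import ReflectanceRecord
from .pigments import AbsorbanceReplicates
from .csf import TrialRecord
from .spectra import Spectrum, TemplateParams, govardovskii_absorbance

__all__ = [
    "gen_absorbance_replicates",
    "gen_ocr_trials",
    "gen_direction_sequence",
    "gen_reflectance",
    "gen_visual_field",
    "DEFAULT_CONTRAST_LADDER",
]

#: 12-level log-spaced contrast ladder spanning the tested range 0.012–0.99.
DEFAULT_CONTRAST_LADDER: tuple[float, ...] = tuple(
    float(c) for c in np.round(np.geomspace(0.012, 0.99, 12), 4)
)


def gen_absorbance_replicates(
    lambda_max: float,
    n: int = 7,
    noise_sd: float = 0.02,
    seed: int = 0,
    grid: Iterable[float] | None = None,
    pigment_name: str = "synthetic",
    baseline_sd: float = 0.0,
    include_beta_band: bool = True,
) -> AbsorbanceReplicates:
    """Replicate absorbance spectra: template + per-point Gaussian noise.

    ``baseline_sd`` adds an optional constant offset per replicate, mimicking
    aliquot-to-aliquot baseline drift.
    """
    if n < 1:
        raise ParameterError("need n >= 1 replicates")
    rng = np.random.default_rng(seed)
    grid = (
        np.arange(300.0, 701.0, 1.0)
        if grid is None
        else np.asarray(list(grid), dtype=float)
    )
    template = govardovskii_absorbance(TemplateParams(lambda_max, include_beta_band), grid)
    reps = []
    for _ in range(n):
        offset = rng.normal(0.0, baseline_sd) if baseline_sd > 0 else 0.0
        vals = template.values + rng.normal(0.0, noise_sd, size=grid.size) + offset
        reps.append(Spectrum(grid, vals))
    return AbsorbanceReplicates(pigment_name, tuple(reps))


def gen_direction_sequence(n: int, seed: int = 0) -> list[str]:
    """Pseudorandom rotation directions, never 4 identical in a row."""
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    for _ in range(n):
        choice = "clockwise" if rng.integers(2) else "anticlockwise"
        if len(seq) >= 3 and seq[-1] == seq[-2] == seq[-3] == choice:
            choice = "anticlockwise" if choice == "clockwise" else "clockwise"
        seq.append(choice)
    return seq


def gen_ocr_trials(
    true_csf: Mapping[float, float],
    contrast_ladder: Sequence[float] = DEFAULT_CONTRAST_LADDER,
    lapse_rate: float = 0.0,
    seed: int = 0,
    individual_id: str = "synthetic",
    n_presentations: int = 5,
) -> list[TrialRecord]:
    """Trial table from a deterministic observer with an optional lapse rate.

    The observer responds when its true sensitivity at the frequency is at
    least the inverse of the presented contrast; each response is flipped
    independently with probability ``lapse_rate``.  Every frequency ×
    contrast combination is presented ``n_presentations`` times with a
    direction sequence limited to three consecutive repeats.
    """
    if not true_csf:
        raise ParameterError("true_csf must map at least one frequency")
    if not (0.0 <= lapse_rate < 1.0):
        raise ParameterError("lapse_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    combos = [
        (f, c) for f in sorted(true_csf) for c in sorted(contrast_ladder, reverse=True)
    ]
    directions = gen_direction_sequence(len(combos) * n_presentations, seed=seed + 1)
    trials: list[TrialRecord] = []
    k = 0
    for freq, contrast in combos:
        for _ in range(n_presentations):
            responds = true_csf[freq] >= 1.0 / contrast
            if lapse_rate > 0 and rng.random() < lapse_rate:
                responds = not responds
            trials.append(
                TrialRecord(
                    individual_id=individual_id,
                    spatial_frequency_cpd=freq,
                    michelson_contrast=contrast,
                    direction=directions[k],
                    response=responds,
                )
            )
            k += 1
    return trials


def gen_reflectance(
    bumps: Sequence[tuple[float, float, float]],
    baseline_pct: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    marker_name: str = "synthetic",
    material_name: str = "material",
    component: str = "diffuse",
) -> ReflectanceRecord:
    """Smooth reflectance: baseline + Gaussian bumps on the 300–780 nm grid.

    Each bump is (center_nm, width_nm, amplitude_pct); amplitudes may push
    values past 100% to mimic fluorescent materials.  Optional Gaussian
    noise is clipped at 0 to keep reflectance physical.
    """
    if any(amp < 0 for _, _, amp in bumps):
        raise ParameterError("bump amplitudes must be non-negative")
    grid = np.arange(300.0, 781.0, 1.0)
    vals = np.full(grid.size, float(baseline_pct))
    for center, width, amp in bumps:
        vals += amp * np.exp(-(((grid - center) / width) ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.clip(vals + rng.normal(0.0, noise_sd, size=grid.size), 0.0, None)
    return ReflectanceRecord(marker_name, material_name, component, Spectrum(grid, vals))


def gen_visual_field(
    binocular_width_by_elevation: Mapping[float, float],
    lateral_each_deg: float | None = 162.5,
    measurement_noise_deg: float = 0.0,
    blocked_elevations: Sequence[float] = (),
    seed: int = 0,
) -> list[FieldBoundaryMeasurement]:
    """Perimeter boundary measurements realising a true field map.

    Converged margins split each elevation's binocular width evenly between
    the eyes; horizontal-plane diverged margins realise the blind sector
    and per-eye lateral fields.  Blocked elevations are dropped so the map
    builder has to interpolate them; optional Gaussian noise perturbs every
    margin.
    """
    rng = np.random.default_rng(seed)
    out: list[FieldBoundaryMeasurement] = []

    def noise() -> float:
        return rng.normal(0.0, measurement_noise_deg) if measurement_noise_deg > 0 else 0.0

    for elev, width in sorted(binocular_width_by_elevation.items()):
        if elev in blocked_elevations:
            continue
        for eye in ("left", "right"):
            out.append(
                FieldBoundaryMeasurement(
                    eye=eye, elevation_deg=elev,
                    azimuth_deg=width / 2.0 + noise(), kind="converged",
                )
            )
    binoc_h = binocular_width_by_elevation.get(0.0)
    if binoc_h is not None and 0.0 not in blocked_elevations and lateral_each_deg is not None:
        # diverged rear margin per eye from the monocular extent identity:
        # extent = conv + 180 − div = binocular + lateral
        conv_h = binoc_h / 2.0
        div_each = conv_h + 180.0 - (binoc_h + lateral_each_deg)
        for eye in ("left", "right"):
            out.append(
                FieldBoundaryMeasurement(
                    eye=eye, elevation_deg=0.0,
                    azimuth_deg=div_each + noise(), kind="diverged",
                )
            )
    return out
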