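"""Contrast sensitivity functions from optocollic-reflex trial tables.

Moving sinusoidal gratings of known spatial frequency and Michelson
contrast elicit an involuntary head-tracking reflex (OCR) when visible.
Each frequency × contrast combination is presented five times; a response
is reliable when the reflex occurs in at least four of the five trials, and
the threshold contrast at a frequency is the lowest reliable contrast.
Sensitivity is the inverse threshold; the per-frequency sensitivities form
the contrast sensitivity function, summarised by its peak sensitivity, the
optimal (peak) frequency and the high cut-off frequency where sensitivity
falls to 1 (only a full-contrast grating is detectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "TrialRecord",
    "CSFPoint",
    "CSF",
    "michelson_contrast",
    "reliable_response",
    "threshold_contrast",
    "build_csf",
    "csf_summary",
    "cutoff_frequency",
    "report_round",
    "read_trials_csv",
    "write_csf_report_csv",
]

#: Tested spatial frequencies (cycles per degree) of the study protocol.
DEFAULT_FREQUENCIES = (0.47, 0.56, 0.85, 1.06, 1.27, 1.59)

#: Tested Michelson contrast range.
CONTRAST_MIN = 0.012
CONTRAST_MAX = 0.99


@dataclass(frozen=True)
class TrialRecord:
    """One grating presentation and whether the reflex occurred."""

    individual_id: str
    spatial_frequency_cpd: float
    michelson_contrast: float
    direction: str  # clockwise | anticlockwise
    response: bool

    def __post_init__(self) -> None:
        if self.spatial_frequency_cpd <= 0:
            raise ParameterError("spatial frequency must be positive")
        if not (0 < self.michelson_contrast <= 1):
            raise ParameterError("contrast must be in (0, 1]")
        if self.direction not in ("clockwise", "anticlockwise"):
            raise ParameterError("direction must be clockwise|anticlockwise")


@dataclass(frozen=True)
class CSFPoint:
    spatial_frequency_cpd: float
    threshold_contrast: float

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.threshold_contrast


@dataclass(frozen=True)
class CSF:
    """One individual's contrast sensitivity function."""

    individual_id: str
    points: tuple[CSFPoint, ...]

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.spatial_frequency_cpd))
        object.__setattr__(self, "points", pts)
        if not pts:
            raise ParameterError("a CSF needs at least one point")

    @property
    def peak_sensitivity(self) -> float:
        return max(p.sensitivity for p in self.points)

    @property
    def peak_frequency_cpd(self) -> float:
        # lowest frequency on ties, for determinism
        return min(
            p.spatial_frequency_cpd
            for p in self.points
            if p.sensitivity == self.peak_sensitivity
        )

    @property
    def cutoff_frequency_cpd(self) -> float | None:
        return cutoff_frequency(self)


def michelson_contrast(i_min: float, i_max: float) -> float:
    """(I_max − I_min)/(I_max + I_min) for luminances in cd m⁻²."""
    if i_min < 0 or i_max < 0:
        raise ParameterError("luminances must be non-negative")
    if i_min > i_max:
        raise ParameterError("i_min must not exceed i_max")
    if i_max + i_min == 0:
        raise DegenerateInputError("contrast undefined for zero total luminance")
    return (i_max - i_min) / (i_max + i_min)


def reliable_response(responses: Sequence[bool]) -> bool:
    """Four-of-five rule: reliable iff ≥4 of exactly 5 presentations responded."""
    if len(responses) != 5:
        raise ParameterError("the reliability rule needs exactly 5 presentations")
    return sum(bool(r) for r in responses) >= 4


def threshold_contrast(trials: Iterable[TrialRecord]) -> CSFPoint | None:
    """Lowest reliable contrast for one individual × one frequency.

    Trials are grouped into 5-presentation blocks per contrast level; the
    threshold is the minimum level whose block satisfies the four-of-five
    rule.  Returns ``None`` when no level is reliable (frequency excluded).
    """
    trials = list(trials)
    if not trials:
        raise ParameterError("no trials supplied")
    ids = {t.individual_id for t in trials}
    freqs = {t.spatial_frequency_cpd for t in trials}
    if len(ids) != 1 or len(freqs) != 1:
        raise ParameterError("trials must cover one individual and one frequency")
    by_level: dict[float, list[bool]] = {}
    for t in trials:
        by_level.setdefault(t.michelson_contrast, []).append(t.response)
    reliable_levels = [
        level for level, resp in by_level.items() if reliable_response(resp)
    ]
    if not reliable_levels:
        return None
    return CSFPoint(next(iter(freqs)), min(reliable_levels))


def build_csf(trials: Iterable[TrialRecord]) -> CSF:
    """Assemble one individual's CSF from their full trial table."""
    trials = list(trials)
    ids = {t.individual_id for t in trials}
    if len(ids) != 1:
        raise ParameterError("build_csf expects a single individual's trials")
    points = []
    for freq in sorted({t.spatial_frequency_cpd for t in trials}):
        pt = threshold_contrast(
            [t for t in trials if t.spatial_frequency_cpd == freq]
        )
        if pt is not None:
            points.append(pt)
    if not points:
        raise DegenerateInputError("no frequency reached a reliable threshold")
    return CSF(next(iter(ids)), tuple(points))


def cutoff_frequency(csf: CSF) -> float | None:
    """High cut-off: frequency where sensitivity falls to 1 (contrast 100%).

    Located on the descending high-frequency limb by log–log linear
    interpolation, or extrapolation of the two highest-frequency points
    when all measured sensitivities exceed 1.  Returns ``None`` when the
    descending limb is absent or not falling.
    """
    if csf.peak_sensitivity < 1.0:
        return None  # whole curve below detection at full contrast
    pts = [p for p in csf.points if p.spatial_frequency_cpd >= csf.peak_frequency_cpd]
    if len(pts) < 2:
        return None
    # endpoint exactly at sensitivity 1
    for a, b in zip(pts, pts[1:]):
        sa, sb = a.sensitivity, b.sensitivity
        if sb == 1.0:
            return b.spatial_frequency_cpd
        if sa > 1.0 > sb:
            return _loglog_cross(a, b)
    last_two = pts[-2:]
    if last_two[1].sensitivity >= last_two[0].sensitivity:
        return None  # limb not descending; no crossing ahead
    return _loglog_cross(*last_two)


def _loglog_cross(a: CSFPoint, b: CSFPoint) -> float:
    la, lb = math.log10(a.spatial_frequency_cpd), math.log10(b.spatial_frequency_cpd)
    sa, sb = math.log10(a.sensitivity), math.log10(b.sensitivity)
    slope = (sb - sa) / (lb - la)
    return 10 ** (la - sa / slope)


def report_round(x: float, ndigits: int = 2) -> float:
    """Half-down rounding used for printed report values (0.955 → 0.95)."""
    q = Decimal(1).scaleb(-ndigits)
    # absorb float representation fuzz before quantizing (0.955000...01 → 0.955)
    return float(Decimal(repr(round(x, 9))).quantize(q, rounding=ROUND_HALF_DOWN))


def csf_summary(csfs: Sequence[CSF]) -> dict:
    """Group summary: mean optimal frequency, mean peak sensitivity, mean curve.

    The mean curve averages sensitivities (not thresholds) at frequencies
    shared by all individuals.  Exact means are retained alongside the
    2-decimal report values.
    """
    if not csfs:
        raise ParameterError("need at least one CSF")
    peak_freqs = [c.peak_frequency_cpd for c in csfs]
    peak_sens = [c.peak_sensitivity for c in csfs]
    mean_freq = float(np.mean(peak_freqs))
    mean_sens = float(np.mean(peak_sens))
    shared = sorted(
        set.intersection(*[{p.spatial_frequency_cpd for p in c.points} for c in csfs])
    )
    mean_curve = {
        f: float(
            np.mean(
                [
                    next(p.sensitivity for p in c.points if p.spatial_frequency_cpd == f)
                    for c in csfs
                ]
            )
        )
        for f in shared
    }
    cutoffs = [c.cutoff_frequency_cpd for c in csfs]
    cutoffs = [c for c in cutoffs if c is not None]
    return {
        "individuals": [c.individual_id for c in csfs],
        "peak_frequencies_cpd": peak_freqs,
        "peak_sensitivities": peak_sens,
        "mean_peak_frequency_cpd": mean_freq,
        "mean_peak_frequency_cpd_report": report_round(mean_freq),
        "mean_peak_sensitivity": mean_sens,
        "mean_peak_sensitivity_report": report_round(mean_sens),
        "min_brightness_difference_pct": 100.0 / mean_sens,
        "mean_curve": mean_curve,
        "mean_cutoff_frequency_cpd": float(np.mean(cutoffs)) if cutoffs else None,
    }


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    """Read the trial dialect: individual_id,spatial_frequency_cpd,contrast,
    block_id,presentation_index,direction,response."""
    df = pd.read_csv(path, comment="#")
    needed = {"individual_id", "spatial_frequency_cpd", "contrast", "direction", "response"}
    if not needed.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns {sorted(needed)}")
    return [
        TrialRecord(
            individual_id=str(r.individual_id),
            spatial_frequency_cpd=float(r.spatial_frequency_cpd),
            michelson_contrast=float(r.contrast),
            direction=str(r.direction),
            response=bool(r.response),
        )
        for r in df.itertuples()
    ]


def write_csf_report_csv(csfs: Sequence[CSF], path: str | Path) -> None:
    rows = [
        {
            "individual_id": c.individual_id,
            "frequency_cpd": p.spatial_frequency_cpd,
            "threshold_contrast": p.threshold_contrast,
            "sensitivity": report_round(p.sensitivity),
        }
        for c in csfs
        for p in c.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
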