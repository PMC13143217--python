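"""Spectrum container, pigment template, normalisation and cutoffs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grousevis.exceptions import DegenerateInputError, OutOfRangeError, ParameterError
from grousevis.spectra import (
    Spectrum,
    TemplateParams,
    cutoff_wavelength,
    govardovskii_absorbance,
    normalize_peak,
    resample,
)


def _alpha_band_scalar(lambda_max: float, lam: float) -> float:
    # independent scalar evaluation of the template's closed form
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        math.exp(69.7 * (a - x))
        + math.exp(28.0 * (0.922 - x))
        + math.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    beta = 0.26 * math.exp(
        -(((lam - (189.0 + 0.315 * lambda_max)) / (-40.5 + 0.195 * lambda_max)) ** 2)
    )
    return alpha + beta


class TestSpectrumInvariants:
    def test_rejects_unsorted_wavelengths(self):
        with pytest.raises(ParameterError):
            Spectrum([500.0, 400.0, 600.0], [1.0, 2.0, 3.0])

    def test_rejects_length_mismatch_and_short(self):
        with pytest.raises(ParameterError):
            Spectrum([400.0, 500.0], [1.0])
        with pytest.raises(ParameterError):
            Spectrum([400.0], [1.0])

    def test_rejects_non_finite_values(self):
        with pytest.raises(ParameterError):
            Spectrum([400.0, 500.0], [1.0, np.nan])

    def test_rejects_out_of_band_wavelengths(self):
        with pytest.raises(ParameterError):
            Spectrum([100.0, 500.0], [1.0, 1.0])


class TestTemplate:
    def test_peak_value_is_one_at_lambda_max(self, fine_grid):
        spec = govardovskii_absorbance(TemplateParams(545.0), fine_grid)
        assert spec.value_at(545.0) == pytest.approx(1.0, abs=1e-3)
        assert np.max(spec.values) == pytest.approx(1.0)

    @pytest.mark.parametrize("lambda_max", [393.0, 436.0, 482.0, 545.0])
    def test_template_bounded_by_one(self, fine_grid, lambda_max):
        spec = govardovskii_absorbance(TemplateParams(lambda_max), fine_grid)
        assert np.all(spec.values <= 1.0 + 1e-12)
        # values equal 1 only in the peak neighbourhood
        near_one = fine_grid[spec.values > 0.999]
        assert np.all(np.abs(near_one - spec.peak_wavelength_nm) < 10.0)

    def test_matches_closed_form_at_one_point(self, fine_grid):
        # λ_max=500 evaluated at 560 nm against independent scalar arithmetic
        spec = govardovskii_absorbance(TemplateParams(500.0), fine_grid)
        raw_560 = _alpha_band_scalar(500.0, 560.0)
        raw_peak = max(_alpha_band_scalar(500.0, l) for l in np.arange(495, 505, 0.1))
        assert spec.value_at(560.0) == pytest.approx(raw_560 / raw_peak, rel=1e-4)

    def test_long_limb_five_percent_cutoff_lw(self, fine_grid):
        # achromatic perception limit of the long-wave cone: ~643 nm
        spec = govardovskii_absorbance(TemplateParams(545.0), fine_grid)
        assert cutoff_wavelength(spec, 0.05, "long") == pytest.approx(643.0, abs=3.0)

    def test_beta_band_adds_short_wavelength_shoulder(self, fine_grid):
        with_beta = govardovskii_absorbance(TemplateParams(545.0, True), fine_grid)
        without = govardovskii_absorbance(TemplateParams(545.0, False), fine_grid)
        assert with_beta.value_at(360.0) > without.value_at(360.0)

    def test_rejects_lambda_max_outside_validity(self):
        with pytest.raises(ParameterError):
            TemplateParams(300.0)
        with pytest.raises(ParameterError):
            TemplateParams(700.0)


class TestCutoff:
    def test_triangular_spectrum_analytic_crossing(self):
        # line segments (400,0)-(500,1)-(600,0): 5% crossings at 405 and 595
        spec = Spectrum([400.0, 500.0, 600.0], [0.0, 1.0, 0.0])
        assert cutoff_wavelength(spec, 0.05, "long") == pytest.approx(595.0)
        assert cutoff_wavelength(spec, 0.05, "short") == pytest.approx(405.0)

    def test_level_one_returns_peak(self, fine_grid):
        spec = govardovskii_absorbance(TemplateParams(482.0), fine_grid)
        assert cutoff_wavelength(spec, 1.0, "long") == spec.peak_wavelength_nm

    def test_sides_bracket_the_peak(self, fine_grid):
        spec = govardovskii_absorbance(TemplateParams(482.0, False), fine_grid)
        lo = cutoff_wavelength(spec, 0.5, "short")
        hi = cutoff_wavelength(spec, 0.5, "long")
        assert lo < spec.peak_wavelength_nm < hi

    def test_uncrossed_level_raises(self):
        spec = Spectrum([400.0, 500.0, 600.0], [0.5, 1.0, 0.5])
        with pytest.raises(OutOfRangeError):
            cutoff_wavelength(spec, 0.05, "long")

    def test_long_cutoff_monotone_in_lambda_max(self, fine_grid):
        cuts = []
        for lm in np.arange(400.0, 561.0, 20.0):
            spec = govardovskii_absorbance(TemplateParams(float(lm)), fine_grid)
            cuts.append(cutoff_wavelength(spec, 0.05, "long"))
        assert np.all(np.diff(cuts) > 0)


class TestNormalizeResample:
    def test_normalize_scales_to_one(self):
        spec = normalize_peak(Spectrum([400.0, 500.0, 600.0], [2.0, 4.0, 8.0]))
        assert spec.values == pytest.approx([0.25, 0.5, 1.0])

    def test_normalize_idempotent(self):
        spec = Spectrum([400.0, 500.0, 600.0], [0.1, 0.9, 0.4])
        once = normalize_peak(spec)
        twice = normalize_peak(once)
        assert np.array_equal(once.values, twice.values)

    def test_normalize_rejects_nonpositive(self):
        with pytest.raises(DegenerateInputError):
            normalize_peak(Spectrum([400.0, 500.0], [-1.0, 0.0]))

    def test_resample_identity_on_own_grid(self, coarse_grid):
        spec = govardovskii_absorbance(TemplateParams(500.0), coarse_grid)
        again = resample(spec, coarse_grid)
        assert np.array_equal(again.values, spec.values)

    def test_resample_midpoint(self):
        spec = Spectrum([400.0, 500.0], [0.0, 1.0])
        assert resample(spec, [450.0, 500.0]).values[0] == pytest.approx(0.5)

    def test_resample_refuses_extrapolation(self):
        spec = Spectrum([400.0, 500.0], [0.0, 1.0])
        with pytest.raises(OutOfRangeError):
            resample(spec, [390.0, 450.0])

    def test_dense_template_resampled_keeps_peak(self):
        dense = govardovskii_absorbance(TemplateParams(482.0), np.arange(300.0, 700.01, 0.1))
        coarse = resample(dense, np.arange(300.0, 700.5, 1.0))
        assert abs(coarse.peak_wavelength_nm - dense.peak_wavelength_nm) <= 1.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_resample_idempotent_property(self, seed):
        rng = np.random.default_rng(seed)
        wl = np.sort(rng.uniform(300.0, 800.0, size=20))
        wl += np.arange(20) * 1e-6  # enforce strict increase
        spec = Spectrum(wl, rng.uniform(0.0, 2.0, size=20))
        grid = np.linspace(wl[0], wl[-1], 15)
        once = resample(spec, grid)
        twice = resample(once, grid)
        assert np.allclose(once.values, twice.values)
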