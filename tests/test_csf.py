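"""Contrast thresholds, CSF assembly and summaries."""

import numpy as np
import pytest

from grousevis.csf import (
    CSF,
    CSFPoint,
    TrialRecord,
    build_csf,
    csf_summary,
    cutoff_frequency,
    michelson_contrast,
    reliable_response,
    report_round,
    threshold_contrast,
)
from grousevis.exceptions import DegenerateInputError, ParameterError
from grousevis.simulate import gen_direction_sequence, gen_ocr_trials


def _block(freq, contrast, n_true, individual="A"):
    """Five presentations of one frequency x contrast combination."""
    return [
        TrialRecord(individual, freq, contrast, "clockwise", i < n_true)
        for i in range(5)
    ]


class TestMichelson:
    @pytest.mark.parametrize(
        "i_min, i_max, expected",
        [(50.0, 50.0, 0.0), (0.0, 80.0, 1.0), (20.0, 80.0, 0.6)],
    )
    def test_known_values(self, i_min, i_max, expected):
        assert michelson_contrast(i_min, i_max) == pytest.approx(expected)

    def test_degenerate_and_invalid(self):
        with pytest.raises(DegenerateInputError):
            michelson_contrast(0.0, 0.0)
        with pytest.raises(ParameterError):
            michelson_contrast(10.0, 5.0)


class TestReliability:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ([True] * 5, True),
            ([True, True, True, True, False], True),
            ([True, True, True, False, False], False),
            ([False] * 5, False),
        ],
    )
    def test_four_of_five_rule(self, pattern, expected):
        assert reliable_response(pattern) is expected

    def test_wrong_count_rejected(self):
        with pytest.raises(ParameterError):
            reliable_response([True, True, True])


class TestThreshold:
    def test_lowest_reliable_level_wins(self):
        trials = (
            _block(0.85, 0.99, 5)
            + _block(0.85, 0.20, 5)
            + _block(0.85, 0.06, 4)
            + _block(0.85, 0.03, 2)
        )
        pt = threshold_contrast(trials)
        assert pt.threshold_contrast == pytest.approx(0.06)
        assert pt.sensitivity == pytest.approx(16.67, abs=0.01)

    def test_boundary_minimum_ladder_level(self):
        trials = _block(0.47, 0.99, 5) + _block(0.47, 0.012, 5)
        assert threshold_contrast(trials).threshold_contrast == pytest.approx(0.012)

    def test_no_reliable_level_flagged(self):
        trials = _block(1.59, 0.99, 3) + _block(1.59, 0.5, 1)
        assert threshold_contrast(trials) is None

    def test_mixed_individuals_rejected(self):
        trials = _block(0.85, 0.2, 5, "A") + _block(0.85, 0.2, 5, "B")
        with pytest.raises(ParameterError):
            threshold_contrast(trials)

    def test_sensitivity_is_exact_inverse(self):
        pt = CSFPoint(0.85, 0.06)
        assert pt.sensitivity * pt.threshold_contrast == pytest.approx(1.0)

    def test_added_reliability_only_lowers_threshold(self):
        base = _block(0.85, 0.99, 5) + _block(0.85, 0.20, 5) + _block(0.85, 0.06, 2)
        more = _block(0.85, 0.99, 5) + _block(0.85, 0.20, 5) + _block(0.85, 0.06, 4)
        assert (
            threshold_contrast(more).threshold_contrast
            <= threshold_contrast(base).threshold_contrast
        )


class TestCutoff:
    def test_endpoint_at_sensitivity_one(self):
        csf = CSF("A", (CSFPoint(0.85, 0.06), CSFPoint(1.27, 0.25), CSFPoint(1.59, 1.0)))
        assert cutoff_frequency(csf) == pytest.approx(1.59)

    def test_loglog_limb_crossing_at_constructed_value(self):
        # descending limb built log-log linear so sensitivity hits 1 at 1.6 cpd
        f1, f2, target = 1.06, 1.27, 1.6
        slope = -4.0
        s2 = (f2 / target) ** slope
        s1 = (f1 / target) ** slope
        csf = CSF(
            "A",
            (CSFPoint(0.85, 1 / 20.0), CSFPoint(f1, 1 / s1), CSFPoint(f2, 1 / s2)),
        )
        assert cutoff_frequency(csf) == pytest.approx(target, rel=1e-6)

    def test_flat_low_csf_has_no_cutoff(self):
        csf = CSF("A", (CSFPoint(0.85, 0.99), CSFPoint(1.27, 0.99)))
        assert cutoff_frequency(csf) is None

    def test_extrapolation_lands_beyond_last_measured_frequency(self):
        # sensitivities stay above 1 for any contrast <= 0.99, so the
        # crossing is extrapolated past the highest tested frequency
        csf = CSF("A", (CSFPoint(0.85, 0.06), CSFPoint(1.27, 0.25), CSFPoint(1.59, 0.9)))
        cut = cutoff_frequency(csf)
        assert cut > 1.59


class TestSummary:
    def test_mean_optimal_frequency_from_two_individuals(self):
        a = CSF("A", (CSFPoint(0.85, 0.06), CSFPoint(1.06, 0.1)))
        b = CSF("B", (CSFPoint(0.85, 0.1), CSFPoint(1.06, 0.06)))
        s = csf_summary([a, b])
        assert s["mean_peak_frequency_cpd"] == pytest.approx(0.955)
        assert s["mean_peak_frequency_cpd_report"] == pytest.approx(0.95)
        assert s["mean_peak_sensitivity_report"] == pytest.approx(16.67)
        # peak sensitivity 16.67 means a ~6% minimum brightness difference
        assert s["min_brightness_difference_pct"] == pytest.approx(6.0, abs=0.01)

    def test_single_individual_equals_group(self):
        a = CSF("A", (CSFPoint(0.85, 0.06),))
        s = csf_summary([a])
        assert s["mean_peak_frequency_cpd"] == a.peak_frequency_cpd
        assert s["mean_peak_sensitivity"] == a.peak_sensitivity

    def test_mean_curve_averages_sensitivities(self):
        a = CSF("A", (CSFPoint(0.85, 0.05), CSFPoint(1.06, 0.1)))
        b = CSF("B", (CSFPoint(0.85, 0.1), CSFPoint(1.06, 0.1)))
        s = csf_summary([a, b])
        assert s["mean_curve"][0.85] == pytest.approx((20.0 + 10.0) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            csf_summary([])

    def test_report_round_half_down(self):
        assert report_round(0.955) == 0.95
        assert report_round(0.9551) == 0.96
        assert report_round(16.666666, 2) == 16.67


class TestSyntheticObserverRecovery:
    def test_deterministic_observer_recovers_ladder_thresholds(self):
        ladder = [0.012, 0.03, 0.06, 0.1, 0.25, 0.5, 0.99]
        truth = {0.47: 6.0, 0.85: 16.67, 1.27: 4.0}
        trials = gen_ocr_trials(truth, contrast_ladder=ladder, lapse_rate=0.0, seed=0)
        csf = build_csf(trials)
        for pt in csf.points:
            # expected: smallest ladder contrast c with truth >= 1/c
            expected = min(c for c in ladder if truth[pt.spatial_frequency_cpd] >= 1 / c)
            assert pt.threshold_contrast == pytest.approx(expected)

    def test_peak_sensitivity_16_67_with_ladder_containing_006(self):
        trials = gen_ocr_trials({0.95: 16.67}, contrast_ladder=[0.03, 0.06, 0.99], seed=1)
        csf = build_csf(trials)
        assert csf.points[0].threshold_contrast == pytest.approx(0.06)

    def test_unresponsive_observer_has_no_csf(self):
        trials = gen_ocr_trials({0.85: 0.0}, contrast_ladder=[0.06, 0.99], seed=2)
        with pytest.raises(DegenerateInputError):
            build_csf(trials)

    def test_direction_sequence_limits_repeats(self):
        seq = gen_direction_sequence(500, seed=3)
        run = 1
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            assert run <= 3
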