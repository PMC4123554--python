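"""Sinc pattern, correlation scoring, first-disk detection, peak
normalization, and the sequential template-guided scan."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertelab import phantom
from vertelab.detection import (
    MODE_CORRELATED,
    MODE_FALLBACK,
    DetectionState,
    DiskDetection,
    accept_or_fallback,
    correlation_curve,
    detect_all_disks,
    detect_first_disk,
    make_pattern,
    normalize_peaks,
    parabolic_offset,
    predict_location,
    refine_location,
    update_ratio,
)
from vertelab.io import T2_LIKE
from vertelab.profile import IntensityProfile


def make_profile(values, step=1.0):
    values = np.asarray(values, dtype=float)
    n = len(values)
    coords = np.column_stack([np.zeros(n), np.zeros(n), -np.arange(n) * step])
    return IntensityProfile(np.arange(n) * step, values, T2_LIKE, coords)


def raised_cosine_train(n, centers, heights, width=4.0):
    s = np.arange(float(n))
    v = np.zeros(n)
    for c, h in zip(centers, heights):
        d = np.abs(s - c)
        v += h * np.where(d <= width, 0.5 * (1 + np.cos(np.pi * d / width)), 0.0)
    return v


def oracle_score(window, pattern_samples):
    """Independent re-derivation of the projection correlation score."""
    w = np.asarray(window, float) - np.mean(window)
    p = np.asarray(pattern_samples, float) - np.mean(pattern_samples)
    return float(np.dot(w, p) / np.dot(p, p))


class TestMakePattern:
    def test_center_sample_is_one(self):
        assert make_pattern().samples[5] == pytest.approx(1.0)

    def test_symmetry(self):
        s = make_pattern(width_mm=12.0, n=9).samples
        assert np.allclose(s, s[::-1])

    def test_closed_form_value_at_5mm(self):
        # sinc(1/3)^20 with the normalized sinc = (sin(pi/3)/(pi/3))^20
        val = make_pattern(width_mm=15.0, n=10).samples[10]
        expected = (np.sin(np.pi / 3) / (np.pi / 3)) ** 20
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.0224, abs=5e-4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_pattern(width_mm=0.0)
        with pytest.raises(ValueError):
            make_pattern(n=0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        width=st.floats(10.0, 20.0),
        n=st.integers(8, 12),
        step=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_pattern_properties(self, width, n, step):
        pat = make_pattern(width, n, step)
        assert len(pat.samples) == 11
        assert np.all(pat.samples >= 0)
        assert pat.samples[5] == pytest.approx(1.0)
        assert np.allclose(pat.samples, pat.samples[::-1])


class TestCorrelationCurve:
    def test_matches_oracle_at_every_interior_offset(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=60)
        pat = make_pattern()
        corr = correlation_curve(v, pat)
        for i in range(5, 55):
            assert corr[i] == pytest.approx(oracle_score(v[i - 5 : i + 6], pat.samples))

    def test_clean_unit_peak_scores_near_one(self):
        v = raised_cosine_train(60, [30], [1.0])
        corr = correlation_curve(v, make_pattern())
        assert np.argmax(corr) == 30
        assert 0.8 < corr[30] < 1.3


class TestDetectFirstDisk:
    def test_most_rostral_of_two_identical_peaks(self):
        v = raised_cosine_train(80, [20, 45], [1.0, 1.0])
        pos, score = detect_first_disk(make_profile(v))
        assert abs(pos - 20) <= 1.0

    def test_single_peak_position_and_score_match_brute_force(self):
        v = raised_cosine_train(80, [30], [1.0])
        pat = make_pattern()
        pos, score = detect_first_disk(make_profile(v), pat)
        brute = [oracle_score(v[i - 5 : i + 6], pat.samples) for i in range(5, 75)]
        assert abs(pos - 30) <= 1.0
        assert score == pytest.approx(max(brute))

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=120)
        v /= v.max()
        with pytest.raises(ValueError, match="starting level"):
            detect_first_disk(make_profile(v))


class TestNormalizePeaks:
    def test_unequal_peaks_flattened(self):
        v = raised_cosine_train(120, [20, 60, 100], [1.0, 0.5, 0.25])
        out = normalize_peaks(make_profile(v), min_separation_mm=8.0)
        assert out.values[[20, 60, 100]] == pytest.approx(1.0, abs=0.05)

    def test_uniform_peaks_are_fixed_point(self):
        v = raised_cosine_train(120, [20, 60, 100], [1.0, 1.0, 1.0])
        out = normalize_peaks(make_profile(v), min_separation_mm=8.0)
        assert np.abs(out.values[[20, 60, 100]] - v[[20, 60, 100]]).max() < 1e-6

    def test_decaying_train_ratio_restored(self):
        centers = [15, 40, 65, 90, 115]
        heights = [1.0, 0.7, 0.5, 0.35, 0.25]
        v = raised_cosine_train(130, centers, heights)
        out = normalize_peaks(make_profile(v), min_separation_mm=8.0)
        ratio = out.values[115] / out.values[15]
        assert ratio >= 0.9

    def test_too_few_maxima_is_identity_with_warning(self):
        v = raised_cosine_train(60, [30], [1.0])
        with pytest.warns(UserWarning, match="skipped"):
            out = normalize_peaks(make_profile(v))
        assert np.allclose(out.values, v)


class TestPredictAndRatio:
    def make_state(self, detections, ratio=1.0, template=None):
        template = template or phantom.default_phantom_template()
        return DetectionState(
            first_peak_loc=detections[0].position_mm,
            template=template,
            detections=list(detections),
            ratio=ratio,
        )

    def test_first_prediction_uses_generic_gap(self, default_template):
        state = self.make_state(
            [DiskDetection(2, 50.0, 0.9, MODE_CORRELATED)], ratio=1.0
        )
        gap = default_template.gap_from(2).mean_mm
        assert predict_location(state) == pytest.approx(50.0 + gap)

    def test_prediction_scales_with_ratio(self, default_template):
        for ratio in (0.9, 1.1):
            state = self.make_state(
                [
                    DiskDetection(2, 50.0, 0.9, MODE_CORRELATED),
                    DiskDetection(3, 68.0, 0.9, MODE_CORRELATED),
                ],
                ratio=ratio,
            )
            gap = default_template.gap_from(3).mean_mm
            assert predict_location(state) == pytest.approx(68.0 + gap * ratio)

    def test_template_exhausted_returns_none(self, default_template):
        last = default_template.last_disk_level
        state = self.make_state([DiskDetection(last, 300.0, 0.9, MODE_CORRELATED)])
        assert predict_location(state) is None

    def test_ratio_detected_over_template_span(self, default_template):
        # detected span 36 mm over two gaps whose template span is 40 mm
        gaps = [
            phantom.TemplateGap(2, 3, 18.0, 1.0, 6),
            phantom.TemplateGap(3, 4, 22.0, 1.0, 6),
        ]
        t = phantom.DiskTemplate(gaps=gaps)
        state = self.make_state(
            [
                DiskDetection(2, 50.0, 0.9, MODE_CORRELATED),
                DiskDetection(3, 66.0, 0.9, MODE_CORRELATED),
                DiskDetection(4, 86.0, 0.9, MODE_CORRELATED),
            ],
            template=t,
        )
        assert update_ratio(state) == pytest.approx(36.0 / 40.0)

    def test_single_detection_keeps_ratio_one(self):
        state = self.make_state([DiskDetection(2, 50.0, 0.9, MODE_CORRELATED)])
        assert update_ratio(state) == 1.0

    def test_ratio_clamped(self):
        gaps = [
            phantom.TemplateGap(2, 3, 20.0, 1.0, 6),
            phantom.TemplateGap(3, 4, 20.0, 1.0, 6),
        ]
        t = phantom.DiskTemplate(gaps=gaps)
        state = self.make_state(
            [
                DiskDetection(2, 50.0, 0.9, MODE_CORRELATED),
                DiskDetection(3, 90.0, 0.9, MODE_CORRELATED),
                DiskDetection(4, 130.0, 0.9, MODE_CORRELATED),
            ],
            template=t,
        )
        assert update_ratio(state) == pytest.approx(1.3)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(span=st.floats(1.0, 200.0))
    def test_ratio_always_within_clamp(self, span):
        gaps = [
            phantom.TemplateGap(2, 3, 20.0, 1.0, 6),
            phantom.TemplateGap(3, 4, 20.0, 1.0, 6),
        ]
        t = phantom.DiskTemplate(gaps=gaps)
        state = self.make_state(
            [
                DiskDetection(2, 0.0, 0.9, MODE_CORRELATED),
                DiskDetection(3, span / 2, 0.9, MODE_CORRELATED),
                DiskDetection(4, span, 0.9, MODE_CORRELATED),
            ],
            template=t,
        )
        assert 0.7 <= update_ratio(state) <= 1.3


class TestRefineLocation:
    def test_windowed_argmax_matches_brute_force(self):
        v = raised_cosine_train(120, [70], [1.0])
        prof = make_profile(v)
        pat = make_pattern()
        pos, score = refine_location(prof, pat, 68.0, 4.0)
        corr = correlation_curve(v, pat)
        idx = [i for i in range(120) if abs(i - 68.0) <= 4.0]
        best = max(idx, key=lambda i: corr[i])
        assert abs(pos - 70.0) <= 1.0
        assert score == pytest.approx(corr[best])

    def test_flat_window_ties_to_prediction(self):
        prof = make_profile(np.zeros(60))
        pos, score = refine_location(prof, make_pattern(), 30.0, 4.0)
        assert score == 0.0
        assert pos == pytest.approx(30.0)

    def test_two_equal_peaks_pick_nearer_prediction(self):
        # configuration symmetric about 66 so both peaks score identically
        v = raised_cosine_train(120, [62, 70], [1.0, 1.0])
        prof = make_profile(v)
        pos, _ = refine_location(prof, make_pattern(), 65.0, 5.0)
        assert pos == pytest.approx(62.0, abs=0.5)
        pos, _ = refine_location(prof, make_pattern(), 67.0, 5.0)
        assert pos == pytest.approx(70.0, abs=0.5)

    def test_window_outside_profile_signals_end(self):
        prof = make_profile(np.zeros(50))
        assert refine_location(prof, make_pattern(), 200.0, 5.0) is None


class TestAcceptOrFallback:
    def test_below_forty_percent_of_median_falls_back(self):
        assert accept_or_fallback(0.30, [0.8, 0.9, 1.0]) == MODE_FALLBACK

    def test_above_threshold_accepted(self):
        assert accept_or_fallback(0.50, [0.8, 0.9, 1.0]) == MODE_CORRELATED

    def test_empty_history_always_accepts(self):
        assert accept_or_fallback(0.01, []) == MODE_CORRELATED

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        history=st.lists(st.floats(0.01, 2.0), min_size=1, max_size=10),
        score=st.floats(0.0, 2.0),
    )
    def test_rule_matches_direct_median_computation(self, history, score):
        mode = accept_or_fallback(score, history)
        expected = MODE_FALLBACK if score < 0.4 * np.median(history) else MODE_CORRELATED
        assert mode == expected


class TestDetectAllDisks:
    def test_noiseless_phantom_all_correlated_within_1mm(
        self, straight_phantom, default_template
    ):
        from vertelab.profile import (
            centerline_from_mask,
            detrend_profile,
            normalize_profile,
            sample_profile,
            shift_centerline_anterior,
        )

        _, volume, truth = straight_phantom
        cl = centerline_from_mask(truth.cord_mask)
        prof = sample_profile(volume, shift_centerline_anterior(cl))
        prof = normalize_profile(detrend_profile(prof))
        prof = normalize_peaks(prof, min_separation_mm=8.0)
        dets = detect_all_disks(prof, default_template)
        assert len(dets) == len(truth.true_disk_positions_mm)
        for d in dets:
            assert d.mode == MODE_CORRELATED
            assert abs(d.position_mm - truth.true_disk_positions_mm[d.level]) < 1.0

    def test_ablated_peak_resolved_by_fallback(self, default_template):
        truth_pos = sorted(phantom.default_disk_positions().items())
        centers = [p for _, p in truth_pos]
        v = raised_cosine_train(370, centers, [1.0] * len(centers))
        ablated_level, ablated_pos = truth_pos[5]
        d = np.abs(np.arange(370.0) - ablated_pos)
        v -= np.where(d <= 4, 0.5 * (1 + np.cos(np.pi * d / 4)), 0.0)
        dets = detect_all_disks(make_profile(v), default_template)
        by_level = {det.level: det for det in dets}
        gap = default_template.gap_from(ablated_level - 1).mean_mm
        assert by_level[ablated_level].mode == MODE_FALLBACK
        assert abs(by_level[ablated_level].position_mm - ablated_pos) <= 0.2 * gap
        for lvl, pos in truth_pos:
            if lvl != ablated_level:
                assert by_level[lvl].mode == MODE_CORRELATED
                assert abs(by_level[lvl].position_mm - pos) < 1.0

    def test_user_start_scans_caudally_only(self, default_template):
        truth_pos = sorted(phantom.default_disk_positions().items())
        centers = [p for _, p in truth_pos]
        v = raised_cosine_train(370, centers, [1.0] * len(centers))
        start_level, start_pos = truth_pos[6]  # T1-T2
        dets = detect_all_disks(
            make_profile(v), default_template, start=(start_level, start_pos)
        )
        assert dets[0].level == start_level
        assert all(d.level >= start_level for d in dets)
        assert len(dets) == len(truth_pos) - 6

    def test_positions_strictly_increasing_and_levels_unique(self, clean_profile,
                                                             default_template):
        dets = detect_all_disks(clean_profile, default_template)
        positions = [d.position_mm for d in dets]
        levels = [d.level for d in dets]
        assert np.all(np.diff(positions) > 0)
        assert len(set(levels)) == len(levels)

    def test_scale_equivariance_at_115_percent(self, default_template):
        base = sorted(phantom.default_disk_positions().items())
        scaled = {lvl: pos * 1.15 for lvl, pos in base}
        centers = [scaled[lvl] for lvl, _ in base]
        v = raised_cosine_train(420, centers, [1.0] * len(centers))
        dets = detect_all_disks(make_profile(v), default_template)
        assert [d.level for d in dets] == [lvl for lvl, _ in base]
        for d in dets:
            assert abs(d.position_mm - scaled[d.level]) < 1.5


def test_parabolic_offset_recovers_fractional_peak():
    s = np.arange(50.0)
    v = np.exp(-((s - 25.3) ** 2) / 20.0)
    i = int(np.argmax(v))
    refined = i + parabolic_offset(v, i)
    assert refined == pytest.approx(25.3, abs=0.05)
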