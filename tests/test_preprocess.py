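import numpy as np
import pytest
from scipy.stats import kstest

from fallstack.preprocess import (
    WindowingConfig,
    extract_activity_clips,
    extract_fall_clips,
    extract_home_clips,
    find_impact_peak,
    magnitude_filter,
    resample_channels,
    resample_clip,
)
from fallstack.simulate import SimConfig, simulate_home_stream, \
    simulate_lab_session
from fallstack.types import AnnotationEvent, SensorStream


def _stream_from(t, accel, gyro=None, subject="S1"):
    if gyro is None:
        gyro = np.zeros_like(accel)
    return SensorStream(subject, "control", t, accel, gyro)


class TestFallWindowing:
    def test_one_fall_yields_ten_clips_inside_event_window(self, lab_session, wcfg):
        stream, events = lab_session
        event = next(e for e in events if e.is_fall)
        clips = extract_fall_clips(stream, event, wcfg,
                                   rng=np.random.default_rng(0))
        assert len(clips) == wcfg.windows_per_fall == 10
        peak = find_impact_peak(stream, event)
        for clip in clips:
            assert clip.is_fall
            assert clip.accel.shape == (3, 250)
            assert clip.window_start_s >= peak - 5.0 - 1e-9
            assert clip.window_start_s + 5.0 <= peak + 5.0 + 1e-9
            assert 0.0 < clip.onset_offset_s < 3.0

    def test_fall_too_close_to_stream_start_errors(self, wcfg):
        rng = np.random.default_rng(1)
        t = np.arange(300) / 50.0  # 6 s of data only
        accel = rng.normal(0, 0.01, (300, 3)) + [0, 0, 1.0]
        accel[100] = [0, 0, 4.0]  # impact at t = 2 s
        stream = _stream_from(t, accel)
        event = AnnotationEvent("S1", "control", "trip", True, "waist", 1.5, 4.0)
        with pytest.raises(ValueError, match="does not cover"):
            extract_fall_clips(stream, event, wcfg)

    def test_event_without_samples_errors(self, wcfg):
        t = np.arange(100) / 50.0
        stream = _stream_from(t, np.ones((100, 3)))
        event = AnnotationEvent("S1", "control", "trip", True, "waist", 50.0, 51.0)
        with pytest.raises(ValueError, match="no samples"):
            extract_fall_clips(stream, event, wcfg)

    def test_onset_offsets_uniform_on_0_3(self, lab_session, wcfg):
        stream, events = lab_session
        rng = np.random.default_rng(3)
        offsets = []
        for event in (e for e in events if e.is_fall):
            for clip in extract_fall_clips(stream, event, wcfg, rng=rng):
                offsets.append(clip.onset_offset_s)
        stat = kstest(np.array(offsets) / 3.0, "uniform")
        assert stat.pvalue > 0.01

    def test_peak_selection_rotation_invariant(self, lab_session, wcfg):
        stream, events = lab_session
        event = next(e for e in events if e.is_fall)
        rot = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        rotated = SensorStream(
            stream.subject, stream.population, stream.timestamps,
            stream.accel @ rot.T, stream.gyro @ rot.T,
        )
        assert find_impact_peak(stream, event) == \
            find_impact_peak(rotated, event)


class TestActivityWindowing:
    def _activity_stream(self, duration, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration * 50)
        t = np.arange(n) / 50.0
        accel = rng.normal(0, 0.05, (n, 3)) + [0, 0, 1.0]
        return _stream_from(t, accel)

    def test_47s_interval_yields_9_clips(self, wcfg):
        stream = self._activity_stream(48.0)
        event = AnnotationEvent("S1", "control", "walking", False, "waist",
                                0.0, 47.0)
        clips = extract_activity_clips(stream, [event], wcfg)
        assert len(clips) == 9
        assert not any(c.is_fall for c in clips)

    def test_interval_shorter_than_window_yields_none(self, wcfg):
        stream = self._activity_stream(6.0)
        event = AnnotationEvent("S1", "control", "standing", False, "waist",
                                0.0, 4.9)
        assert extract_activity_clips(stream, [event], wcfg) == []

    def test_windows_are_nonoverlapping_and_tile_the_interval(self, wcfg):
        stream = self._activity_stream(33.0)
        event = AnnotationEvent("S1", "control", "walking", False, "waist",
                                1.0, 32.0)
        clips = extract_activity_clips(stream, [event], wcfg)
        starts = [c.window_start_s for c in clips]
        assert starts == [1.0 + 5.0 * k for k in range(len(starts))]

    def test_session_clip_count_matches_brute_force_tiling(self, lab_session, wcfg):
        stream, events = lab_session
        activities = [e for e in events if not e.is_fall]
        clips = extract_activity_clips(stream, activities, wcfg)
        expected = sum(int((e.t_end - e.t_start) // 5.0) for e in activities)
        assert len(clips) == expected


class TestMagnitudeFilter:
    def test_stationary_clip_removed_spike_clip_retained(self, wcfg):
        quiet = np.zeros((3, 250))
        quiet[2] = 1.0
        spike = quiet.copy()
        spike[2, 100] = 2.5
        from fallstack.types import Clip

        clips = [
            Clip("S", "control", "waist", False, quiet, np.zeros((3, 250))),
            Clip("S", "control", "waist", False, spike, np.zeros((3, 250))),
        ]
        kept = magnitude_filter(clips, 2.0)
        assert kept == [clips[1]]

    def test_matches_brute_force_max_norm_scan(self, lab_clips):
        kept = magnitude_filter(lab_clips, 2.0)
        expected = [
            c for c in lab_clips
            if max(
                (ax * ax + ay * ay + az * az) ** 0.5
                for ax, ay, az in zip(*c.accel)
            ) > 2.0
        ]
        assert kept == expected

    def test_idempotent(self, lab_clips):
        once = magnitude_filter(lab_clips, 2.0)
        assert magnitude_filter(once, 2.0) == once

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            magnitude_filter([], -1.0)


class TestResampling:
    def test_uniform_50hz_input_reproduced_at_nodes(self, wcfg):
        rng = np.random.default_rng(5)
        t = np.arange(260) / 50.0
        accel = rng.normal(0, 1, (260, 3))
        gyro = rng.normal(0, 1, (260, 3))
        clip = resample_clip(t, accel, gyro, wcfg)
        np.testing.assert_allclose(clip.accel, accel[:250].T, atol=1e-9)
        np.testing.assert_allclose(clip.gyro, gyro[:250].T, atol=1e-9)

    def test_any_valid_input_yields_250_samples(self, wcfg):
        rng = np.random.default_rng(6)
        n = 180  # irregular ~35 Hz sampling
        t = np.sort(rng.uniform(0, 5.2, n))
        clip = resample_clip(t, rng.normal(0, 1, (n, 3)),
                             rng.normal(0, 1, (n, 3)), wcfg)
        assert clip.accel.shape == clip.gyro.shape == (3, 250)

    def test_cubic_polynomial_reconstructed_exactly(self, wcfg):
        # not-a-knot cubic splines reproduce cubics; closed-form oracle
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(-0.1, 5.2, 300))
        coeffs = rng.normal(0, 1, (3, 4))

        def poly(ts):
            return np.stack(
                [c[0] + c[1] * ts + c[2] * ts**2 + c[3] * ts**3 for c in coeffs]
            )

        out = resample_channels(t, poly(t).T, 0.0, 250, 50.0)
        grid = np.arange(250) / 50.0
        np.testing.assert_allclose(out, poly(grid), atol=1e-9)

    def test_too_few_samples_rejected(self, wcfg):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match=">= 4 samples"):
            resample_channels(t, np.ones((3, 3)), 0.0, 250, 50.0)

    def test_short_span_rejected(self, wcfg):
        t = np.arange(100) / 50.0  # 2 s
        with pytest.raises(ValueError, match="span"):
            resample_clip(t, np.ones((100, 3)), np.ones((100, 3)), wcfg)


class TestHomeExtraction:
    def test_prescreened_extraction_matches_exhaustive_filtering(self):
        cfg = SimConfig(seed=11, home_days=0.02, adl_supra2g_rate=120.0)
        stream = simulate_home_stream(cfg, "A09")
        wcfg = WindowingConfig(rng_seed=1)
        clips = extract_home_clips(stream, wcfg)
        # exhaustive oracle: resample every window, then filter
        t = stream.timestamps
        n_windows = int((t[-1] - t[0]) // 5.0)
        all_clips = []
        for k in range(n_windows):
            w0 = t[0] + 5.0 * k
            sel = (t >= w0 - 0.2) & (t <= w0 + 5.2)
            all_clips.append(
                resample_clip(t[sel], stream.accel[sel], stream.gyro[sel],
                              wcfg, t0=w0)
            )
        expected = magnitude_filter(all_clips, 2.0)
        assert [c.window_start_s for c in clips] == \
            [c.window_start_s for c in expected]
        assert all(not c.is_fall for c in clips)


class TestWindowingConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            WindowingConfig(event_window_s=3.0)
        with pytest.raises(ValueError):
            WindowingConfig(onset_range_s=(0.0, 6.0))
        with pytest.raises(ValueError):
            WindowingConfig(filter_threshold_g=0.0)
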