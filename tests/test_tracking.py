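import numpy as np
import pytest

from ehtkit import (
    DetectionParams,
    Recording,
    TwitchSpec,
    detect_markers,
    make_twitch_trace,
    render_marker_video,
    track_pair,
)
from ehtkit.errors import TrackingError
from ehtkit.synth import _render_disk


def _frame_with_disks(centers, radius=8.0, shape=(200, 400)):
    img = np.full(shape, 0.85)
    for cx, cy in centers:
        _render_disk(img, cx, cy, radius, 0.08)
    return img


class TestDetectMarkers:
    def test_two_disks_localized_within_half_pixel(self):
        frame = _frame_with_disks([(100.0, 100.0), (300.0, 100.0)])
        found = detect_markers(frame)
        assert len(found) == 2
        assert found[0] == pytest.approx((100.0, 100.0), abs=0.5)
        assert found[1] == pytest.approx((300.0, 100.0), abs=0.5)

    def test_blank_frame_yields_empty_list(self):
        assert detect_markers(np.full((64, 64), 0.9)) == []

    def test_three_disks_all_returned(self):
        frame = _frame_with_disks([(60.0, 100.0), (200.0, 60.0), (330.0, 140.0)])
        found = detect_markers(frame)
        assert len(found) == 3
        assert [x for x, _ in found] == sorted(x for x, _ in found)

    def test_area_filter_rejects_specks(self):
        frame = _frame_with_disks([(100.0, 100.0)], radius=1.5)
        assert detect_markers(frame, DetectionParams(min_area=20)) == []

    @pytest.mark.parametrize("noise_sd,tol", [(0.0, 0.25), (0.05, 0.5)])
    def test_subpixel_accuracy(self, noise_sd, tol):
        """Centroid error stays sub-pixel on random fractional disk positions."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(10):
            cx = 100.0 + rng.uniform(-0.5, 0.5)
            cy = 100.0 + rng.uniform(-0.5, 0.5)
            frame = _frame_with_disks([(cx, cy), (300.0, 100.0)])
            if noise_sd:
                frame = np.clip(frame + rng.normal(0, noise_sd, frame.shape), 0, 1)
            found = detect_markers(frame)
            assert len(found) == 2
            worst = max(worst, float(np.hypot(found[0][0] - cx, found[0][1] - cy)))
        assert worst < tol

    def test_intensity_rescaling_moves_centroids_less_than_tenth_pixel(self):
        frame = _frame_with_disks([(100.3, 99.6), (300.0, 100.0)])
        rescaled = 0.2 + 0.6 * frame  # contrast change, same polarity
        a = detect_markers(frame)
        b = detect_markers(rescaled)
        for (xa, ya), (xb, yb) in zip(a, b):
            assert np.hypot(xa - xb, ya - yb) < 0.1


def _static_recording(n_frames=100, centers=((70.0, 60.0), (170.0, 60.0))):
    frame = _frame_with_disks(list(centers), radius=9.0, shape=(120, 240))
    return Recording(
        frames=np.repeat(frame[None], n_frames, axis=0), frame_rate=100.0, pixel_size=2.0
    )


class TestTrackPair:
    def test_static_video_gives_zero_deflection(self):
        trace = track_pair(_static_recording())
        assert np.all(np.abs(trace.deflection) < 0.1)
        assert trace.baseline_distance == pytest.approx(200.0, abs=0.5)

    def test_oscillating_disks_recover_programmed_amplitude(self):
        # each marker moves 5 px toward the other -> 10 px = 20 µm total deflection
        spec = TwitchSpec(amplitude=20.0, pacing_frequency=1.0, duty=0.4, phase=0.3)
        twitch = make_twitch_trace(spec, duration=3.0, frame_rate=100.0)
        rec, _ = render_marker_video(twitch.values, pixel_size=2.0, seed=1)
        trace = track_pair(rec)
        assert trace.deflection.max() == pytest.approx(20.0, abs=1.0)

    def test_long_blank_gap_raises_with_frame_range(self):
        rec = _static_recording(100)
        frames = rec.frames.copy()
        frames[40:61] = 0.9  # blank out frames 40-60
        broken = Recording(frames=frames, frame_rate=100.0, pixel_size=2.0)
        with pytest.raises(TrackingError, match=r"40–60"):
            track_pair(broken, max_gap=10)

    def test_short_gap_interpolated_and_flagged(self):
        rec = _static_recording(50)
        frames = rec.frames.copy()
        frames[20:24] = 0.9
        patched = Recording(frames=frames, frame_rate=100.0, pixel_size=2.0)
        trace = track_pair(patched, max_gap=5)
        assert trace.interpolated[20:24].all()
        assert not trace.interpolated[:20].any()
        assert np.all(np.abs(trace.deflection) < 0.1)

    def test_translation_invariance(self):
        """Shifting every frame by an integer offset leaves the distance trace unchanged."""
        spec = TwitchSpec(amplitude=12.0, pacing_frequency=1.0, duty=0.4)
        twitch = make_twitch_trace(spec, duration=2.0, frame_rate=100.0)
        rec, _ = render_marker_video(twitch.values, pixel_size=2.0, seed=2)
        shifted = Recording(
            frames=np.roll(rec.frames, (7, 13), axis=(1, 2)),
            frame_rate=rec.frame_rate,
            pixel_size=rec.pixel_size,
        )
        d0 = track_pair(rec).distance
        d1 = track_pair(shifted).distance
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_third_blob_does_not_derail_pair_continuity(self):
        rec = _static_recording(30)
        frames = rec.frames.copy()
        for i in range(30):  # extra dot wandering near the pair
            _render_disk(frames[i], 120.0 + 0.3 * i, 30.0, 6.0, 0.08)
        rec3 = Recording(frames=frames, frame_rate=100.0, pixel_size=2.0)
        trace = track_pair(rec3)
        assert trace.distance == pytest.approx(200.0, abs=0.5)

    def test_deflection_nonnegative_when_markers_only_approach(self):
        spec = TwitchSpec(amplitude=10.0, pacing_frequency=1.0, duty=0.4)
        twitch = make_twitch_trace(spec, duration=3.0, frame_rate=100.0)
        rec, _ = render_marker_video(twitch.values, pixel_size=2.0, noise_sd=0.03, seed=3)
        trace = track_pair(rec)
        eps = 2 * 0.5 * rec.pixel_size  # 2 × centroid error bound × calibration
        assert trace.deflection.min() > -eps

    def test_per_post_convention_halves_deflection(self):
        spec = TwitchSpec(amplitude=10.0, pacing_frequency=1.0, duty=0.4)
        twitch = make_twitch_trace(spec, duration=2.0, frame_rate=100.0)
        rec, _ = render_marker_video(twitch.values, pixel_size=2.0, seed=4)
        total = track_pair(rec).deflection
        half = track_pair(rec, per_post_deflection=True).deflection
        np.testing.assert_allclose(half, total / 2.0)

    def test_tracking_table_columns(self):
        df = track_pair(_static_recording(20)).to_frame()
        assert list(df.columns) == [
            "frame", "time_s", "x1", "y1", "x2", "y2",
            "distance_um", "deflection_um", "interpolated_flag",
        ]
        assert len(df) == 20
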