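import numpy as np
import pytest

from ehtkit import (
    TwitchSpec,
    analyze_force_trace,
    beat_features,
    make_twitch_trace,
    segment_beats,
    summarize_recording,
)
from ehtkit.errors import FeatureExtractionError, NoBeatsError, ValidationError
from ehtkit.kinetics import BeatFeatures

from conftest import force_trace_from_values

# closed forms for a raised-cosine twitch F(t) = A/2·(1 − cos 2πt/d), from onset
A, D = 10.0, 0.4
T10 = D * np.arccos(0.8) / (2 * np.pi)  # 0.040967 s
T90 = D * np.arccos(-0.8) / (2 * np.pi)  # 0.159033 s
MAX_DFDT = A * np.pi / D  # 78.5398 µN/s


def raised_cosine_window(frame_rate=100.0, pre=0.3, post=0.3, amplitude=A, duration=D):
    """One twitch embedded in a beat window with flat baseline on both sides."""
    n = int(round((pre + duration + post) * frame_rate))
    t = np.arange(n) / frame_rate
    tau = t - pre
    f = np.where(
        (tau >= 0) & (tau <= duration),
        amplitude / 2.0 * (1.0 - np.cos(2 * np.pi * np.clip(tau, 0, duration) / duration)),
        0.0,
    )
    return f, t


class TestSegmentBeats:
    def test_ten_second_paced_train_gives_ten_windows(self):
        trace = make_twitch_trace(TwitchSpec(amplitude=10.0), duration=10.0, frame_rate=100.0)
        windows = segment_beats(force_trace_from_values(trace.values), pacing_frequency=1.0)
        assert len(windows) == 10

    def test_constant_trace_raises_no_beats_with_noise_estimate(self):
        with pytest.raises(NoBeatsError) as err:
            segment_beats(force_trace_from_values(np.ones(500)), pacing_frequency=1.0)
        assert err.value.noise_estimate is not None

    def test_auto_mode_recovers_two_hertz_rate(self):
        spec = TwitchSpec(amplitude=8.0, pacing_frequency=2.0, duty=0.4, phase=0.3)
        trace = make_twitch_trace(spec, duration=5.0, frame_rate=100.0)
        ft = force_trace_from_values(trace.values)
        windows = segment_beats(ft, pacing_frequency=None)
        assert len(windows) == 10
        _, summary = analyze_force_trace(ft, pacing_frequency=None)
        assert summary.beat_rate == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("pacing", [0.5, 1.0, 2.0, 3.0])
    def test_count_matches_programmed_beats_across_pacing(self, pacing):
        spec = TwitchSpec(amplitude=10.0, pacing_frequency=pacing, duty=0.4, phase=0.3)
        trace = make_twitch_trace(spec, duration=8.0, frame_rate=100.0)
        windows = segment_beats(force_trace_from_values(trace.values), pacing_frequency=pacing)
        assert len(windows) == trace.beat_count

    def test_trace_shorter_than_two_periods_rejected(self):
        with pytest.raises(ValidationError):
            segment_beats(force_trace_from_values(np.zeros(100)), pacing_frequency=1.0)


class TestBeatFeatures:
    def test_raised_cosine_closed_form_dense_grid(self):
        """At dense sampling the estimator reproduces the analytic twitch features."""
        f, t = raised_cosine_window(frame_rate=10_000.0)
        b = beat_features(f, t)
        assert b.peak_force == pytest.approx(A, rel=1e-6)
        assert b.t10_contraction == pytest.approx(T10, abs=2e-4)
        assert b.t90_contraction == pytest.approx(T90, abs=2e-4)
        assert b.t90_contraction - b.t10_contraction == pytest.approx(T90 - T10, abs=2e-4)
        assert b.t10_relaxation == pytest.approx(T10, abs=2e-4)
        assert b.t90_relaxation == pytest.approx(T90, abs=2e-4)
        assert b.contraction_velocity == pytest.approx(MAX_DFDT, rel=0.01)
        assert b.relaxation_velocity == pytest.approx(MAX_DFDT, rel=0.01)

    def test_time_rescaling_identity(self):
        """t → t/k divides every time readout by k, multiplies velocities by k."""
        k = 2.0
        f1, t1 = raised_cosine_window(frame_rate=1000.0)
        b1 = beat_features(f1, t1)
        b2 = beat_features(f1, t1 / k)  # same samples on a compressed clock
        assert b2.peak_force == pytest.approx(b1.peak_force, rel=1e-9)
        assert b2.t10_contraction == pytest.approx(b1.t10_contraction / k, rel=1e-6)
        assert b2.t90_relaxation == pytest.approx(b1.t90_relaxation / k, rel=1e-6)
        assert b2.contraction_velocity == pytest.approx(k * b1.contraction_velocity, rel=1e-6)

    def test_amplitude_scaling_homogeneity(self):
        c = 3.7
        f, t = raised_cosine_window(frame_rate=1000.0)
        b1 = beat_features(f, t)
        b2 = beat_features(c * f, t)
        assert b2.peak_force == pytest.approx(c * b1.peak_force)
        assert b2.contraction_velocity == pytest.approx(c * b1.contraction_velocity, rel=1e-9)
        assert b2.t10_contraction == pytest.approx(b1.t10_contraction, rel=1e-9)
        assert b2.t90_relaxation == pytest.approx(b1.t90_relaxation, rel=1e-9)

    def test_time_shift_changes_only_beat_start(self):
        f, t = raised_cosine_window(frame_rate=1000.0)
        b1 = beat_features(f, t)
        b2 = beat_features(f, t + 5.0)
        assert b2.beat_start_time == pytest.approx(b1.beat_start_time + 5.0)
        assert b2.t10_contraction == pytest.approx(b1.t10_contraction)
        assert b2.amplitude == pytest.approx(b1.amplitude)

    def test_noisy_train_recovers_programmed_kinetics(self):
        """2% amplitude noise: peak within 3%, timings within one frame + 5%,
        velocities within 10% of the programmed ground truth."""
        spec = TwitchSpec(amplitude=10.0, noise_sd=0.02, seed=5)
        trace = make_twitch_trace(spec, duration=10.0, frame_rate=100.0)
        truth = trace.ground_truth
        _, s = analyze_force_trace(force_trace_from_values(trace.values), pacing_frequency=1.0)
        frame = 0.01
        assert s.mean["peak_force"] == pytest.approx(truth["peak"], rel=0.03)
        for key in ("t10_contraction", "t90_contraction", "t10_relaxation", "t90_relaxation"):
            assert s.mean[key] == pytest.approx(truth[key], abs=frame + 0.05 * truth[key])
        assert s.mean["contraction_velocity"] == pytest.approx(
            truth["contraction_velocity"], rel=0.10
        )
        assert s.mean["relaxation_velocity"] == pytest.approx(
            truth["relaxation_velocity"], rel=0.10
        )

    def test_asymmetric_twitch_contracts_faster_than_it_relaxes(self):
        spec = TwitchSpec(amplitude=10.0, shape="asymmetric_two_phase", rise_fraction=0.3)
        trace = make_twitch_trace(spec, duration=5.0, frame_rate=200.0)
        _, s = analyze_force_trace(force_trace_from_values(trace.values, 200.0), 1.0)
        assert s.mean["contraction_velocity"] > s.mean["relaxation_velocity"]
        truth = trace.ground_truth
        assert s.mean["contraction_velocity"] == pytest.approx(
            truth["contraction_velocity"], rel=0.05
        )

    def test_garbage_window_raises_feature_error(self):
        with pytest.raises(FeatureExtractionError):
            beat_features(np.linspace(1, 0, 50), np.arange(50) / 100.0)  # no upstroke

    def test_too_short_window_rejected(self):
        with pytest.raises(FeatureExtractionError):
            beat_features(np.zeros(5), np.arange(5) / 100.0)


def _beat(amplitude, start=0.0):
    return BeatFeatures(
        beat_start_time=start,
        peak_time=start + 0.2,
        peak_force=amplitude,
        baseline_force=0.0,
        amplitude=amplitude,
        contraction_velocity=amplitude * 8.0,
        relaxation_velocity=amplitude * 7.0,
        t10_contraction=0.04,
        t90_contraction=0.16,
        t10_relaxation=0.04,
        t90_relaxation=0.16,
    )


class TestSummarizeRecording:
    def test_identical_beats_have_zero_sd(self):
        s = summarize_recording([_beat(10.0, i) for i in range(10)], duration=10.0,
                                pacing_frequency=1.0)
        assert s.beat_count == 10
        assert s.beat_rate == pytest.approx(1.0)
        assert s.mean_amplitude == pytest.approx(10.0)
        assert all(v == 0.0 for v in s.sd.values())

    def test_sample_standard_deviation(self):
        s = summarize_recording([_beat(8.0), _beat(10.0), _beat(12.0)], duration=3.0)
        assert s.mean_amplitude == pytest.approx(10.0)
        assert s.sd["amplitude"] == pytest.approx(2.0)  # sample (n−1) formula

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            summarize_recording([], duration=10.0)
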