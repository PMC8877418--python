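"""Twitch segmentation and per-beat kinetic readouts.

A 10-s recording paced at 1 Hz contains ten twitches. Segmentation places one
window per pacing period with boundaries at the pre-upstroke baseline minima
between successive peaks; without a pacing frequency, peaks are detected by
prominence and the dominant period is estimated from the peak spacing.
Incomplete first/last beats (windows that do not return to baseline on both
sides) are discarded.

Per-beat conventions
--------------------
baseline
    mean of the first ``baseline_frac`` of the window (the pre-upstroke rest
    phase).
amplitude
    peak − baseline.
t10/t90 of contraction
    time from upstroke onset (last baseline crossing before the peak) to the
    first crossing of baseline + 10% / 90% of the amplitude.
t10/t90 of relaxation
    time from the peak to the first crossing of baseline + 90% / 10% of the
    amplitude on the decay — i.e. 10% / 90% of relaxation *completed*.
velocities
    extrema of the Savitzky–Golay-smoothed derivative on the upstroke / decay,
    in µN/s (µm/s if the input is a deflection trace).

All crossings are located by linear interpolation between samples, so the
timing readouts are sub-frame accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import FeatureExtractionError, NoBeatsError, ValidationError
from .mechanics import ForceTrace

__all__ = [
    "KineticsParams",
    "BeatFeatures",
    "RecordingSummary",
    "segment_beats",
    "beat_features",
    "summarize_recording",
    "analyze_force_trace",
]

#: BeatFeatures fields aggregated into a RecordingSummary
FEATURE_FIELDS = (
    "peak_force",
    "baseline_force",
    "amplitude",
    "contraction_velocity",
    "relaxation_velocity",
    "t10_contraction",
    "t90_contraction",
    "t10_relaxation",
    "t90_relaxation",
)


@dataclass(frozen=True)
class KineticsParams:
    """Settings for segmentation and feature extraction.

    ``savgol_window`` (samples) and ``savgol_order`` control derivative
    smoothing; the defaults (11, 3) suit 100 fps acquisition. ``baseline_frac``
    is the leading fraction of each beat window averaged into the baseline.
    ``prominence_frac`` (fraction of the global amplitude) gates peak detection
    in unpaced (auto) mode.
    """

    baseline_frac: float = 0.1
    prominence_frac: float = 0.2
    savgol_window: int = 11
    savgol_order: int = 3
    completeness_frac: float = 0.3


@dataclass(frozen=True)
class BeatFeatures:
    """Kinetic summary of a single twitch. Units are µN and seconds
    (µm if the analyzed trace is a deflection rather than a force)."""

    beat_start_time: float
    peak_time: float
    peak_force: float
    baseline_force: float
    amplitude: float
    contraction_velocity: float
    relaxation_velocity: float
    t10_contraction: float
    t90_contraction: float
    t10_relaxation: float
    t90_relaxation: float


@dataclass(frozen=True)
class RecordingSummary:
    """Mean/SD of every beat feature over the complete beats of one recording."""

    identifier: str
    beat_count: int
    beat_rate: float
    duration: float
    pacing_frequency: float | None
    mean: dict
    sd: dict

    @property
    def mean_amplitude(self) -> float:
        return self.mean["amplitude"]

    @property
    def mean_contraction_velocity(self) -> float:
        return self.mean["contraction_velocity"]

    @property
    def mean_relaxation_velocity(self) -> float:
        return self.mean["relaxation_velocity"]

    def to_frame(self) -> pd.DataFrame:
        row: dict = {
            "identifier": self.identifier,
            "beat_count": self.beat_count,
            "beat_rate_hz": self.beat_rate,
            "duration_s": self.duration,
            "pacing_frequency_hz": self.pacing_frequency,
        }
        for f in FEATURE_FIELDS:
            row[f + "_mean"] = self.mean[f]
            row[f + "_sd"] = self.sd[f]
        return pd.DataFrame([row])


def _noise_estimate(values: np.ndarray) -> float:
    """Robust noise SD from first differences (MAD-based)."""
    d = np.diff(values)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)) if len(d) else 0.0


def segment_beats(
    force: ForceTrace,
    pacing_frequency: float | None = None,
    params: KineticsParams | None = None,
) -> list[tuple[int, int]]:
    """Split a force trace into per-twitch index windows ``(start, stop)``.

    With ``pacing_frequency`` given, one window per pacing period with the
    larger of any competing peaks winning within a period; without it, peaks
    are found by prominence (``prominence_frac`` × global amplitude) and the
    period is the median peak spacing. Incomplete first/last beats — windows
    whose boundary samples sit well above baseline — are discarded.

    Raises
    ------
    NoBeatsError
        If no peak rises above the noise floor; carries the noise estimate.
    """
    params = params or KineticsParams()
    values = np.asarray(force.force, dtype=np.float64)
    times = np.asarray(force.time, dtype=np.float64)
    n = len(values)
    if n < 2:
        raise ValidationError("force trace too short to segment")
    dt = times[1] - times[0]
    if pacing_frequency is not None:
        if pacing_frequency <= 0:
            raise ValidationError("pacing_frequency must be positive")
        if times[-1] - times[0] < 2.0 / pacing_frequency:
            raise ValidationError("trace shorter than two pacing periods")
    elif times[-1] - times[0] < 1.0:
        raise ValidationError("unpaced segmentation needs at least 1 s of signal")

    amp = float(values.max() - values.min())
    noise = _noise_estimate(values)
    prominence = max(params.prominence_frac * amp, 4.0 * noise)
    if amp <= 0 or (noise > 0 and amp < 6.0 * noise):
        raise NoBeatsError("no beats detected: trace amplitude within noise floor", noise)

    if pacing_frequency is not None:
        period_s = 1.0 / pacing_frequency
        distance = max(1, int(round(0.75 * period_s / dt)))
    else:
        distance = max(1, int(round(0.1 / dt)))
    peaks, _ = find_peaks(values, prominence=prominence, distance=distance)
    if len(peaks) == 0:
        raise NoBeatsError("no beats detected above the noise floor", noise)

    if pacing_frequency is None:
        period_s = float(np.median(np.diff(peaks))) * dt if len(peaks) > 1 else times[-1] - times[0]
    period = max(2, int(round(period_s / dt)))

    def _boundary(lo: int, hi_: int) -> int:
        # center of the rest plateau between two peaks: with noise the raw
        # argmin can sit right at the next upstroke, which would rob the beat
        # window of its pre-upstroke baseline segment
        seg = values[lo : hi_ + 1]
        near_min = np.flatnonzero(seg <= seg.min() + 0.05 * amp)
        return lo + int(near_min[len(near_min) // 2])

    # window boundaries between successive peaks, extended by one period at the edges
    bounds = [_boundary(max(0, peaks[0] - period), peaks[0])]
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        bounds.append(_boundary(p0, p1))
    last = peaks[-1]
    bounds.append(_boundary(last, min(n - 1, last + period)))

    baseline_level = float(np.min(values))
    windows: list[tuple[int, int]] = []
    for lo, hi_, pk in zip(bounds[:-1], bounds[1:], peaks):
        # completeness: both boundaries back near baseline, peak interior
        limit = baseline_level + params.completeness_frac * amp
        if values[lo] > limit or values[hi_] > limit:
            continue
        if pk - lo < 2 or hi_ - pk < 2:
            continue
        windows.append((lo, hi_ + 1))
    return windows


def _cross_up(values, times, lo, hi, level):
    """First upward crossing time of `level` in [lo, hi], linearly interpolated."""
    for i in range(lo, hi):
        if values[i] < level <= values[i + 1]:
            f = (level - values[i]) / (values[i + 1] - values[i])
            return float(times[i] + f * (times[i + 1] - times[i]))
        if values[i] == level:
            return float(times[i])
    return None


def _cross_down(values, times, lo, hi, level):
    """First downward crossing time of `level` in [lo, hi], linearly interpolated."""
    for i in range(lo, hi):
        if values[i] > level >= values[i + 1]:
            f = (values[i] - level) / (values[i] - values[i + 1])
            return float(times[i] + f * (times[i + 1] - times[i]))
        if values[i] == level:
            return float(times[i])
    return None


def beat_features(
    window: np.ndarray, times: np.ndarray, params: KineticsParams | None = None
) -> BeatFeatures:
    """Extract kinetic features from one beat window (one upstroke + one decay).

    Raises :class:`FeatureExtractionError` on garbage windows (no amplitude,
    no baseline crossing, no relaxation) — callers exclude such beats from the
    recording summary.
    """
    params = params or KineticsParams()
    values = np.asarray(window, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    n = len(values)
    if n < 10:
        raise FeatureExtractionError(f"beat window too short ({n} samples)")
    dt = float(times[1] - times[0])

    n_base = max(1, int(round(params.baseline_frac * n)))
    baseline = float(values[:n_base].mean())
    peak_idx = int(np.argmax(values))
    peak = float(values[peak_idx])
    amplitude = peak - baseline
    if amplitude <= 0:
        raise FeatureExtractionError("non-positive amplitude")

    # upstroke onset: last baseline crossing before the peak
    onset_idx = None
    for i in range(peak_idx, -1, -1):
        if values[i] <= baseline:
            onset_idx = i
            break
    if onset_idx is None:
        raise FeatureExtractionError("no baseline crossing before peak")
    if values[onset_idx] == baseline or onset_idx == peak_idx:
        onset_time = float(times[onset_idx])
    else:
        f = (baseline - values[onset_idx]) / (values[onset_idx + 1] - values[onset_idx])
        onset_time = float(times[onset_idx] + f * dt)

    lvl10 = baseline + 0.10 * amplitude
    lvl90 = baseline + 0.90 * amplitude
    t10c = _cross_up(values, times, onset_idx, peak_idx + 1, lvl10)
    t90c = _cross_up(values, times, onset_idx, peak_idx + 1, lvl90)
    t10r = _cross_down(values, times, peak_idx, n - 1, lvl90)  # 10% relaxed
    t90r = _cross_down(values, times, peak_idx, n - 1, lvl10)  # 90% relaxed
    if None in (t10c, t90c, t10r, t90r):
        raise FeatureExtractionError("missing threshold crossing (incomplete twitch)")
    peak_time = float(times[peak_idx])

    wl = min(params.savgol_window, n if n % 2 == 1 else n - 1)
    if wl > params.savgol_order + 1:
        deriv = savgol_filter(values, wl, params.savgol_order, deriv=1, delta=dt)
    else:
        deriv = np.gradient(values, dt)
    contraction_velocity = float(np.max(deriv[onset_idx : peak_idx + 1]))
    relaxation_velocity = float(np.max(-deriv[peak_idx:]))

    return BeatFeatures(
        beat_start_time=float(times[0]),
        peak_time=peak_time,
        peak_force=peak,
        baseline_force=baseline,
        amplitude=amplitude,
        contraction_velocity=max(contraction_velocity, 0.0),
        relaxation_velocity=max(relaxation_velocity, 0.0),
        t10_contraction=t10c - onset_time,
        t90_contraction=t90c - onset_time,
        t10_relaxation=t10r - peak_time,
        t90_relaxation=t90r - peak_time,
    )


def summarize_recording(
    beats: list[BeatFeatures],
    duration: float,
    pacing_frequency: float | None = None,
    identifier: str = "",
) -> RecordingSummary:
    """Mean/SD of each beat feature; ``beat_rate = beat_count / duration``.

    SD uses the sample (n−1) formula; a single beat reports SD 0.
    """
    if not beats:
        raise ValidationError("cannot summarize an empty beat list")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    mean: dict = {}
    sd: dict = {}
    for f in FEATURE_FIELDS:
        vals = np.array([getattr(b, f) for b in beats], dtype=np.float64)
        mean[f] = float(vals.mean())
        # identical values report exactly 0 (two-pass std leaves ~1e-17 residue)
        sd[f] = float(vals.std(ddof=1)) if len(vals) > 1 and np.ptp(vals) > 0 else 0.0
    return RecordingSummary(
        identifier=identifier,
        beat_count=len(beats),
        beat_rate=len(beats) / duration,
        duration=duration,
        pacing_frequency=pacing_frequency,
        mean=mean,
        sd=sd,
    )


def analyze_force_trace(
    force: ForceTrace,
    pacing_frequency: float | None = None,
    params: KineticsParams | None = None,
) -> tuple[list[BeatFeatures], RecordingSummary]:
    """Segment, extract features beat-by-beat (excluding failures), summarize."""
    params = params or KineticsParams()
    windows = segment_beats(force, pacing_frequency, params)
    beats = []
    for lo, hi in windows:
        try:
            beats.append(beat_features(force.force[lo:hi], force.time[lo:hi], params))
        except FeatureExtractionError:
            continue
    if not beats:
        raise NoBeatsError("all beat windows failed feature extraction", _noise_estimate(force.force))
    duration = float(force.time[-1] - force.time[0]) + force.frame_interval
    summary = summarize_recording(beats, duration, pacing_frequency, identifier=force.identifier)
    return beats, summary
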