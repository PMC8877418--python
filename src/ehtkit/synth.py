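"""Synthetic fixtures with known ground truth.

Everything the analysis pipeline consumes can be generated here with exact
programmed answers: parametric twitch trains (with closed-form or dense-grid
kinetic ground truth), rendered marker videos (anti-aliased dark discs on a
light background with exact sub-pixel centroids), Hill dose–response tables,
and tissue silhouettes of analytic area.

Every generator is a pure function of its seed and parameters: identical
inputs produce bit-identical outputs. Noise models cover the two dominant
brightfield artifacts — additive Gaussian sensor noise and slow sinusoidal
illumination drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dose import hill_response
from .errors import ValidationError
from .io import Recording

__all__ = [
    "TwitchSpec",
    "TwitchTrace",
    "MarkerLayout",
    "make_twitch_trace",
    "render_marker_video",
    "write_recording_tiff",
    "make_dose_table",
    "make_tissue_silhouette",
    "dense_grid_truth",
]


@dataclass(frozen=True)
class TwitchSpec:
    """Parameters of a periodic twitch train.

    ``amplitude`` is in the caller's unit (µm for deflection, µN for force).
    ``duty`` is the twitch duration as a fraction of the pacing period,
    ``phase`` the fraction of the period of rest before the upstroke (so the
    trace never starts mid-twitch), ``rise_fraction`` the share of the twitch
    spent contracting (0.5 = symmetric). ``noise_sd`` is relative to the
    amplitude.
    """

    amplitude: float = 10.0
    pacing_frequency: float = 1.0
    duty: float = 0.4
    shape: str = "raised_cosine"  # or "asymmetric_two_phase"
    rise_fraction: float = 0.5
    phase: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.duty < 1):
            raise ValidationError("duty must be in (0, 1)")
        if not (0 < self.rise_fraction < 1):
            raise ValidationError("rise_fraction must be in (0, 1)")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")
        if not (0 <= self.phase < 1 - self.duty + 1e-12):
            raise ValidationError("phase must leave room for the twitch within the period")
        if self.shape not in ("raised_cosine", "asymmetric_two_phase"):
            raise ValidationError(f"unknown twitch shape {self.shape!r}")


@dataclass
class TwitchTrace:
    """A generated trace plus its analytic ground truth."""

    time: np.ndarray
    values: np.ndarray
    spec: TwitchSpec
    frame_rate: float
    beat_count: int
    ground_truth: dict  # per-beat kinetic features, noise-free


def _twitch_shape(tau: np.ndarray, duration: float, rise_fraction: float, shape: str) -> np.ndarray:
    """Unit-amplitude twitch evaluated at in-twitch time ``tau`` ∈ [0, duration]."""
    out = np.zeros_like(tau)
    inside = (tau >= 0) & (tau <= duration)
    t = tau[inside]
    if shape == "raised_cosine":
        out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))
    else:  # asymmetric_two_phase: raised-cosine rise then raised-cosine decay
        tr = rise_fraction * duration
        td = duration - tr
        rise = t <= tr
        vals = np.empty_like(t)
        vals[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / tr))
        vals[~rise] = 0.5 * (1.0 + np.cos(np.pi * (t[~rise] - tr) / td))
        out[inside] = vals
    return out


def dense_grid_truth(
    spec: TwitchSpec, n_grid: int = 200_001
) -> dict:
    """Noise-free kinetic ground truth of one twitch via a dense numeric grid.

    Threshold crossings are located by linear interpolation on ``n_grid``
    points across the twitch; max slopes by central finite differences. For a
    raised cosine this reproduces the closed forms
    t10 = (d/2π)·arccos(0.8), t90 = (d/2π)·arccos(−0.8) (measured from onset)
    and max |dF/dt| = Aπ/d to grid accuracy — it is an oracle independent of
    the analysis module's estimator.
    """
    d = spec.duty / spec.pacing_frequency
    A = spec.amplitude
    t = np.linspace(0.0, d, n_grid)
    f = A * _twitch_shape(t, d, spec.rise_fraction, spec.shape)
    peak_idx = int(np.argmax(f))

    def up(level):
        i = int(np.argmax(f[: peak_idx + 1] >= level))
        if i == 0:
            return 0.0
        frac = (level - f[i - 1]) / (f[i] - f[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    def down(level):
        rel = f[peak_idx:]
        i = int(np.argmax(rel <= level))
        frac = (rel[i - 1] - level) / (rel[i - 1] - rel[i])
        return float(t[peak_idx + i - 1] + frac * (t[1] - t[0]))

    df = np.gradient(f, t)
    return {
        "peak": float(A),
        "baseline": 0.0,
        "amplitude": float(A),
        "twitch_duration": float(d),
        "t10_contraction": up(0.1 * A),
        "t90_contraction": up(0.9 * A),
        "t10_relaxation": down(0.9 * A) - float(t[peak_idx]),
        "t90_relaxation": down(0.1 * A) - float(t[peak_idx]),
        "contraction_velocity": float(df[: peak_idx + 1].max()),
        "relaxation_velocity": float(-df[peak_idx:].min()),
    }


def make_twitch_trace(
    spec: TwitchSpec, duration: float = 10.0, frame_rate: float = 100.0
) -> TwitchTrace:
    """Sample a periodic twitch train and report its noise-free ground truth.

    Deterministic for a fixed ``spec.seed``. The ground truth is computed on
    the analytic waveform (dense grid), never from the sampled/noisy trace.
    """
    period = 1.0 / spec.pacing_frequency
    if duration < period:
        raise ValidationError("duration must cover at least one pacing period")
    n = int(round(duration * frame_rate))
    time = np.arange(n) / frame_rate
    d = spec.duty * period
    onset = spec.phase * period
    tau = (time % period) - onset
    values = spec.amplitude * _twitch_shape(tau, d, spec.rise_fraction, spec.shape)
    # complete twitches fitting in [0, duration]: onsets at (phase + k)·period
    beat_count = int(np.floor((duration - onset - d) / period + 1e-9)) + 1
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd * spec.amplitude, size=n)
    return TwitchTrace(
        time=time,
        values=values,
        spec=spec,
        frame_rate=frame_rate,
        beat_count=beat_count,
        ground_truth=dense_grid_truth(spec),
    )


@dataclass(frozen=True)
class MarkerLayout:
    """Rendering geometry for the two cantilever-top markers.

    Defaults mimic the platform scaled to a small field of view: two dark
    discs (the carbon-black-stained 1 mm post caps) on a light background,
    separated along x. Intensities are in [0, 1].
    """

    frame_height: int = 120
    frame_width: int = 240
    radius_px: float = 9.0
    left_x: float = 70.0
    right_x: float = 170.0
    center_y: float = 60.0
    background: float = 0.85
    marker: float = 0.08


def _render_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float, ss: int = 4) -> None:
    """Alpha-composite an anti-aliased disk via ss× supersampled coverage."""
    h, w = img.shape
    x0, x1 = max(0, int(np.floor(cx - r)) - 1), min(w - 1, int(np.ceil(cx + r)) + 1)
    y0, y1 = max(0, int(np.floor(cy - r)) - 1), min(h - 1, int(np.ceil(cy + r)) + 1)
    if x1 < x0 or y1 < y0:
        return
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    xs = np.arange(x0, x1 + 1)[:, None] + sub[None, :]  # (nx, ss)
    ys = np.arange(y0, y1 + 1)[:, None] + sub[None, :]
    dx2 = (xs - cx) ** 2  # (nx, ss)
    dy2 = (ys - cy) ** 2  # (ny, ss)
    inside = (dy2[:, None, :, None] + dx2[None, :, None, :]) <= r * r  # (ny, nx, ss, ss)
    coverage = inside.mean(axis=(2, 3))
    patch = img[y0 : y1 + 1, x0 : x1 + 1]
    img[y0 : y1 + 1, x0 : x1 + 1] = patch * (1.0 - coverage) + value * coverage


def render_marker_video(
    deflection_um: np.ndarray,
    pixel_size: float,
    frame_rate: float = 100.0,
    layout: MarkerLayout | None = None,
    noise_sd: float = 0.0,
    illumination_amp: float = 0.0,
    illumination_period_s: float = 5.0,
    seed: int = 0,
    identifier: str = "synthetic",
) -> tuple[Recording, pd.DataFrame]:
    """Render a marker video realizing a programmed deflection trace.

    Each marker moves toward the other by half the deflection, so the
    inter-marker distance shrinks by exactly ``deflection_um(t)``. Returns the
    Recording and a ground-truth table with exact sub-pixel centroids and the
    programmed distance per frame. Bit-reproducible for a fixed seed.
    """
    layout = layout or MarkerLayout()
    delta_px = np.asarray(deflection_um, dtype=np.float64) / pixel_size
    n = len(delta_px)
    sep0 = layout.right_x - layout.left_x
    min_sep = sep0 - delta_px.max()
    if min_sep < 4.0 * layout.radius_px:
        raise ValidationError(
            f"markers would come within {min_sep:.1f} px (< 2 diameters); enlarge layout"
        )
    if (
        layout.left_x - layout.radius_px < 1
        or layout.right_x + layout.radius_px > layout.frame_width - 1
        or layout.center_y - layout.radius_px < 1
        or layout.center_y + layout.radius_px > layout.frame_height - 1
    ):
        raise ValidationError("markers must stay inside the frame")

    rng = np.random.default_rng(seed)
    frames = np.empty((n, layout.frame_height, layout.frame_width), dtype=np.float64)
    truth = np.empty((n, 4))
    for i in range(n):
        img = np.full((layout.frame_height, layout.frame_width), layout.background)
        lx = layout.left_x + delta_px[i] / 2.0
        rx = layout.right_x - delta_px[i] / 2.0
        _render_disk(img, lx, layout.center_y, layout.radius_px, layout.marker)
        _render_disk(img, rx, layout.center_y, layout.radius_px, layout.marker)
        if illumination_amp > 0:
            img = img + illumination_amp * np.sin(
                2.0 * np.pi * (i / frame_rate) / illumination_period_s
            )
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0.0, 1.0)
        truth[i] = (lx, layout.center_y, rx, layout.center_y)

    truth_df = pd.DataFrame(truth, columns=["x1", "y1", "x2", "y2"])
    truth_df.insert(0, "frame", np.arange(n))
    truth_df["distance_um"] = (truth_df.x2 - truth_df.x1) * pixel_size
    truth_df["deflection_um"] = np.asarray(deflection_um, dtype=np.float64)
    rec = Recording(
        frames=frames, frame_rate=frame_rate, pixel_size=pixel_size, identifier=identifier
    )
    return rec, truth_df


def write_recording_tiff(recording: Recording, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a Recording as a 16-bit multi-page TIFF (+ optional ground-truth JSON)."""
    path = Path(path)
    data = np.round(np.clip(recording.frames, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def make_dose_table(
    ic50: float,
    hill: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized-force dose table on a descending Hill curve.

    The 0-concentration anchor is always present with response exactly 1
    before noise. Deterministic for a fixed seed.
    """
    conc = np.unique(np.concatenate([[0.0], np.asarray(concentrations, dtype=np.float64)]))
    resp = hill_response(conc, ic50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=len(conc))
    return pd.DataFrame({"concentration_M": conc, "normalized_force": resp})


def make_tissue_silhouette(
    shape: str,
    dimensions_mm: tuple,
    pixel_size: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_px: int = 12,
) -> tuple[np.ndarray, float]:
    """Render a dark tissue silhouette and return (frame, analytic area in mm²).

    Shapes: ``disk`` (radius,), ``ellipse`` (semi_a, semi_b), ``capsule``
    (total_length, width) — a rectangle with semicircular caps, area
    w·(l−w) + π(w/2)². Dimensions in mm; pixel_size in µm/px.
    """
    px_per_mm = 1000.0 / pixel_size
    ss = 4
    sub = (np.arange(ss) + 0.5) / ss - 0.5

    if shape == "disk":
        (r_mm,) = dimensions_mm
        half_w = half_h = r_mm * px_per_mm
        area = np.pi * r_mm**2

        def inside(x, y):
            return x**2 + y**2 <= (r_mm * px_per_mm) ** 2

    elif shape == "ellipse":
        a_mm, b_mm = dimensions_mm
        half_w, half_h = a_mm * px_per_mm, b_mm * px_per_mm
        area = np.pi * a_mm * b_mm

        def inside(x, y):
            return (x / (a_mm * px_per_mm)) ** 2 + (y / (b_mm * px_per_mm)) ** 2 <= 1.0

    elif shape == "capsule":
        l_mm, w_mm = dimensions_mm
        if w_mm > l_mm:
            raise ValidationError("capsule width must not exceed its total length")
        r = (w_mm / 2.0) * px_per_mm
        half_body = (l_mm / 2.0) * px_per_mm - r
        half_w, half_h = (l_mm / 2.0) * px_per_mm, r
        area = w_mm * (l_mm - w_mm) + np.pi * (w_mm / 2.0) ** 2

        def inside(x, y):
            xc = np.clip(x, -half_body, half_body)
            return (x - xc) ** 2 + y**2 <= r**2

    else:
        raise ValidationError(f"unknown silhouette shape {shape!r}")

    h = int(np.ceil(2 * half_h)) + 2 * margin_px
    w = int(np.ceil(2 * half_w)) + 2 * margin_px
    cy, cx = h / 2.0, w / 2.0
    ys = np.arange(h)[:, None, None, None] + sub[None, None, :, None] - cy
    xs = np.arange(w)[None, :, None, None] + sub[None, None, None, :] - cx
    coverage = inside(xs, ys).mean(axis=(2, 3))
    img = 0.9 - 0.8 * coverage
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), float(area)
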