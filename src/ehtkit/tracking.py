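"""Detection and tracking of the two black cantilever-top markers.

The carbon-black discs capping the PDMS posts are the only high-contrast
features in a brightfield field of view, so detection is deliberately simple:
global Otsu threshold on the inverted frame, connected components, then area
and circularity filters. Sub-pixel localization uses the intensity-weighted
centroid of the inverted image within each blob, which exploits the
anti-aliased disc edge.

Tracking pairs the two markers across frames by nearest-neighbour continuity:
the first usable frame seeds the pair with the two largest blobs, every later
frame keeps the two detections closest to the previous pair. Frames where
fewer than two markers survive the filters are linearly interpolated (and
flagged) up to ``max_gap`` consecutive frames; longer gaps abort tracking
with the offending frame range in the error message.

Deflection convention: ``deflection(t) = baseline_distance − distance(t)``
where the baseline is the *relaxed* inter-marker distance — by default the
maximum distance seen in the recording, because a recording may start
mid-twitch. The deflection is the total change of the inter-marker distance
(both posts bend); a ``per_post_deflection`` flag halves it for users who
prefer the symmetric-post convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import TrackingError, ValidationError
from .io import Recording

__all__ = [
    "DetectionParams",
    "Blob",
    "MarkerPair",
    "DeflectionTrace",
    "detect_blobs",
    "detect_markers",
    "track_pair",
]


@dataclass(frozen=True)
class DetectionParams:
    """Blob-filter settings for marker detection.

    ``min_area``/``max_area`` are in px²; ``min_circularity`` is 4πA/P² (1 for a
    perfect circle). Defaults suit discs of roughly 4–30 px radius.
    """

    min_area: float = 20.0
    max_area: float | None = None
    min_circularity: float = 0.5


@dataclass(frozen=True)
class Blob:
    """One detected dark blob: sub-pixel centroid (x right, y down) and area in px²."""

    x: float
    y: float
    area: float


@dataclass(frozen=True)
class MarkerPair:
    """Canonically ordered marker pair in one frame (left.x < right.x)."""

    centroid_left: tuple[float, float]
    centroid_right: tuple[float, float]
    frame_index: int

    def distance_px(self) -> float:
        dx = self.centroid_right[0] - self.centroid_left[0]
        dy = self.centroid_right[1] - self.centroid_left[1]
        return float(np.hypot(dx, dy))


@dataclass
class DeflectionTrace:
    """Per-frame inter-marker distance and derived deflection.

    Attributes
    ----------
    time : seconds per frame.
    distance : µm per frame (Euclidean inter-centroid distance × pixel size).
    baseline_distance : µm, relaxed-state inter-marker distance.
    deflection : µm per frame, ``baseline_distance − distance``.
    positions : ``(n, 2, 2)`` array of (left, right) × (x, y) pixel centroids.
    interpolated : boolean flags for gap-filled frames.
    """

    time: np.ndarray
    distance: np.ndarray
    baseline_distance: float
    deflection: np.ndarray
    positions: np.ndarray
    interpolated: np.ndarray
    pixel_size: float
    identifier: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame tracking table (the CSV exchanged between CLI stages)."""
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.time)),
                "time_s": self.time,
                "x1": self.positions[:, 0, 0],
                "y1": self.positions[:, 0, 1],
                "x2": self.positions[:, 1, 0],
                "y2": self.positions[:, 1, 1],
                "distance_um": self.distance,
                "deflection_um": self.deflection,
                "interpolated_flag": self.interpolated.astype(int),
            }
        )


def detect_blobs(frame: np.ndarray, params: DetectionParams | None = None) -> list[Blob]:
    """Detect dark blobs in a normalized grayscale frame.

    Otsu threshold on the inverted image → connected components → area and
    circularity filters → intensity-weighted sub-pixel centroids, sorted by x.
    An empty list is a valid result (blank frame); pairing handles counts.
    """
    params = params or DetectionParams()
    inv = 1.0 - np.asarray(frame, dtype=np.float64)
    if inv.max() - inv.min() < 1e-6:
        return []
    mask = inv > threshold_otsu(inv)
    if not mask.any() or mask.all():
        return []
    max_area = params.max_area if params.max_area is not None else 0.25 * mask.size
    blobs: list[Blob] = []
    for rp in regionprops(label(mask), intensity_image=inv):
        if not (params.min_area <= rp.area <= max_area):
            continue
        perim = rp.perimeter
        if perim > 0:
            circularity = 4.0 * np.pi * rp.area / perim**2
            if circularity < params.min_circularity:
                continue
        cy, cx = rp.centroid_weighted
        blobs.append(Blob(x=float(cx), y=float(cy), area=float(rp.area)))
    blobs.sort(key=lambda b: b.x)
    return blobs


def detect_markers(
    frame: np.ndarray, params: DetectionParams | None = None
) -> list[tuple[float, float]]:
    """Sub-pixel centroids of candidate markers in one frame, sorted by x."""
    return [(b.x, b.y) for b in detect_blobs(frame, params)]


def _seed_pair(blobs: list[Blob]) -> tuple[Blob, Blob]:
    """Initial pair = two largest blobs; area ties broken by leftmost x."""
    best = sorted(blobs, key=lambda b: (-b.area, b.x))[:2]
    return tuple(sorted(best, key=lambda b: b.x))  # type: ignore[return-value]


def _continue_pair(
    blobs: list[Blob], prev: tuple[tuple[float, float], tuple[float, float]]
) -> tuple[Blob, Blob]:
    """Pick the two blobs nearest the previous pair (summed assignment distance)."""
    if len(blobs) == 2:
        chosen = blobs
    else:
        best_cost = np.inf
        chosen = blobs[:2]
        for pair in itertools.combinations(blobs, 2):
            for cand in (pair, pair[::-1]):
                cost = sum(
                    np.hypot(c.x - p[0], c.y - p[1]) for c, p in zip(cand, prev)
                )
                if cost < best_cost:
                    best_cost = cost
                    chosen = list(cand)
    return tuple(sorted(chosen, key=lambda b: b.x))  # type: ignore[return-value]


def _crop_offsets(frame: np.ndarray, roi) -> list[tuple[np.ndarray, float, float]]:
    if roi is None:
        return [(frame, 0.0, 0.0)]
    rects = roi if isinstance(roi[0], (tuple, list)) else [roi]
    views = []
    for x0, y0, x1, y1 in rects:
        views.append((frame[int(y0) : int(y1), int(x0) : int(x1)], float(x0), float(y0)))
    return views


def track_pair(
    recording: Recording,
    params: DetectionParams | None = None,
    roi=None,
    max_gap: int = 5,
    baseline_distance_um: float | None = None,
    per_post_deflection: bool = False,
) -> DeflectionTrace:
    """Track the marker pair through a recording and derive the deflection trace.

    Parameters
    ----------
    recording:
        Input frame stack (≥ 2 frames).
    roi:
        Optional rectangle ``(x0, y0, x1, y1)`` or list of rectangles limiting
        detection (e.g. one tissue of a multi-tissue field).
    max_gap:
        Longest run of frames with < 2 detections that is bridged by linear
        interpolation (flagged in the output). Default 5 frames = 50 ms at
        100 fps, shorter than any twitch phase at 1 Hz pacing.
    baseline_distance_um:
        Override for the relaxed inter-marker distance; default is the maximum
        distance observed over the recording.
    per_post_deflection:
        Report δ/2 (per-post convention) instead of the total inter-marker
        distance change.

    Raises
    ------
    TrackingError
        If more than ``max_gap`` consecutive frames lack a valid pair, naming
        the frame range.
    """
    if recording.n_frames < 2:
        raise ValidationError("tracking needs a recording with at least 2 frames")
    n = recording.n_frames
    positions = np.full((n, 2, 2), np.nan)
    prev_pair: tuple[tuple[float, float], tuple[float, float]] | None = None
    for i in range(n):
        blobs: list[Blob] = []
        for view, ox, oy in _crop_offsets(recording.frames[i], roi):
            blobs.extend(
                Blob(x=b.x + ox, y=b.y + oy, area=b.area) for b in detect_blobs(view, params)
            )
        blobs.sort(key=lambda b: b.x)
        if len(blobs) < 2:
            continue
        left, right = (
            _seed_pair(blobs) if prev_pair is None else _continue_pair(blobs, prev_pair)
        )
        positions[i, 0] = (left.x, left.y)
        positions[i, 1] = (right.x, right.y)
        prev_pair = ((left.x, left.y), (right.x, right.y))

    valid = ~np.isnan(positions[:, 0, 0])
    if not valid.any():
        raise TrackingError(f"no valid marker pair in any frame (0–{n - 1})")
    # locate gaps and check against max_gap
    interpolated = ~valid
    gap_start = None
    for i in range(n + 1):
        if i < n and not valid[i]:
            gap_start = i if gap_start is None else gap_start
        elif gap_start is not None:
            gap_len = i - gap_start
            if gap_len > max_gap:
                raise TrackingError(
                    f"tracking failed: no valid marker pair in frames {gap_start}–{i - 1} "
                    f"({gap_len} frames > max_gap={max_gap})"
                )
            gap_start = None
    # linear interpolation of centroid coordinates across gaps (edges: nearest valid)
    idx = np.arange(n)
    for m in range(2):
        for c in range(2):
            col = positions[:, m, c]
            positions[:, m, c] = np.interp(idx, idx[valid], col[valid])

    dist_px = np.hypot(
        positions[:, 1, 0] - positions[:, 0, 0], positions[:, 1, 1] - positions[:, 0, 1]
    )
    distance = dist_px * recording.pixel_size
    baseline = (
        float(baseline_distance_um)
        if baseline_distance_um is not None
        else float(distance.max())
    )
    deflection = baseline - distance
    if per_post_deflection:
        deflection = deflection / 2.0
    return DeflectionTrace(
        time=recording.times,
        distance=distance,
        baseline_distance=baseline,
        deflection=deflection,
        positions=positions,
        interpolated=interpolated,
        pixel_size=recording.pixel_size,
        identifier=recording.identifier,
    )
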