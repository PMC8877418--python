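"""Reading image stacks and snapshots.

A :class:`Recording` is the uniform frame-sequence abstraction used by the
tracker: an ordered ``(n_frames, height, width)`` float array in ``[0, 1]``
plus explicit acquisition metadata. Frame rate and pixel size are *always*
supplied by the caller (config or CLI), never parsed from container tags —
TIFF/AVI metadata dialects are too unreliable to trust silently.

Multi-channel input is collapsed to grayscale by an unweighted channel mean:
the markers are near-black carbon dots on a light background, so channel
weighting is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError, ValidationError

__all__ = ["Recording", "Snapshot", "load_recording", "load_snapshot"]


@dataclass(frozen=True)
class Recording:
    """An ordered grayscale frame stack with acquisition metadata.

    Attributes
    ----------
    frames:
        ``(n_frames, height, width)`` float array, intensities in ``[0, 1]``.
    frame_rate:
        Acquisition rate in frames per second.
    pixel_size:
        Spatial calibration in micrometers per pixel.
    identifier:
        Free-text well/tissue/condition label, carried into all output tables.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.pixel_size <= 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise ValidationError(
                f"frames must be a non-empty (n, h, w) stack, got shape {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds (= frame count / frame rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Per-frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class Snapshot:
    """A single calibrated grayscale frame (whole-tissue brightfield image)."""

    frame: np.ndarray
    pixel_size: float
    identifier: str = ""


def _to_grayscale_01(arr: np.ndarray) -> np.ndarray:
    """Collapse trailing channel axis by mean and normalize intensities to [0, 1]."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = (arr.astype(np.float64) - min(info.min, 0)) / float(info.max - min(info.min, 0))
    else:
        arr = arr.astype(np.float64)
        if arr.size and arr.max() > 1.0:  # float stack stored on an integer scale
            arr = arr / arr.max()
    # channel axis: (h, w, 3|4) single image or (n, h, w, 3|4) stack
    if arr.ndim in (3, 4) and arr.shape[-1] in (3, 4) and arr.shape[-2] not in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    return np.clip(arr, 0.0, 1.0)


def _read_stack(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        try:
            return tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - message path
            raise InputError(f"could not read TIFF stack {path}: {exc}") from exc
    # AVI or anything else imageio can handle; requires an ffmpeg-capable plugin.
    try:
        import imageio.v3 as iio

        return iio.imread(path)
    except Exception as exc:
        raise InputError(f"could not read image stack {path}: {exc}") from exc


def load_recording(
    path: str | Path,
    frame_rate: float,
    pixel_size: float,
    identifier: str = "",
) -> Recording:
    """Load a multi-page TIFF (or AVI, plugin permitting) as a :class:`Recording`.

    Parameters
    ----------
    path:
        Image-stack file. Frames are kept in acquisition order.
    frame_rate, pixel_size:
        Acquisition metadata (must be positive); see module docstring for why
        these are explicit inputs.
    identifier:
        Optional tissue/condition label.

    Raises
    ------
    InputError
        If the file is missing, unreadable, or contains zero frames.
    ValidationError
        If a metadata value is non-positive.
    """
    if frame_rate <= 0 or pixel_size <= 0:
        raise ValidationError(
            f"frame_rate and pixel_size must be positive, got {frame_rate}, {pixel_size}"
        )
    path = Path(path)
    if not path.is_file():
        raise InputError(f"recording not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"empty file: {path}")
    raw = _read_stack(path)
    gray = _to_grayscale_01(raw)
    if gray.ndim == 2:
        gray = gray[None, ...]
    if gray.ndim != 3 or gray.shape[0] == 0:
        raise InputError(f"{path}: expected a frame stack, got array of shape {raw.shape}")
    return Recording(frames=gray, frame_rate=frame_rate, pixel_size=pixel_size, identifier=identifier)


def load_snapshot(path: str | Path, pixel_size: float, identifier: str = "") -> Snapshot:
    """Load a single brightfield snapshot with spatial calibration attached."""
    if pixel_size <= 0:
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    path = Path(path)
    if not path.is_file():
        raise InputError(f"snapshot not found: {path}")
    try:
        import imageio.v3 as iio

        raw = iio.imread(path)
    except Exception as exc:
        raise InputError(f"could not read snapshot {path}: {exc}") from exc
    gray = _to_grayscale_01(raw)
    if gray.ndim == 3:  # single-page stack
        gray = gray[0]
    if gray.ndim != 2:
        raise InputError(f"{path}: expected a single 2-D image, got shape {raw.shape}")
    return Snapshot(frame=gray, pixel_size=pixel_size, identifier=identifier)
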