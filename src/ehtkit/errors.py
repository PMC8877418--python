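"""Exception hierarchy.

Every error a pipeline stage can raise derives from :class:`EhtKitError` so the
CLI can map failures to a single machine-readable record.
"""


class EhtKitError(Exception):
    """Base class for all package errors."""


class InputError(EhtKitError):
    """Unreadable, empty or malformed input file."""


class ValidationError(EhtKitError):
    """Parameter or metadata value violates an invariant (e.g. a > L, fps <= 0)."""


class TrackingError(EhtKitError):
    """Marker pair could not be followed; message names the offending frame range."""


class NoBeatsError(EhtKitError):
    """No contraction peaks found above the noise floor."""

    def __init__(self, message: str, noise_estimate: float | None = None):
        super().__init__(message)
        self.noise_estimate = noise_estimate


class FeatureExtractionError(EhtKitError):
    """A beat window yielded no usable kinetic features (excluded from summaries)."""


class PairingError(EhtKitError):
    """Baseline/treated summaries do not come from the same tissue."""


class NormalizationError(EhtKitError):
    """Dose series lacks a positive zero-concentration anchor."""


class SegmentationError(EhtKitError):
    """No tissue component found in a snapshot."""
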