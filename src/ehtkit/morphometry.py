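"""Tissue-level bookkeeping: area segmentation, compaction, success rate, seeding dose.

Compaction convention: tissues are cast on an 11 mm² footprint (day 0).
Early-stage compaction is the day-5 projected area as a fraction of that
seeding area; late-stage compaction is the area on days 11/15/20 normalized
to the *same tissue's* day-5 area.

Area segmentation replaces manual tracing with Otsu thresholding of the dark
tissue on a light background (largest connected component, holes filled); a
manual-mask override (:func:`tissue_area_from_mask`) reproduces hand tracing.

Tissue-formation success ("homogeneously distributed around the cantilevers
without tissue rupture at any timepoint") is a visual judgment and therefore a
user-annotated input, never image-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import SegmentationError, ValidationError

__all__ = [
    "CompactionRecord",
    "OutcomeRecord",
    "SuccessRate",
    "SeedingDose",
    "tissue_area",
    "tissue_area_from_mask",
    "compaction_metrics",
    "success_rate",
    "seeding_dose",
]

#: measurement schedule (days after tissue formation)
LATE_DAYS = (11, 15, 20)
DEFAULT_SEEDING_AREA_MM2 = 11.0


@dataclass(frozen=True)
class CompactionRecord:
    """Areas over the measurement days and the derived compaction fractions.

    ``early_compaction`` = area(day 5) / seeding area; ``late_compaction[d]``
    = area(d) / area(day 5) for d in {11, 15, 20}. Missing days simply yield
    missing metrics.
    """

    tissue_id: str
    areas: dict
    seeding_area: float = DEFAULT_SEEDING_AREA_MM2
    early_compaction: float | None = None
    late_compaction: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OutcomeRecord:
    """Manual success annotation per timepoint for one tissue.

    Success at a later timepoint implies success at all earlier ones (a
    ruptured tissue does not heal); violated orderings raise on construction.
    """

    tissue_id: str
    condition: str
    success: dict  # timepoint (day) -> bool
    failure_mode: str = ""

    def __post_init__(self) -> None:
        days = sorted(self.success)
        failed = False
        for d in days:
            if failed and self.success[d]:
                raise ValidationError(
                    f"{self.tissue_id}: success at day {d} after an earlier failure"
                )
            failed = failed or not self.success[d]


class SuccessRate(NamedTuple):
    raw: float  # exact percentage
    rounded: int  # nearest integer percent (reporting style of the source tables)


class SeedingDose(NamedTuple):
    raw: float  # exact cell count
    rounded: float  # 3 significant figures


def tissue_area(
    snapshot: np.ndarray,
    pixel_size: float,
    min_area_px: float = 50.0,
    dark_tissue: bool = True,
) -> float:
    """Projected tissue area in mm² from a calibrated grayscale snapshot.

    Otsu threshold → largest connected component → hole filling →
    pixel count × (pixel_size/1000)². Set ``dark_tissue=False`` for inverted
    polarity.

    Raises :class:`SegmentationError` when no component exceeds
    ``min_area_px``.
    """
    if pixel_size <= 0:
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    img = np.asarray(snapshot, dtype=np.float64)
    work = 1.0 - img if dark_tissue else img
    if work.max() - work.min() < 1e-6:
        raise SegmentationError("blank snapshot: no intensity contrast to segment")
    mask = work > threshold_otsu(work)
    lab = label(mask)
    if lab.max() == 0:
        raise SegmentationError("no foreground component found")
    counts = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < min_area_px:
        raise SegmentationError(
            f"largest component ({counts[best - 1]} px) below min_area ({min_area_px} px)"
        )
    component = binary_fill_holes(lab == best)
    return float(component.sum()) * (pixel_size / 1000.0) ** 2


def tissue_area_from_mask(mask: np.ndarray, pixel_size: float) -> float:
    """Area in mm² of a user-supplied (hand-traced) binary mask."""
    if pixel_size <= 0:
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    m = np.asarray(mask) > 0
    if not m.any():
        raise SegmentationError("manual mask is empty")
    return float(m.sum()) * (pixel_size / 1000.0) ** 2


def compaction_metrics(
    areas: dict,
    seeding_area: float = DEFAULT_SEEDING_AREA_MM2,
    tissue_id: str = "",
) -> CompactionRecord:
    """Early/late compaction fractions from per-day areas (mm²).

    ``areas`` maps day (int) to area; day 0 defaults to the seeding area when
    absent. Late-stage metrics need the day-5 area; missing days produce
    missing metrics rather than errors.
    """
    if seeding_area <= 0:
        raise ValidationError("seeding_area must be positive")
    areas = {int(d): float(a) for d, a in areas.items()}
    for d, a in areas.items():
        if a <= 0:
            raise ValidationError(f"area at day {d} must be positive, got {a}")
    areas.setdefault(0, seeding_area)
    early = areas[5] / seeding_area if 5 in areas else None
    late = {d: areas[d] / areas[5] for d in LATE_DAYS if d in areas} if 5 in areas else {}
    return CompactionRecord(
        tissue_id=tissue_id,
        areas=areas,
        seeding_area=seeding_area,
        early_compaction=early,
        late_compaction=late,
    )


def success_rate(n_success: int, n_total: int) -> SuccessRate:
    """Percentage of successful tissues out of all tissues produced.

    Returned both exact and rounded to the nearest integer percent
    (e.g. 11 of 15 → 73.33, 73).
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not (0 <= n_success <= n_total):
        raise ValidationError(f"need 0 <= n_success <= n_total, got {n_success}/{n_total}")
    raw = 100.0 * n_success / n_total
    rounded = int(Decimal(str(raw)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return SuccessRate(raw=raw, rounded=rounded)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    exponent = int(np.floor(np.log10(abs(x))))
    q = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def seeding_dose(final_concentration: float, volume_ul: float) -> SeedingDose:
    """Cells per tissue from a final concentration (cells/mL) and volume (µL).

    16.3 × 10⁶ cells/mL × 15 µL = 244,500 ≈ 2.45 × 10⁵ at 3 significant figures.
    """
    if final_concentration < 0 or volume_ul < 0:
        raise ValidationError("concentration and volume must be non-negative")
    raw = final_concentration * volume_ul * 1e-3  # µL → mL
    return SeedingDose(raw=raw, rounded=_round_sig(raw, 3))
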