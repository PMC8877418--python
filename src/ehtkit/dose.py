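"""Inotropy analyses: gain of force and Hill concentration–response fitting.

Positive inotropy (e.g. 3 nM isoproterenol) is reported as the absolute gain
of mean twitch amplitude and velocities of the treated recording over the
0 nM baseline recording of the *same tissue*.

Negative inotropy (e.g. a nifedipine dose series) is summarized by fitting a
descending Hill curve to the per-tissue normalized force

    r(c) = 1 / (1 + (c / IC50)^h)

with the top fixed at 1 (the 0-concentration anchor) and the bottom at 0
(saturating Ca²⁺-channel block abolishes contraction). Fixing the asymptotes
stabilizes fits on the short 5–7 point series typical of these experiments; a
``free_bottom`` switch enables a floating lower asymptote. The optimization
runs over (log10 IC50, h) with a multi-start grid of 16 log-spaced IC50 seeds
spanning the tested concentration range. The 0-concentration point anchors
the normalization but is excluded from the log-concentration fit domain.

Per-tissue normalization always precedes cross-tissue averaging, preserving
the within-tissue pairing of the measurement protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import NormalizationError, PairingError, ValidationError
from .kinetics import RecordingSummary

__all__ = [
    "InotropyResult",
    "DoseResponseFit",
    "hill_response",
    "gain_of_force",
    "fit_ic50",
    "normalize_dose_series",
    "normalize_dose_table",
]


@dataclass(frozen=True)
class InotropyResult:
    """Absolute treated − baseline gains for one tissue (µN and µN/s)."""

    tissue_id: str
    gain_force: float
    gain_contraction_velocity: float
    gain_relaxation_velocity: float
    baseline_summary: RecordingSummary
    treated_summary: RecordingSummary


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a descending Hill fit (IC50 in the concentration's units, M)."""

    concentrations: np.ndarray
    normalized_force: np.ndarray
    ic50: float
    hill_coefficient: float
    bottom: float
    residual_rms: float
    fit_converged: bool
    message: str = ""

    def predict(self, concentrations) -> np.ndarray:
        return hill_response(concentrations, self.ic50, self.hill_coefficient, self.bottom)


def hill_response(c, ic50: float, h: float, bottom: float = 0.0, top: float = 1.0):
    """Descending Hill model ``bottom + (top−bottom) / (1 + (c/ic50)^h)``.

    Defined for c = 0 (returns ``top``); r(IC50) = (top+bottom)/2 for any h.
    """
    c = np.asarray(c, dtype=np.float64)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** h, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def gain_of_force(baseline: RecordingSummary, treated: RecordingSummary) -> InotropyResult:
    """Treated − baseline differences of mean amplitude and velocities.

    Both summaries must carry the same tissue identifier; a mismatch raises
    :class:`PairingError` because gains are only meaningful within a tissue.
    Negative gains (negative inotropy) are representable.
    """
    if baseline.identifier != treated.identifier:
        raise PairingError(
            f"summaries are from different tissues: {baseline.identifier!r} vs {treated.identifier!r}"
        )
    return InotropyResult(
        tissue_id=baseline.identifier,
        gain_force=treated.mean_amplitude - baseline.mean_amplitude,
        gain_contraction_velocity=treated.mean_contraction_velocity
        - baseline.mean_contraction_velocity,
        gain_relaxation_velocity=treated.mean_relaxation_velocity
        - baseline.mean_relaxation_velocity,
        baseline_summary=baseline,
        treated_summary=treated,
    )


def _failure(conc, resp, message: str) -> DoseResponseFit:
    return DoseResponseFit(
        concentrations=np.asarray(conc, dtype=np.float64),
        normalized_force=np.asarray(resp, dtype=np.float64),
        ic50=np.nan,
        hill_coefficient=np.nan,
        bottom=0.0,
        residual_rms=np.nan,
        fit_converged=False,
        message=message,
    )


def fit_ic50(
    concentrations,
    normalized_force,
    weights=None,
    free_bottom: bool = False,
    n_starts: int = 16,
) -> DoseResponseFit:
    """Least-squares descending Hill fit returning the IC50 and Hill coefficient.

    Requires at least 4 distinct non-zero concentrations (the 0-concentration
    anchor may be present; it is excluded from the fit domain). Degenerate
    inputs — too few points, or responses that do not decrease with
    concentration — return a non-converged fit with a diagnostic message
    rather than raising, so batch runs continue.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    resp = np.asarray(normalized_force, dtype=np.float64)
    if conc.shape != resp.shape:
        raise ValidationError("concentrations and responses must have the same length")
    w = np.ones_like(resp) if weights is None else np.asarray(weights, dtype=np.float64)

    pos = conc > 0
    c, r, wp = conc[pos], resp[pos], w[pos]
    n_params = 3 if free_bottom else 2
    if len(np.unique(c)) < 4 or len(c) < n_params:
        return _failure(conc, resp, "too few non-zero concentrations for a Hill fit")
    if np.ptp(r) < 1e-9:
        return _failure(conc, resp, "no dose dependence: responses are constant")
    logc = np.log10(c)
    slope = np.polyfit(logc, r, 1)[0]
    if slope >= 0:
        return _failure(conc, resp, "no dose dependence: responses non-decreasing overall")

    def residuals(p):
        ic50 = 10.0 ** p[0]
        h = p[1]
        bottom = p[2] if free_bottom else 0.0
        return wp * (hill_response(c, ic50, h, bottom) - r)

    grid = np.linspace(np.log10(c.min()), np.log10(c.max()), n_starts)
    lower = [-np.inf, 1e-3] + ([-0.5] if free_bottom else [])
    upper = [np.inf, 50.0] + ([0.9] if free_bottom else [])
    best = None
    for log_ic50_0 in grid:
        x0 = [log_ic50_0, 1.0] + ([0.0] if free_bottom else [])
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        return _failure(conc, resp, "optimizer failed to converge from every start")

    ic50 = float(10.0 ** best.x[0])
    h = float(best.x[1])
    bottom = float(best.x[2]) if free_bottom else 0.0
    rms = float(np.sqrt(np.mean((hill_response(c, ic50, h, bottom) - r) ** 2)))
    order = np.argsort(conc)
    return DoseResponseFit(
        concentrations=conc[order],
        normalized_force=resp[order],
        ic50=ic50,
        hill_coefficient=h,
        bottom=bottom,
        residual_rms=rms,
        fit_converged=bool(best.success),
        message=str(best.message),
    )


def normalize_dose_series(
    summaries_by_concentration: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize one tissue's dose series to its 0-concentration amplitude.

    ``summaries_by_concentration`` maps concentration (M) to either a
    :class:`RecordingSummary` or a precomputed mean amplitude. Returns
    concentrations sorted ascending and the matching normalized forces; the
    entry at 0 is exactly 1 by construction.
    """
    if 0 not in summaries_by_concentration and 0.0 not in summaries_by_concentration:
        raise NormalizationError("dose series lacks the 0-concentration baseline entry")

    def _amp(v):
        return v.mean_amplitude if isinstance(v, RecordingSummary) else float(v)

    base = _amp(summaries_by_concentration[0.0 if 0.0 in summaries_by_concentration else 0])
    if base <= 0:
        raise NormalizationError(f"baseline amplitude must be positive, got {base}")
    conc = np.array(sorted(summaries_by_concentration), dtype=np.float64)
    norm = np.array([_amp(summaries_by_concentration[k]) / base for k in sorted(summaries_by_concentration)])
    return conc, norm


def normalize_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue normalization, then cross-tissue averaging per concentration.

    ``table`` needs columns ``tissue_id``, ``concentration_M`` and
    ``amplitude``. The order matters: normalizing each tissue to its own
    baseline *before* averaging preserves within-tissue pairing (averaging
    raw amplitudes first weights strong tissues more and gives a different
    curve).
    """
    required = {"tissue_id", "concentration_M", "amplitude"}
    if not required.issubset(table.columns):
        raise ValidationError(f"dose table needs columns {sorted(required)}")
    parts = []
    for tissue, grp in table.groupby("tissue_id"):
        series = dict(zip(grp["concentration_M"], grp["amplitude"]))
        conc, norm = normalize_dose_series(series)
        parts.append(pd.DataFrame({"tissue_id": tissue, "concentration_M": conc, "normalized_force": norm}))
    tidy = pd.concat(parts, ignore_index=True)
    out = (
        tidy.groupby("concentration_M", as_index=False)["normalized_force"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "normalized_force", "std": "sd", "count": "n_tissues"})
    )
    return out.sort_values("concentration_M").reset_index(drop=True)
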