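"""Deflection-to-force conversion via elastic beam bending.

The tissue pulls on each PDMS cantilever at height ``a`` above the base; for a
point load at that height the Euler–Bernoulli tip deflection of a circular
cantilever gives

    F = 3 π E R⁴ δ / (2 a² (3L − a))

with ``E`` the Young's modulus, ``R`` the post radius, ``L`` its length and
``δ`` the measured change of the inter-marker distance. This is identical to
the textbook form F = 6 E I δ / (a² (3L − a)) with second moment
I = πR⁴/4 — the test suite checks the two agree to machine precision.

All internal arithmetic is strict SI (meters, pascals, newtons); the reporting
unit is µN. Unit conversion happens in exactly one place (this module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tracking import DeflectionTrace

__all__ = ["PlatformGeometry", "ForceTrace", "beam_force", "beam_stiffness", "force_trace"]

UM_PER_M = 1e6
UN_PER_N = 1e6


@dataclass(frozen=True)
class PlatformGeometry:
    """Beam-equation constants plus optical calibration.

    Parameters
    ----------
    E_pa : Young's modulus of the PDMS cantilever, Pa.
    R_m : cantilever radius, m.
    L_m : cantilever length, m (3 mm for this platform).
    a_m : height of the tissue on the cantilever measured from the base, m.
    pixel_size_um, frame_rate : optional acquisition calibration carried along
        so every output table records the geometry it was computed with.

    The default ``L_m`` is the platform's 3 mm post; ``E_pa``, ``R_m`` and
    ``a_m`` defaults are placeholders typical of Sylgard 184 (1:10) posts of
    this size — **users must calibrate them** for absolute forces.
    """

    E_pa: float = 2.0e6
    R_m: float = 0.25e-3
    L_m: float = 3.0e-3
    a_m: float = 1.5e-3
    pixel_size_um: float | None = None
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        if self.E_pa <= 0 or self.R_m <= 0 or self.L_m <= 0:
            raise ValidationError("E, R and L must all be positive")
        if not (0 < self.a_m <= self.L_m):
            raise ValidationError(
                f"tissue height a must satisfy 0 < a <= L, got a={self.a_m}, L={self.L_m}"
            )


def beam_stiffness(geometry: PlatformGeometry) -> float:
    """Deflection-to-force constant 3πER⁴ / (2a²(3L−a)) in N/m."""
    g = geometry
    return 3.0 * np.pi * g.E_pa * g.R_m**4 / (2.0 * g.a_m**2 * (3.0 * g.L_m - g.a_m))


def beam_force(delta_um: float | np.ndarray, geometry: PlatformGeometry) -> float | np.ndarray:
    """Contraction force in µN for a deflection ``δ`` in µm.

    Linear in δ and E, quartic in R. Negative δ (post pushed outward) yields a
    negative force — reported, not clipped, because it flags a mis-estimated
    baseline to the user.
    """
    delta_m = np.asarray(delta_um, dtype=np.float64) / UM_PER_M
    force_n = beam_stiffness(geometry) * delta_m
    out = force_n * UN_PER_N
    return float(out) if np.isscalar(delta_um) else out


@dataclass
class ForceTrace:
    """Force time series derived from a deflection trace.

    ``force`` is in µN on the same time axis as the source trace.
    """

    time: np.ndarray
    force: np.ndarray
    deflection_um: np.ndarray
    geometry: PlatformGeometry
    identifier: str = ""

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "deflection_um": self.deflection_um, "force_uN": self.force}
        )


def force_trace(trace: DeflectionTrace, geometry: PlatformGeometry) -> ForceTrace:
    """Apply :func:`beam_force` elementwise to a deflection trace."""
    return ForceTrace(
        time=np.asarray(trace.time, dtype=np.float64),
        force=np.asarray(beam_force(trace.deflection, geometry)),
        deflection_um=np.asarray(trace.deflection, dtype=np.float64),
        geometry=geometry,
        identifier=trace.identifier,
    )
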