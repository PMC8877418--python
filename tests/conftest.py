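import numpy as np
import pytest

from ehtkit import PlatformGeometry, TwitchSpec, make_twitch_trace, render_marker_video
from ehtkit.mechanics import ForceTrace


@pytest.fixture
def unit_geometry():
    """Geometry with all constants 1 (SI), so F[N] = 3π/4 × δ[m]."""
    return PlatformGeometry(E_pa=1.0, R_m=1.0, L_m=1.0, a_m=1.0)


@pytest.fixture
def default_geometry():
    return PlatformGeometry()


def force_trace_from_values(values, frame_rate=100.0, identifier=""):
    """Wrap a raw signal as a ForceTrace (unit geometry; values pass through)."""
    values = np.asarray(values, dtype=np.float64)
    return ForceTrace(
        time=np.arange(len(values)) / frame_rate,
        force=values,
        deflection_um=values,
        geometry=PlatformGeometry(),
        identifier=identifier,
    )


@pytest.fixture
def twitch_video():
    """A short (4 s) rendered twitch video with its programmed ground truth."""
    spec = TwitchSpec(amplitude=20.0, pacing_frequency=1.0, duty=0.4, phase=0.3)
    trace = make_twitch_trace(spec, duration=4.0, frame_rate=100.0)
    recording, truth = render_marker_video(trace.values, pixel_size=2.0, seed=11)
    return spec, trace, recording, truth
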