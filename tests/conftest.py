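import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emgrid as eg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def standard():
    """The packaged 128-electrode forearm layout."""
    return eg.standard_layout()


@pytest.fixture(scope="session")
def small_layout():
    """A full 6x6 grid, 10 mm pitch, reference column 2."""
    return eg.build_grid(eg.GridSpec(n_rows=6, n_cols=6, pitch_mm=10.0, reference_col=2))


def single_source_recording(
    layout,
    center=(30.0, 50.0),
    noise_rms=0.1,
    amplitude=1.0,
    seed=0,
    duration_s=3.0,
    fs=2048.0,
    spread_mm=10.0,
):
    truth = eg.GroundTruth(
        sources=(
            eg.SourceSpec(
                center_mm=tuple(center), spread_mm=spread_mm, rms_amplitude=amplitude
            ),
        ),
        noise_rms=noise_rms,
        seed=seed,
    )
    return eg.generate_recording(layout, truth, duration_s, fs)
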