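import numpy as np
import pytest

from egflow.flow import segment_flow
from egflow.geometry import build_grid
from egflow.interpolate import render_frames
from egflow.preprocess import clean, segment
from egflow.synth import ArtifactSpec, WaveScenario, simulate_recording

DURATION = 12.0


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def artifacts():
    return ArtifactSpec(qrs_amplitude=0.3, baseline_wander=0.2, noise_sd=0.02)


@pytest.fixture(scope="session")
def planar_recording(artifacts):
    return simulate_recording(
        WaveScenario(kind="planar", direction=0.9, seed=1),
        artifacts, duration=DURATION,
    )


@pytest.fixture(scope="session")
def planar_maps(planar_recording):
    return segment_flow(render_frames(segment(clean(planar_recording))))


@pytest.fixture(scope="session")
def focal_truth():
    return (2.0, 4.0)


@pytest.fixture(scope="session")
def focal_recording(artifacts, focal_truth):
    return simulate_recording(
        WaveScenario(kind="focal", source_location=focal_truth,
                     active_fraction=0.5, chaos_level=1.0, seed=3),
        artifacts, duration=DURATION,
    )


@pytest.fixture(scope="session")
def focal_maps(focal_recording):
    return segment_flow(render_frames(segment(clean(focal_recording))))


@pytest.fixture(scope="session")
def fib_maps(artifacts):
    rec = simulate_recording(
        WaveScenario(kind="fibrillatory", seed=7), artifacts, duration=DURATION)
    return segment_flow(render_frames(segment(clean(rec))))


def chart_dist(a, b):
    dx = (a[0] - b[0] + 4.0) % 8.0 - 4.0
    return float(np.hypot(dx, a[1] - b[1]))
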