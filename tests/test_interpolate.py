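import numpy as np
import pytest

from egflow.interpolate import (FrameStack, evaluate_biharmonic, fit_biharmonic,
                                greens_biharmonic, periodic_chart_distance,
                                render_frames)
from egflow.preprocess import segment
from egflow.synth import EGMRecording, WaveScenario, simulate_recording


def test_interpolant_reproduces_node_values():
    rng = np.random.default_rng(0)
    for _ in range(20):
        xy = rng.uniform(0, 8, (10, 2))
        vals = rng.normal(size=10)
        w = fit_biharmonic(xy, vals)
        assert np.abs(evaluate_biharmonic(xy, w, xy) - vals).max() < 1e-8


def test_constant_values_reproduced_at_nodes():
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 8, (12, 2))
    w = fit_biharmonic(xy, np.full(12, 3.7))
    assert np.allclose(evaluate_biharmonic(xy, w, xy), 3.7, atol=1e-8)


def test_weights_match_independent_dense_solve():
    rng = np.random.default_rng(2)
    xy = rng.uniform(0, 8, (10, 2))
    vals = rng.normal(size=10)
    w = fit_biharmonic(xy, vals)
    # oracle: explicit Green's matrix and numpy solve
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
    G = np.where(d > 0, d**2 * (np.log(np.where(d > 0, d, 1.0)) - 1), 0.0)
    assert np.allclose(w, np.linalg.solve(G, vals), atol=1e-8)


def test_greens_function_limit_at_zero():
    assert greens_biharmonic(np.array([0.0]))[0] == 0.0
    r = np.array([1e-12])
    assert abs(greens_biharmonic(r)[0]) < 1e-20


def test_duplicate_nodes_fall_back_to_ridge():
    xy = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 3.0], [4.0, 2.0]])
    w = fit_biharmonic(xy, np.array([1.0, 1.0, 2.0, 3.0]))
    assert np.all(np.isfinite(w))


def test_too_few_nodes_rejected():
    with pytest.raises(ValueError):
        fit_biharmonic(np.array([[0.0, 0.0], [1.0, 1.0]]), np.array([1.0, 2.0]))


def test_quiescent_recording_renders_zero_frames():
    rec = simulate_recording(WaveScenario(kind="quiescent", seed=0), None,
                             duration=2.0)
    stack = render_frames(segment(rec))
    assert np.allclose(stack.frames, 0.0)


def test_single_active_electrode_peaks_at_its_pixel():
    x = np.zeros((64, 2000))
    x[18] = 1.0  # C3
    stack = render_frames(segment(EGMRecording(samples=x, fs=1000.0)),
                          frame_rate=1.0)
    r, c = np.unravel_index(np.argmax(stack.frames[0]), stack.frames[0].shape)
    er, ec = stack.electrode_pixel_map["C3"]
    assert abs(r - er) <= 1 and abs(c - ec) <= 1


def test_field_is_periodic_across_spline_seam():
    rng = np.random.default_rng(3)
    from egflow.synth import electrode_chart_coords
    from scipy import linalg as sla

    xy = electrode_chart_coords()
    v = rng.normal(size=64)
    G = greens_biharmonic(periodic_chart_distance(xy, xy))
    w = sla.solve(G, v)
    q = np.column_stack([np.full(15, 0.01), np.linspace(1, 8, 15)])
    qw = q + [8.0, 0.0]
    f1 = greens_biharmonic(periodic_chart_distance(q, xy)) @ w
    f2 = greens_biharmonic(periodic_chart_distance(qw, xy)) @ w
    assert np.abs(f1 - f2).max() < 1e-6


def test_masked_electrode_loses_influence():
    x = np.zeros((64, 2000))
    x[18] = 1.0  # C3 active
    x[45] = 0.5  # F6 active
    seg = segment(EGMRecording(samples=x, fs=1000.0))
    mask = np.ones(64, bool)
    full = render_frames(seg, frame_rate=1.0)
    mask[18] = False
    masked = render_frames(seg, contact_mask=mask, frame_rate=1.0)
    r, c = (int(round(v)) for v in full.electrode_pixel_map["C3"])
    assert abs(full.frames[0, r, c] - masked.frames[0, r, c]) > 0.1


def test_all_masked_rejected():
    x = np.zeros((64, 2000))
    with pytest.raises(ValueError):
        render_frames(segment(EGMRecording(samples=x, fs=1000.0)),
                      contact_mask=np.zeros(64, bool))


def test_framestack_round_trips_through_npz(tmp_path):
    rec = simulate_recording(WaveScenario(kind="planar", seed=1), None,
                             duration=2.0)
    stack = render_frames(segment(rec))
    p = str(tmp_path / "stack.npz")
    stack.save(p)
    back = FrameStack.load(p)
    assert np.array_equal(back.frames, stack.frames)
    assert back.frame_rate == stack.frame_rate
    assert back.electrode_pixel_map == stack.electrode_pixel_map
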