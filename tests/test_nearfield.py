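import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egflow.nearfield import (NearFieldConfig, conduction_component,
                              instantaneous_component, nearfield_score,
                              xcorr_norm, _xcorr_all_lags)
from egflow.preprocess import CleanConfig, clean, segment
from egflow.synth import ArtifactSpec, WaveScenario, simulate_recording

FS = 1000.0


def _noise(n, seed):
    return np.random.default_rng(seed).normal(size=n)


def test_autocorrelation_peak_is_unity():
    x = _noise(2000, 0)
    assert xcorr_norm(x, x, 0) == pytest.approx(1.0)


def test_orthogonal_signals_correlate_near_zero():
    t = np.arange(2000) / FS
    x = np.sin(2 * np.pi * 10 * t)
    y = np.cos(2 * np.pi * 10 * t)
    assert abs(xcorr_norm(x, y, 0)) < 0.05


def test_delayed_copy_peaks_at_true_lag_brute_force():
    x = _noise(2000, 1)
    k = 23
    y = np.roll(x, -k)
    # brute-force oracle over every admissible lag
    brute = [xcorr_norm(x, y, dt) for dt in range(0, 1001)]
    assert int(np.argmax(brute)) == k
    fast = _xcorr_all_lags(x, y)
    assert np.allclose(fast, brute, atol=1e-10)


def test_zero_energy_window_returns_zero():
    assert xcorr_norm(np.zeros(100), _noise(100, 2), 0) == 0.0


def test_out_of_range_lag_rejected():
    with pytest.raises(ValueError):
        xcorr_norm(_noise(100, 0), _noise(100, 1), 51)


def test_conducted_neighbor_recovers_shift_and_unity_component():
    x = _noise(2000, 3)
    nb = np.roll(x, 20)  # neighbor leads by 20 ms at 1 kHz
    rc, dt = conduction_component(x, [nb], FS)
    assert rc > 0.9
    assert dt == pytest.approx(20.0, abs=1.0)


def test_zero_lag_copy_is_not_conduction():
    x = _noise(2000, 4)
    rc, dt = conduction_component(x, [x.copy()], FS)
    assert rc == 0.0


def test_too_slow_shift_is_not_conduction():
    x = _noise(2000, 5)
    rc, _ = conduction_component(x, [np.roll(x, 60)], FS)
    assert rc == 0.0


def test_instantaneous_component_rules():
    x = _noise(2000, 6)
    # conduction present -> instantaneous forced to zero
    assert instantaneous_component(x, [np.roll(x, 20)], re_cond=0.8) == 0.0
    # exact zero-lag copies -> unity
    assert instantaneous_component(x, [x.copy(), x.copy()], re_cond=0.0) == \
        pytest.approx(1.0)
    # independent noise -> small
    others = [_noise(2000, 7 + i) for i in range(4)]
    assert abs(instantaneous_component(x, others, re_cond=0.0)) < 0.3


def test_components_never_simultaneously_nonzero(planar_recording):
    rc = clean(planar_recording, CleanConfig(qrs_subtraction=False))
    nf = nearfield_score(segment(rc))
    assert not np.any((nf.re_cond != 0) & (nf.re_inst != 0))
    assert np.all((nf.mask == 0) | (nf.mask == 1))
    assert np.all((nf.score >= 0) & (nf.score <= 1))


def test_score_invariant_to_uniform_amplitude_scaling(planar_recording):
    rc = clean(planar_recording, CleanConfig(qrs_subtraction=False))
    seg = segment(rc)
    nf1 = nearfield_score(seg)
    seg.samples = seg.samples * 7.3
    nf2 = nearfield_score(seg)
    assert np.array_equal(nf1.score, nf2.score)


def test_contact_boundary_is_inclusive():
    # score exactly 0.7 -> contact good (poor is strictly < 0.7)
    from egflow.nearfield import NearFieldComponents
    score = np.full(64, 0.7)
    assert np.all(score >= NearFieldConfig().poor_contact_score)


def test_planted_noncontact_channels_called_poor(artifacts):
    bad = frozenset({5, 23, 40, 64})
    art = ArtifactSpec(qrs_amplitude=0.3, baseline_wander=0.2, noise_sd=0.02,
                       noncontact_channels=bad)
    rec = simulate_recording(WaveScenario(kind="planar", direction=0.9, seed=2),
                             art, duration=12.0)
    nf = nearfield_score(segment(clean(rec, CleanConfig(qrs_subtraction=False))))
    truth = np.array(rec.truth["contact"])
    assert np.all(~nf.contact[~truth])  # all planted channels called poor
    assert np.mean(nf.contact[truth]) >= 0.95


def test_caption_mode_requires_positive_conduction_window():
    """Under the alternative mask rule a channel with conducted activity is
    near-field but a channel of pure independent noise is not."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=(64, 4000)) * 0.01
    # give channels 1..63 conducted structure; keep channel 64 pure noise
    base = rng.normal(size=4000)
    for c in range(63):
        x[c] += np.roll(base, 10 * (c % 4))
    from egflow.synth import EGMRecording
    seg = segment(EGMRecording(samples=x, fs=FS))
    nf = nearfield_score(seg, config=NearFieldConfig(caption_mode=True))
    assert nf.score[0] == 1.0
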