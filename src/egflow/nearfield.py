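"""Near-field contact scoring from electrogram cross-correlation.

A contacting electrode sees wavefronts that reach its neighbors a few tens of
milliseconds earlier or later; a non-contacting electrode sees mostly the
ventricular far-field, which arrives on all channels simultaneously.  Signal
energy in each 2-s segment is decomposed accordingly:

* conduction component RE_cond — the peak normalized cross-correlation with a
  neighbor, attributed to conduction only when the best lag dt* falls in
  5..50 ms (faster is far-field, slower is not conduction);
* instantaneous component RE_inst — evaluated only when no conduction was
  found, as the mean zero-lag normalized correlation with all neighbors;
* fractionation remainder RE_frac = 1 - RE_cond - RE_inst.

The per-segment near-field mask is 1 iff RE_inst < 0.3; the per-electrode
score is the mask averaged over segments, and contact is called poor when
the score is < 0.7.  Neighbor sets follow the basket grid topology, with the
artificial polar channels P1/P8 (ring-1 / ring-8 averages) standing in at the
poles.

The cross-correlation uses N = len/2 samples so the lagged window never runs
off the segment; both orderings of each electrode pair are evaluated and the
overall peak taken, since the wavefront may reach either electrode first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import N_CHANNELS, BasketGrid, build_grid, label_of, channel_from_label

RE_INST_THRESHOLD = 0.3
POOR_CONTACT_SCORE = 0.7
LAG_MIN_MS = 5.0
LAG_MAX_MS = 50.0


@dataclass
class NearFieldConfig:
    re_inst_threshold: float = RE_INST_THRESHOLD
    poor_contact_score: float = POOR_CONTACT_SCORE
    lag_min_ms: float = LAG_MIN_MS
    lag_max_ms: float = LAG_MAX_MS
    #: alternative mask rule: near-field iff some neighbor has positive
    #: correlation peaking at a lag within the conduction window
    caption_mode: bool = False


@dataclass
class NearFieldComponents:
    """Per-channel, per-segment energy-ratio decomposition and contact calls."""

    re_cond: np.ndarray  # (64, S)
    re_inst: np.ndarray  # (64, S)
    dt_star: np.ndarray  # (64, S) best conduction lag, ms (NaN if none)
    mask: np.ndarray  # (64, S) binary near-field mask
    score: np.ndarray  # (64,) mean of mask over segments
    contact: np.ndarray  # (64,) score >= 0.7

    @property
    def re_frac(self) -> np.ndarray:
        return 1.0 - self.re_cond - self.re_inst

    def to_records(self) -> list[dict]:
        out = []
        for c in range(N_CHANNELS):
            out.append(
                {"channel": label_of(c + 1), "score": float(self.score[c]),
                 "contact": bool(self.contact[c])}
            )
        return out


def xcorr_norm(X: np.ndarray, Y: np.ndarray, dt: int) -> float:
    """Normalized cross-correlation of X delayed by dt samples against Y.

    sum_{t} X[t+dt] Y[t] over an N = len/2 window, normalized by the energies
    of the two windows actually used.  Zero-energy windows return 0.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("signals must have equal length")
    N = len(X) // 2
    if not 0 <= dt <= N:
        raise ValueError(f"lag {dt} out of range 0..{N}")
    xw = X[dt : dt + N]
    yw = Y[:N]
    den = np.sqrt(np.sum(xw**2) * np.sum(yw**2))
    if den == 0:
        return 0.0
    return float(np.dot(xw, yw) / den)


def _xcorr_all_lags(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """xcorr_norm for every lag 0..N at once (FFT cross-correlation with a
    sliding-window energy normalization)."""
    N = len(X) // 2
    yw = Y[:N]
    num = sps.correlate(X, yw, mode="valid", method="auto")  # lag 0..len(X)-N
    num = num[: N + 1]
    csum = np.concatenate([[0.0], np.cumsum(X**2)])
    ex = csum[N : 2 * N + 1] - csum[:N + 1]  # energy of X[dt:dt+N]
    den = np.sqrt(ex * np.sum(yw**2))
    out = np.zeros(N + 1)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _pair_conduction(X, Y, fs, cfg) -> tuple[float, float, float]:
    """Best conduction peak over both orderings of the pair.

    Returns (re_cond_pair, dt_star_ms, zero_lag_corr).  The global peak over
    lags 1..N is gated by the 5..50 ms conduction window; a peak outside the
    window yields 0.
    """
    cxy = _xcorr_all_lags(X, Y)
    cyx = _xcorr_all_lags(Y, X)
    zero_lag = cxy[0]
    best = 0.0
    best_dt = np.nan
    for c in (cxy, cyx):
        if len(c) < 2:
            continue
        k = 1 + int(np.argmax(c[1:]))
        if c[k] > best:
            best = float(c[k])
            best_dt = k / fs * 1000.0
    if not np.isfinite(best_dt) or not (cfg.lag_min_ms <= best_dt <= cfg.lag_max_ms):
        return 0.0, np.nan, float(zero_lag)
    return best, float(best_dt), float(zero_lag)


def _neighbor_signals(seg: np.ndarray, grid: BasketGrid, channel: int) -> list[np.ndarray]:
    """Neighbor traces of a channel within one segment block, polar virtual
    channels included as ring averages."""
    out = []
    for nb in grid.neighbors[label_of(channel)]:
        if nb == "P1":
            out.append(seg[0::8].mean(axis=0))  # ring-1 electrodes A1..H1
        elif nb == "P8":
            out.append(seg[7::8].mean(axis=0))
        else:
            out.append(seg[channel_from_label(nb) - 1])
    return out


def conduction_component(X: np.ndarray, neighbors: list[np.ndarray], fs: float,
                         config: NearFieldConfig | None = None) -> tuple[float, float]:
    """Channel-level conduction ratio: mean of the non-zero pairwise
    conduction components; returns (RE_cond, dt_star of the strongest pair)."""
    cfg = config or NearFieldConfig()
    if not neighbors:
        raise ValueError("channel has no neighbors")
    comps, lags = [], []
    for Y in neighbors:
        c, dt, _ = _pair_conduction(X, Y, fs, cfg)
        if c != 0.0:
            comps.append(c)
            lags.append(dt)
    if not comps:
        return 0.0, np.nan
    return float(np.mean(comps)), float(lags[int(np.argmax(comps))])


def instantaneous_component(X: np.ndarray, neighbors: list[np.ndarray],
                            re_cond: float) -> float:
    """Zero-lag correlation with all neighbors; defined to be 0 whenever the
    channel has a conduction component."""
    if re_cond != 0.0:
        return 0.0
    vals = [xcorr_norm(X, Y, 0) for Y in neighbors]
    return float(np.mean(vals))


def nearfield_score(segmented, grid: BasketGrid | None = None,
                    config: NearFieldConfig | None = None) -> NearFieldComponents:
    """Full decomposition, per-segment mask, and per-electrode contact score."""
    cfg = config or NearFieldConfig()
    grid = grid or build_grid()
    fs = segmented.fs
    S = segmented.n_segments
    re_cond = np.zeros((N_CHANNELS, S))
    re_inst = np.zeros((N_CHANNELS, S))
    dt_star = np.full((N_CHANNELS, S), np.nan)
    mask = np.zeros((N_CHANNELS, S))

    for s in range(S):
        seg = segmented.segment_samples(s)
        for c in range(N_CHANNELS):
            X = seg[c]
            nbs = _neighbor_signals(seg, grid, c + 1)
            pair_results = [_pair_conduction(X, Y, fs, cfg) for Y in nbs]
            comps = [pc for pc, _, _ in pair_results if pc != 0.0]
            lags = [dt for pc, dt, _ in pair_results if pc != 0.0]
            rc = float(np.mean(comps)) if comps else 0.0
            re_cond[c, s] = rc
            if comps:
                dt_star[c, s] = lags[int(np.argmax(comps))]
            if rc == 0.0:
                re_inst[c, s] = np.mean([zl for _, _, zl in pair_results])
            if cfg.caption_mode:
                mask[c, s] = 1.0 if any(pc > 0.0 for pc, _, _ in pair_results) else 0.0
            else:
                mask[c, s] = 1.0 if re_inst[c, s] < cfg.re_inst_threshold else 0.0

    score = mask.mean(axis=1)
    contact = score >= cfg.poor_contact_score
    return NearFieldComponents(
        re_cond=re_cond, re_inst=re_inst, dt_star=dt_star,
        mask=mask, score=score, contact=contact,
    )
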