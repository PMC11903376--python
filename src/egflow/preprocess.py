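"""Unipolar electrogram cleaning and 2-s segmentation.

Cleaning removes the three artifact families of an intracardiac unipolar
recording: baseline wander (zero-phase high-pass), broadband noise
(zero-phase low-pass, optional mains notch), and the ventricular far-field
"QRS" deflection.  The far-field is, by construction, near-identical and
simultaneous on all channels, so it is cancelled by common-mode template
subtraction: detect beats on the cross-channel median trace, build an
average beat, and subtract it at each occurrence.

Segmentation slices a recording into contiguous half-open 2-s windows; a
60-s recording yields 30 segments, trailing partial segments are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

SEGMENT_S = 2.0


@dataclass
class CleanConfig:
    # 1 Hz suppresses sub-0.5 Hz wander essentially completely (a second
    # pass is then a no-op); atrial deflections carry no energy that low
    highpass_hz: float = 1.0
    # atrial deflections are ~10 ms wide (spectral peak near 60 Hz with
    # energy well above 100 Hz); 400 Hz keeps them intact
    lowpass_hz: float = 400.0
    notch_hz: float | None = None  # 50 or 60 to enable
    qrs_subtraction: bool = True


@dataclass
class SegmentedRecording:
    """Cleaned samples plus the half-open segment windows that partition them."""

    samples: np.ndarray  # (64, T)
    fs: float
    segments: list[tuple[int, int]]  # [start, stop) sample windows
    meta: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_samples(self, k: int) -> np.ndarray:
        a, b = self.segments[k]
        return self.samples[:, a:b]


def _common_mode_qrs_subtract(x: np.ndarray, fs: float, log: list[str]) -> np.ndarray:
    """Detect simultaneous cross-channel deflections and subtract an average
    beat per channel at each occurrence."""
    cm = np.median(x, axis=0)
    # smooth the common mode so narrow atrial deflections don't trigger
    win = max(int(0.02 * fs), 3)
    cm_s = sps.convolve(cm, np.ones(win) / win, mode="same")
    # MAD underestimates on a sparse beat train (mostly-zero trace), so the
    # threshold is floored at a fraction of the peak amplitude
    mad = np.median(np.abs(cm_s - np.median(cm_s))) / 0.6745
    peak = np.abs(cm_s).max()
    if peak <= 1e-12:
        log.append("qrs: flat common mode, nothing to subtract")
        return x
    thresh = max(4.0 * mad, 0.3 * peak)
    min_dist = int(0.25 * fs)  # < 240 bpm
    peaks, _ = sps.find_peaks(np.abs(cm_s), height=thresh, distance=min_dist)
    if len(peaks) == 0:
        log.append("qrs: no common-mode beats detected")
        return x
    half = int(0.10 * fs)
    peaks = peaks[(peaks >= half) & (peaks < x.shape[1] - half)]
    if len(peaks) == 0:
        return x
    # per-channel average beat over all occurrences
    idx = peaks[:, None] + np.arange(-half, half)[None, :]
    beats = x[:, idx]  # (64, n_beats, 2*half)
    template = beats.mean(axis=1)
    taper = sps.windows.tukey(2 * half, alpha=0.4)
    template = template * taper[None, :]
    out = x.copy()
    for p in peaks:
        out[:, p - half : p + half] -= template
    log.append(f"qrs: subtracted average beat at {len(peaks)} occurrences")
    return out


def clean(recording, config: CleanConfig | None = None):
    """Return a cleaned copy of a recording (same type, new samples).

    Zero-phase Butterworth band-pass plus optional mains notch, then optional
    common-mode QRS subtraction.  The processing log is appended to the
    recording metadata.
    """
    from .synth import EGMRecording

    config = config or CleanConfig()
    fs = recording.fs
    if fs is None or fs <= 0:
        raise ValueError("recording sampling rate must be known and positive")
    if recording.samples.shape[1] < SEGMENT_S * fs:
        raise ValueError("recording shorter than one 2-s segment")
    x = np.asarray(recording.samples, dtype=float)
    log: list[str] = []

    nyq = fs / 2
    # low-cutoff zero-phase filtering needs ~1 s of reflected padding or the
    # edge transients dominate short recordings
    padlen = min(int(fs), x.shape[1] - 1)
    if config.highpass_hz and config.highpass_hz > 0:
        sos = sps.butter(4, config.highpass_hz / nyq, btype="highpass", output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1, padlen=padlen)
        log.append(f"highpass {config.highpass_hz} Hz")
    if config.lowpass_hz and config.lowpass_hz < nyq:
        sos = sps.butter(4, config.lowpass_hz / nyq, btype="lowpass", output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1, padlen=padlen)
        log.append(f"lowpass {config.lowpass_hz} Hz")
    if config.notch_hz:
        b, a = sps.iirnotch(config.notch_hz, Q=30, fs=fs)
        x = sps.filtfilt(b, a, x, axis=1)
        log.append(f"notch {config.notch_hz} Hz")
    if config.qrs_subtraction:
        x = _common_mode_qrs_subtract(x, fs, log)

    out = EGMRecording(
        samples=x, fs=fs, rhythm=recording.rhythm, atrium=recording.atrium,
        position_id=recording.position_id, truth=recording.truth,
    )
    out.processing_log = log  # type: ignore[attr-defined]
    return out


def segment(recording) -> SegmentedRecording:
    """Slice into floor(duration / 2 s) contiguous half-open windows."""
    fs = recording.fs
    seg_len = int(round(SEGMENT_S * fs))
    T = recording.samples.shape[1]
    n = T // seg_len
    if n < 1:
        raise ValueError("recording shorter than one 2-s segment")
    windows = [(k * seg_len, (k + 1) * seg_len) for k in range(n)]
    return SegmentedRecording(
        samples=np.asarray(recording.samples, dtype=float),
        fs=fs,
        segments=windows,
        meta={
            "rhythm": recording.rhythm, "atrium": recording.atrium,
            "position_id": recording.position_id, "truth": recording.truth,
        },
    )
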