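"""Synthetic basket-catheter electrogram generator.

Real registry recordings are not publicly deposited, so this module emulates
64-channel unipolar basket electrograms with known ground truth: planar,
focal-source, fibrillatory, and quiescent wavefront regimes, plus the
artifacts an intracardiac recording carries (ventricular far-field "QRS"
deflections common to all channels, baseline wander, broadband noise) and
non-contact electrodes that pick up only far-field and noise.

The signal model is geometric, not biophysical: each wavefront is a set of
arrival times on the unrolled 8 x 8 electrode chart (spline axis periodic,
ring axis bounded), and every contacting electrode receives a biphasic
derivative-of-Gaussian deflection (~10 ms wide, ~1 mV) at each arrival.
The far-field QRS is a broad low-frequency deflection with zero inter-channel
lag — exactly the instantaneous component the near-field contact score is
designed to detect.

Defaults reflect the mapped conditions: 1-min recordings, 1 kHz sampling,
AF cycle length 180 ms, sinus cycle length 800 ms, conduction fast enough
that neighboring electrodes see delays inside the 5-50 ms conduction window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import N_CHANNELS, N_RINGS, N_SPLINES, build_grid, label_of

#: distance between adjacent electrodes, chart units
GRID_SPACING = 1.0
#: default conduction velocity, grid-units/s (20 ms neighbor delay)
DEFAULT_VELOCITY = 50.0
AF_CYCLE_MS = 180.0
SR_CYCLE_MS = 800.0
DEFAULT_FS = 1000.0
SEGMENT_S = 2.0


@dataclass
class WaveScenario:
    """Ground-truth wavefront dynamics for one recording."""

    kind: str = "planar"  # planar | focal | fibrillatory | quiescent
    cycle_length: float = AF_CYCLE_MS  # ms
    conduction_velocity: float = DEFAULT_VELOCITY  # grid-units/s
    direction: float = 0.0  # radians, planar propagation direction
    source_location: tuple[float, float] = (3.5, 4.5)  # (spline, ring) chart coords
    active_fraction: float = 1.0  # fraction of 2-s segments the focal source fires
    #: fibrillatory: mixing weight, 0 = planar .. 1 = fully random wavelets;
    #: focal: intensity of the fibrillatory background that continues
    #: throughout the recording while the source fires intermittently
    chaos_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"planar", "focal", "fibrillatory", "quiescent"}:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")


@dataclass
class ArtifactSpec:
    """Amplitudes and rates of the injected recording artifacts."""

    qrs_rate: float = 60.0  # bpm
    qrs_amplitude: float = 0.0  # mV, common-mode ventricular far-field
    baseline_wander: float = 0.0  # mV amplitude
    baseline_frequency: float = 0.25  # Hz
    noise_sd: float = 0.0  # mV
    noncontact_channels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if min(self.qrs_amplitude, self.baseline_wander, self.noise_sd) < 0:
            raise ValueError("artifact amplitudes must be >= 0")
        self.noncontact_channels = frozenset(self.noncontact_channels)


@dataclass
class EGMRecording:
    """A 64 x T block of unipolar electrogram samples with metadata.

    ``truth`` carries the generating scenario, the contact flags, the active
    segment indices and per-channel deflection times — everything a test
    needs to score the pipeline against ground truth.
    """

    samples: np.ndarray  # (64, T) mV
    fs: float
    rhythm: str = "AF"  # AF | SR
    atrium: str = "LA"  # LA | RA
    position_id: str = "LA-1"
    truth: dict | None = None

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def _deflection_kernel(fs: float, width_ms: float = 10.0, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic derivative-of-Gaussian local activation waveform."""
    sigma = width_ms / 4.0 / 1000.0  # total width ~ 4 sigma
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs)
    w = -t / sigma * np.exp(-0.5 * (t / sigma) ** 2)
    peak = np.abs(w).max()
    return amplitude * w / peak if peak > 0 else w


def _qrs_kernel(fs: float, amplitude: float, width_ms: float = 90.0) -> np.ndarray:
    """Broad biphasic far-field deflection (zero inter-channel lag).

    The RS-like biphasic shape gives the far-field a sharp central
    zero-crossing, so cross-channel correlation peaks exactly at lag 0 —
    the signature the near-field score keys on.
    """
    sigma = width_ms / 5.0 / 1000.0
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs)
    w = -t / sigma * np.exp(-0.5 * (t / sigma) ** 2)
    peak = np.abs(w).max()
    return amplitude * w / peak if peak > 0 else w


def _periodic_dx(x: np.ndarray | float, x0: float) -> np.ndarray:
    """Signed spline-axis offset on the periodic chart."""
    d = np.asarray(x, dtype=float) - x0
    return (d + N_SPLINES / 2) % N_SPLINES - N_SPLINES / 2


def _chart_distance(xy: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    dx = _periodic_dx(xy[:, 0], origin[0])
    dy = xy[:, 1] - origin[1]
    return np.hypot(dx, dy)


def electrode_chart_coords() -> np.ndarray:
    """(64, 2) array of chart coordinates in channel order A1..H8."""
    grid = build_grid()
    return np.array([grid.coords[label_of(c)] for c in range(1, N_CHANNELS + 1)])


def active_segment_set(scenario: WaveScenario, n_segments: int) -> np.ndarray:
    """Segments during which a focal source fires: exactly
    round(active_fraction * n_segments) of them, drawn reproducibly."""
    rng = np.random.default_rng(scenario.seed + 104729)
    k = int(round(scenario.active_fraction * n_segments))
    return np.sort(rng.choice(n_segments, size=k, replace=False))


def _planar_events(xy, scenario, duration, rng):
    cl = scenario.cycle_length / 1000.0
    d = np.array([np.cos(scenario.direction), np.sin(scenario.direction)])
    proj = xy @ d
    proj = proj - proj.min()
    delays = proj / scenario.conduction_velocity
    starts = np.arange(0.05, duration, cl)
    return [np.asarray(starts) + delays[c] for c in range(len(xy))]


def _focal_events(xy, scenario, duration, rng):
    cl = scenario.cycle_length / 1000.0
    dist = _chart_distance(xy, tuple(scenario.source_location))
    delays = dist / scenario.conduction_velocity
    n_seg = int(duration // SEGMENT_S)
    active = active_segment_set(scenario, n_seg)
    starts = []
    for s in active:
        t0, t1 = s * SEGMENT_S, (s + 1) * SEGMENT_S
        starts.extend(np.arange(t0 + 0.02, t1 - delays.max(), cl))
    starts = np.asarray(starts)
    events = [starts + delays[c] for c in range(len(xy))]
    if scenario.chaos_level > 0:
        # fibrillatory conduction continues between source firings; during
        # active segments the driver entrains the local tissue
        bg = _wavelet_events(xy, scenario, duration, rng,
                             rate_scale=scenario.chaos_level,
                             exclude_segments=set(int(s) for s in active))
        events = [np.sort(np.concatenate([e, b])) for e, b in zip(events, bg)]
    return events, active


def _wavelet_events(xy, scenario, duration, rng, rate_scale=1.0,
                    exclude_segments=()):
    """Poisson-seeded circular wavelets with random origins and velocities.

    Origins are drawn from a domain larger than the mapped chart (ring axis
    -2..11): the basket samples a patch of a whole atrium, so most wavelets
    arrive from outside it rather than originating under an electrode.
    ``exclude_segments`` suppresses wavelets seeded during those 2-s
    segments (used while a focal driver entrains the tissue).
    """
    cl = scenario.cycle_length / 1000.0
    rate = rate_scale / cl  # wavelets per second
    n_wavelets = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0, duration, n_wavelets))
    if len(exclude_segments):
        keep = ~np.isin((times // SEGMENT_S).astype(int), list(exclude_segments))
        times = times[keep]
    events: list[list[float]] = [[] for _ in range(len(xy))]
    for t0 in times:
        origin = (rng.uniform(0, N_SPLINES), rng.uniform(1 - 3.0, N_RINGS + 3.0))
        v = scenario.conduction_velocity * rng.uniform(0.6, 1.4)
        radius = rng.uniform(2.0, 5.0)
        dist = _chart_distance(xy, origin)
        for c in np.nonzero(dist <= radius)[0]:
            events[c].append(t0 + dist[c] / v)
    return [np.asarray(e) for e in events]


def _fibrillatory_events(xy, scenario, duration, rng):
    c = float(np.clip(scenario.chaos_level, 0.0, 1.0))
    events = _wavelet_events(xy, scenario, duration, rng, rate_scale=c)
    if c < 1.0:
        planar = _planar_events(xy, scenario, duration, rng)
        keep = rng.random(len(planar[0])) < (1.0 - c)
        events = [np.sort(np.concatenate([e, p[keep]])) for e, p in zip(events, planar)]
    return events


def simulate_recording(
    scenario: WaveScenario,
    artifacts: ArtifactSpec | None = None,
    fs: float = DEFAULT_FS,
    duration: float = 60.0,
    rhythm: str = "AF",
    atrium: str = "LA",
    position_id: str = "LA-1",
) -> EGMRecording:
    """Render a synthetic 64-channel unipolar recording with ground truth.

    Every contacting channel carries a biphasic deflection at each wavefront
    arrival; arrival times follow the closed-form geometry of the scenario.
    Non-contact channels carry only far-field and noise.  Artifacts are
    strictly additive on top of the clean local component.
    """
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz for activation-timing resolution")
    artifacts = artifacts or ArtifactSpec()
    xy = electrode_chart_coords()
    rng = np.random.default_rng(scenario.seed)
    T = int(round(fs * duration))

    active_segments = None
    if scenario.kind == "quiescent":
        events = [np.empty(0) for _ in range(N_CHANNELS)]
    elif scenario.kind == "planar":
        events = _planar_events(xy, scenario, duration, rng)
    elif scenario.kind == "focal":
        events, active_segments = _focal_events(xy, scenario, duration, rng)
    else:
        events = _fibrillatory_events(xy, scenario, duration, rng)

    kernel = _deflection_kernel(fs)
    half = len(kernel) // 2
    local = np.zeros((N_CHANNELS, T))
    contact = np.ones(N_CHANNELS, dtype=bool)
    for c in sorted(artifacts.noncontact_channels):
        contact[c - 1] = False
    kept_events = []
    for c in range(N_CHANNELS):
        if not contact[c]:
            kept_events.append(np.empty(0))
            continue
        idx = np.round(np.asarray(events[c]) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < T)]
        kept_events.append(idx / fs)
        train = np.zeros(T)
        np.add.at(train, idx, 1.0)
        local[c] = np.convolve(train, kernel, mode="full")[half : half + T]

    samples = local.copy()
    art_rng = np.random.default_rng(scenario.seed + 7919)
    if artifacts.qrs_amplitude > 0:
        qk = _qrs_kernel(fs, artifacts.qrs_amplitude)
        qhalf = len(qk) // 2
        beat_period = 60.0 / artifacts.qrs_rate
        train = np.zeros(T)
        beats = np.arange(0.3, duration, beat_period)
        bidx = np.round(beats * fs).astype(int)
        np.add.at(train, bidx[bidx < T], 1.0)
        qrs = np.convolve(train, qk, mode="full")[qhalf : qhalf + T]
        samples = samples + qrs[None, :]  # identical waveform, zero lag
    if artifacts.baseline_wander > 0:
        t = np.arange(T) / fs
        phases = art_rng.uniform(0, 2 * np.pi, N_CHANNELS)
        samples = samples + artifacts.baseline_wander * np.sin(
            2 * np.pi * artifacts.baseline_frequency * t[None, :] + phases[:, None]
        )
    if artifacts.noise_sd > 0:
        samples = samples + art_rng.normal(0, artifacts.noise_sd, samples.shape)

    truth = {
        "scenario": asdict(scenario),
        "artifacts": {**asdict(artifacts), "noncontact_channels": sorted(artifacts.noncontact_channels)},
        "contact": contact.tolist(),
        "event_times": kept_events,
        "active_segments": None if active_segments is None else active_segments.tolist(),
    }
    return EGMRecording(
        samples=samples, fs=fs, rhythm=rhythm, atrium=atrium,
        position_id=position_id, truth=truth,
    )


# ---------------------------------------------------------------------------
# voltage-map image fixture

#: HSV used when painting synthetic map pixels
_PURPLE_HSV = (280 / 360, 0.80, 0.90)
_GREY_HSV = (0.0, 0.02, 0.55)


def simulate_voltage_image(
    high_voltage_fraction: float,
    grey_fraction: float,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> np.ndarray:
    """Synthetic bipolar voltage-map screenshot as an RGB uint8 array.

    Colored "map" pixels occupy a central disc on a black background; they
    are painted purple (healthy, > 0.5 mV), grey (scar, < 0.1 mV) or an
    intermediate blue-to-red hue in exactly the given proportions.
    """
    if high_voltage_fraction < 0 or grey_fraction < 0:
        raise ValueError("fractions must be >= 0")
    if high_voltage_fraction + grey_fraction > 1:
        raise ValueError("fractions must sum to <= 1")
    from skimage.color import hsv2rgb

    h, w = size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = min(h, w) * 0.42
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    idx = np.flatnonzero(inside)
    rng.shuffle(idx)
    n = len(idx)
    n_purple = int(round(high_voltage_fraction * n))
    n_grey = int(round(grey_fraction * n))

    hsv = np.zeros((h, w, 3))
    flat = hsv.reshape(-1, 3)
    flat[idx[:n_purple]] = _PURPLE_HSV
    flat[idx[n_purple : n_purple + n_grey]] = _GREY_HSV
    mid = idx[n_purple + n_grey :]
    # intermediate voltages span red (0 deg, lowest) to blue (240 deg)
    hues = rng.uniform(0.0, 240 / 360, len(mid))
    flat[mid, 0] = hues
    flat[mid, 1] = 0.90
    flat[mid, 2] = 0.90
    rgb = hsv2rgb(hsv)
    return (rgb * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort fixture

#: FFAF rates by phenotype used when sampling synthetic outcomes
_FFAF_RATE = {"I": 1.00, "II": 0.86, "III": 0.43, "IV": 0.25}


@dataclass
class CohortPatient:
    """Inputs for one synthetic patient: recordings plus planted truth."""

    patient_id: str
    af_type: str
    procedure: str
    true_phenotype: str
    recordings: list[EGMRecording] = field(repr=False, default_factory=list)
    outcome: str = "FFAF"


def _phenotype_recordings(phenotype, base_seed, duration, fs, artifacts):
    """Two recordings (one per atrium) realizing a planted phenotype.

    High-consistency patients get organized planar flow; low-consistency
    patients get fibrillatory wavelet activity.  Patients with a source get a
    focal recording: continuously firing for the high-consistency case,
    firing in ~60% of segments for the low-consistency case.
    """
    v = DEFAULT_VELOCITY
    if phenotype == "I":
        scens = [
            WaveScenario(kind="planar", direction=0.9, conduction_velocity=v, seed=base_seed),
            WaveScenario(kind="planar", direction=2.1, conduction_velocity=v, seed=base_seed + 1),
        ]
    elif phenotype == "II":
        scens = [
            WaveScenario(kind="planar", direction=0.9, conduction_velocity=v, seed=base_seed),
            WaveScenario(kind="focal", source_location=(2.0, 4.0), active_fraction=1.0,
                         chaos_level=0.0, conduction_velocity=v, seed=base_seed + 1),
        ]
    elif phenotype == "III":
        scens = [
            WaveScenario(kind="fibrillatory", conduction_velocity=v, seed=base_seed),
            WaveScenario(kind="focal", source_location=(5.0, 5.0), active_fraction=0.6,
                         chaos_level=1.0, conduction_velocity=v, seed=base_seed + 1),
        ]
    elif phenotype == "IV":
        scens = [
            WaveScenario(kind="fibrillatory", conduction_velocity=v, seed=base_seed),
            WaveScenario(kind="fibrillatory", conduction_velocity=v, seed=base_seed + 1),
        ]
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    recs = []
    for i, (scen, atrium) in enumerate(zip(scens, ["LA", "RA"])):
        recs.append(
            simulate_recording(
                scen, artifacts, fs=fs, duration=duration, rhythm="AF",
                atrium=atrium, position_id=f"{atrium}-1",
            )
        )
    return recs


def generate_cohort(
    n_patients: int,
    seed: int = 0,
    duration: float = 60.0,
    fs: float = DEFAULT_FS,
    artifacts: ArtifactSpec | None = None,
) -> list[CohortPatient]:
    """Synthetic cohort cycling through the four planted phenotypes.

    Patient k gets phenotype I/II/III/IV by k mod 4, AF recordings in both
    atria realizing that phenotype, and an outcome sampled at the phenotype's
    nominal freedom-from-AF rate.
    """
    if n_patients < 4:
        raise ValueError("need n_patients >= 4 to cover all phenotypes")
    rng = np.random.default_rng(seed)
    phenos = ["I", "II", "III", "IV"]
    out = []
    for k in range(n_patients):
        ph = phenos[k % 4]
        base_seed = int(rng.integers(0, 2**31 - 1))
        recs = _phenotype_recordings(ph, base_seed, duration, fs, artifacts)
        outcome = "FFAF" if rng.random() < _FFAF_RATE[ph] else "recurrence"
        af_type = rng.choice(["PAF", "PeAF", "LS-PeAF"], p=[0.36, 0.56, 0.08])
        out.append(
            CohortPatient(
                patient_id=f"SYN-{k + 1:03d}",
                af_type=str(af_type),
                procedure=str(rng.choice(["de novo", "redo"], p=[0.64, 0.36])),
                true_phenotype=ph,
                recordings=recs,
                outcome=outcome,
            )
        )
    return out


# ---------------------------------------------------------------------------
# serialization

def save_recording_bundle(rec: EGMRecording, basename: str) -> None:
    """Write a recording as <basename>.csv (samples, one column per channel,
    header A1..H8) plus <basename>.json metadata/ground-truth sidecar."""
    import pandas as pd

    labels = [label_of(c) for c in range(1, N_CHANNELS + 1)]
    pd.DataFrame(rec.samples.T, columns=labels).to_csv(f"{basename}.csv", index=False)
    meta = {
        "fs": rec.fs, "rhythm": rec.rhythm, "atrium": rec.atrium,
        "position_id": rec.position_id,
        "truth": None if rec.truth is None else {
            **rec.truth,
            "event_times": [list(map(float, e)) for e in rec.truth["event_times"]],
        },
    }
    with open(f"{basename}.json", "w") as fh:
        json.dump(meta, fh)


def load_recording_bundle(basename: str) -> EGMRecording:
    import pandas as pd

    df = pd.read_csv(f"{basename}.csv")
    with open(f"{basename}.json") as fh:
        meta = json.load(fh)
    truth = meta.get("truth")
    if truth is not None:
        truth["event_times"] = [np.asarray(e) for e in truth["event_times"]]
    return EGMRecording(
        samples=df.to_numpy().T, fs=meta["fs"], rhythm=meta["rhythm"],
        atrium=meta["atrium"], position_id=meta["position_id"], truth=truth,
    )
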