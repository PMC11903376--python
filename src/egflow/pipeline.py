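"""End-to-end orchestration: recording -> flow map -> EGFC/sources -> phenotype.

Stage order for one recording:

1. clean baseline wander and broadband noise (far-field retained);
2. near-field contact scoring on the far-field-bearing signals — the
   zero-lag instantaneous component being scored IS the far-field, so it
   must still be present at this stage;
3. ventricular far-field subtraction, then 2-s segmentation;
4. Green's-function interpolation into field frames (non-contact electrodes
   excluded from the node set);
5. Horn-Schunck flow, averaged per segment into electrode vectors;
6. EGFC (contact-masked mean vector modulus) and divergence-based source
   detection with SAC.

Patient-level processing aggregates recording EGFCs position -> atrium ->
patient and collects the maximum SAC over all recordings; the cohort step
computes the EGFC median and assigns Type I-IV phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import egfc as egfc_mod
from .flow import FlowParams, segment_flow
from .geometry import build_grid
from .interpolate import DEFAULT_FRAME_RATE, DEFAULT_RESOLUTION, render_frames
from .nearfield import NearFieldConfig, nearfield_score
from .phenotype import PatientRecord, cohort_phenotypes, phenotype_table
from .preprocess import CleanConfig, clean, segment
from .sources import SourceParams, classify_significance, detect_sources


@dataclass
class RunConfig:
    frame_rate: float = DEFAULT_FRAME_RATE
    resolution: int = DEFAULT_RESOLUTION
    flow: FlowParams = field(default_factory=FlowParams)
    kappa: float = 1.0  # global EGFC scale, arbitrary units
    nearfield: NearFieldConfig = field(default_factory=NearFieldConfig)
    sources: SourceParams = field(default_factory=SourceParams)
    clean: CleanConfig = field(default_factory=CleanConfig)
    sr_slope: float | None = None  # SR->AF conversion, must be configured
    sr_intercept: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecordingResult:
    position_id: str
    atrium: str
    rhythm: str
    egfc: float
    contact_mask: np.ndarray = field(repr=False)
    nearfield_score: np.ndarray = field(repr=False)
    segment_maps: list = field(repr=False)
    sources: list = field(default_factory=list)

    @property
    def max_sac(self) -> float:
        return max((s.sac for s in self.sources), default=0.0)


def process_recording(recording, config: RunConfig | None = None) -> RecordingResult:
    """Run one recording through cleaning, contact scoring, interpolation,
    flow, EGFC and source detection."""
    cfg = config or RunConfig()
    grid = build_grid()

    # baseline/noise removal with far-field retained, for contact scoring
    pre_cfg = CleanConfig(highpass_hz=cfg.clean.highpass_hz,
                          lowpass_hz=cfg.clean.lowpass_hz,
                          notch_hz=cfg.clean.notch_hz, qrs_subtraction=False)
    rec_nf = clean(recording, pre_cfg)
    nf = nearfield_score(segment(rec_nf), grid, cfg.nearfield)
    contact = nf.contact

    if cfg.clean.qrs_subtraction:
        rec_clean = clean(rec_nf, CleanConfig(highpass_hz=0.0, lowpass_hz=0.0,
                                              notch_hz=None, qrs_subtraction=True))
    else:
        rec_clean = rec_nf
    segmented = segment(rec_clean)

    stack = render_frames(segmented, grid, contact_mask=contact,
                          frame_rate=cfg.frame_rate, resolution=cfg.resolution)
    maps = segment_flow(stack, contact_mask=contact, params=cfg.flow)
    value = egfc_mod.recording_egfc(maps, kappa=cfg.kappa)
    srcs = detect_sources(maps, cfg.sources, recording_id=recording.position_id)
    return RecordingResult(
        position_id=recording.position_id, atrium=recording.atrium,
        rhythm=recording.rhythm, egfc=value, contact_mask=contact,
        nearfield_score=nf.score, segment_maps=maps, sources=srcs,
    )


def process_patient(patient, config: RunConfig | None = None) -> PatientRecord:
    """Process all of a patient's recordings and aggregate to patient level."""
    cfg = config or RunConfig()
    results = [process_recording(r, cfg) for r in patient.recordings]
    agg = egfc_mod.aggregate(
        [{"egfc": r.egfc, "position_id": r.position_id, "atrium": r.atrium}
         for r in results]
    )
    value = agg["patient"]
    rhythms = {r.rhythm for r in results}
    if rhythms == {"SR"}:
        if cfg.sr_slope is not None and cfg.sr_intercept is not None:
            value = egfc_mod.sr_to_af(value, cfg.sr_slope, cfg.sr_intercept).value
        else:
            import warnings

            warnings.warn(
                f"patient {patient.patient_id}: SR-only recordings and no "
                "SR->AF coefficients configured; EGFC left unconverted"
            )
    all_sources = [s for r in results for s in r.sources
                   if classify_significance(s, cfg.sources)]
    return PatientRecord(
        patient_id=patient.patient_id,
        patient_egfc=value,
        max_sac=max((s.sac for r in results for s in r.sources), default=0.0),
        af_type=getattr(patient, "af_type", ""),
        procedure=getattr(patient, "procedure", ""),
        outcome=getattr(patient, "outcome", ""),
        sources=all_sources,
    )


def run_cohort(patients, config: RunConfig | None = None):
    """Process a cohort and phenotype it.

    Returns (patient records with phenotypes, cohort EGFC median, table).
    """
    cfg = config or RunConfig()
    records = [process_patient(p, cfg) for p in patients]
    records, median = cohort_phenotypes(records, cfg.sources.sac_threshold)
    return records, median, phenotype_table(records)
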