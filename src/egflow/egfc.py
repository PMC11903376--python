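"""Electrographic flow consistency (EGFC).

EGFC for a recording is the mean Euclidean length (modulus) of the
per-electrode, per-segment temporal-mean flow vectors, pooled over all
contacting electrodes and all segments, in arbitrary units (a global scale
constant kappa is available in config).  Electrodes with poor contact
(near-field score < 0.7) are excluded because non-contacting electrodes
carry artificially low local flow consistency.

Aggregation to the patient level gives every recording position equal
weight: recordings average into positions, positions into atria, and the
two atrial means into the patient's overall EGFC.  A patient mapped only in
sinus rhythm can be converted to the AF scale with a linear equation whose
coefficients must be supplied in config (none are bundled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class EGFCRecord:
    value: float
    level: str  # recording | position | atrium | patient
    rhythm: str = "AF"
    converted: bool = False
    detail: dict = field(default_factory=dict)


def recording_egfc(segment_maps: list, contact_mask: np.ndarray | None = None,
                   kappa: float = 1.0) -> float:
    """kappa times the mean vector modulus over (contacting electrode,
    segment) pairs."""
    moduli = []
    for smap in segment_maps:
        m = smap.modulus
        if contact_mask is not None:
            m = m[np.asarray(contact_mask, bool)]
        moduli.append(m[np.isfinite(m)])
    pooled = np.concatenate(moduli) if moduli else np.array([])
    if pooled.size == 0:
        raise ValueError("no contacting electrodes; EGFC undefined")
    return float(kappa * pooled.mean())


def aggregate(recording_values: list[dict]) -> dict:
    """Hierarchical unweighted means: recordings -> position -> atrium ->
    patient.

    ``recording_values`` rows need keys ``egfc``, ``position_id``,
    ``atrium``.  Returns {"positions": {...}, "atria": {...}, "patient": x}.
    A patient with a single mapped atrium gets that atrium's value, flagged.
    """
    if not recording_values:
        raise ValueError("no recordings to aggregate")
    by_pos: dict[str, list[float]] = {}
    pos_atrium: dict[str, str] = {}
    for row in recording_values:
        by_pos.setdefault(row["position_id"], []).append(float(row["egfc"]))
        pos_atrium[row["position_id"]] = row["atrium"]
    positions = {p: float(np.mean(v)) for p, v in by_pos.items()}
    by_atrium: dict[str, list[float]] = {}
    for p, v in positions.items():
        by_atrium.setdefault(pos_atrium[p], []).append(v)
    atria = {a: float(np.mean(v)) for a, v in by_atrium.items()}
    single = len(atria) == 1
    if single:
        warnings.warn("patient mapped in a single atrium; patient EGFC from one atrium")
    patient = float(np.mean(list(atria.values())))
    return {"positions": positions, "atria": atria, "patient": patient,
            "single_atrium": single}


def sr_to_af(egfc_sr: float, slope: float | None = None,
             intercept: float | None = None) -> EGFCRecord:
    """Convert a sinus-rhythm EGFC to the AF scale with a configured linear
    equation; refuses without coefficients."""
    if slope is None or intercept is None:
        raise ValueError(
            "SR->AF conversion coefficients are not bundled; supply slope and "
            "intercept in config or analyze SR patients unconverted"
        )
    return EGFCRecord(value=slope * egfc_sr + intercept, level="patient",
                      rhythm="AF", converted=True)
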