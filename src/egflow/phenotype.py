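"""Patient phenotyping from source significance and flow consistency.

Patients fall in a 2 x 2 grid: does any recording carry a significant
source (SAC >= 25%), and is the patient's overall EGFC at or above the
cohort median?

    Type I   — no significant source, EGFC >= median
    Type II  — significant source,    EGFC >= median
    Type III — significant source,    EGFC <  median
    Type IV  — no significant source, EGFC <  median

Freedom from AF at follow-up falls monotonically from Type I to Type IV,
which is what makes the phenotype clinically useful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAC_THRESHOLD = 25.0


@dataclass
class PatientRecord:
    patient_id: str
    patient_egfc: float
    max_sac: float = 0.0
    af_type: str = ""
    procedure: str = ""
    outcome: str = ""  # FFAF | recurrence | LTFU
    phenotype: str = ""
    sources: list = field(default_factory=list)


def classify(patient_egfc: float, max_sac: float, cohort_median: float,
             sac_threshold: float = SAC_THRESHOLD) -> str:
    """Phenotype of one patient given the cohort EGFC median.

    The source criterion is whether any recording's source reaches
    SAC >= 25%; both >= comparisons are inclusive.
    """
    has_source = max_sac >= sac_threshold
    high_egfc = patient_egfc >= cohort_median
    if high_egfc:
        return "II" if has_source else "I"
    return "III" if has_source else "IV"


def cohort_phenotypes(patients: list[PatientRecord],
                      sac_threshold: float = SAC_THRESHOLD) -> tuple[list[PatientRecord], float]:
    """Assign phenotypes across a cohort.

    The median is taken over all patients' overall EGFC (even count: mean of
    the two central values).  Returns the patients (phenotype filled in) and
    the median.
    """
    if len(patients) < 2:
        raise ValueError("need >= 2 patients for a cohort median")
    med = float(np.median([p.patient_egfc for p in patients]))
    for p in patients:
        p.phenotype = classify(p.patient_egfc, p.max_sac, med, sac_threshold)
    return patients, med


def phenotype_table(patients: list[PatientRecord]) -> "pandas.DataFrame":
    """Per-phenotype counts, EGFC summaries and outcome tabulation."""
    import pandas as pd

    rows = []
    for ph in ["I", "II", "III", "IV"]:
        grp = [p for p in patients if p.phenotype == ph]
        n = len(grp)
        fu = [p for p in grp if p.outcome in ("FFAF", "recurrence")]
        rows.append(
            {
                "phenotype": ph,
                "n": n,
                "egfc_mean": float(np.mean([p.patient_egfc for p in grp])) if grp else np.nan,
                "egfc_sd": float(np.std([p.patient_egfc for p in grp], ddof=1)) if n > 1 else np.nan,
                "sources_mean": float(np.mean([len(p.sources) for p in grp])) if grp else np.nan,
                "completed_followup": len(fu),
                "ffaf": sum(p.outcome == "FFAF" for p in fu),
            }
        )
    return pd.DataFrame(rows)
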