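# egflow

Electrographic-flow (EGF) mapping of basket-catheter atrial electrograms:
from 64-channel unipolar recordings to wavefront flow maps, flow-consistency
(EGFC) scores, extra-pulmonary-vein source detection, electrode-contact
scoring, Type I–IV patient phenotyping, voltage-map quantification, and the
statistics of the accompanying 25-patient registry.

## The problem

Pulmonary-vein isolation fails in a substantial fraction of atrial-fibrillation
(AF) patients, often because extra-PV drivers ("sources") sustain the
arrhythmia, or because the atrial substrate conducts too chaotically for any
focal ablation to help. EGF mapping addresses both questions from one minute
of panoramic 64-pole basket recordings per position:

* Unipolar electrograms are cleaned, the activation field over the unrolled
  8×8 electrode grid is estimated with **biharmonic Green's-function spline
  interpolation** (g(r) = r²(ln r − 1)), and wavefront motion is recovered
  with **Horn–Schunck optical flow**.
* Per 2-s segment, flow at each electrode is averaged into one vector; its
  length measures how consistently the wave moves the same way. **EGFC** is
  the mean vector modulus over contacting electrodes and segments (arbitrary
  units), aggregated recording → position → atrium → patient with equal
  weights.
* **Sources** are origins of divergent flow; **SAC** (source activity) is the
  percentage of 2-s segments in which a source emanates flow, with SAC ≥ 25%
  prespecified as clinically significant.
* A per-electrode **near-field score** (fraction of segments whose signal is
  conducted, not simultaneous far-field, judged by lagged normalized
  cross-correlation with the four grid neighbors) flags poor-contact
  electrodes (score < 0.7), which are excluded from EGFC.
* Patients are phenotyped on (significant source present?) × (EGFC ≥ cohort
  median?): Types I–IV, with freedom from AF falling from Type I to Type IV.
* Bipolar voltage-map screenshots are quantified by color into a
  healthy-voltage percentage (purple > 0.5 mV vs the blue→red spectrum).

The clinical recordings of the registry are not public, so the package ships
a first-class synthetic generator (`egflow.synth`) producing basket
recordings with planted planar / focal / fibrillatory wavefront dynamics,
ventricular far-field, baseline wander, noise, and non-contact electrodes —
every downstream stage is validated against its ground truth. See
`docs/methods.md` for the full model and parameter rationale.

## Worked example

```python
import numpy as np
from egflow import (WaveScenario, ArtifactSpec, simulate_recording,
                    clean, segment, render_frames, segment_flow,
                    recording_egfc, detect_sources, classify_significance)

art = ArtifactSpec(qrs_amplitude=0.3, baseline_wander=0.2, noise_sd=0.02)
rec = simulate_recording(
    WaveScenario(kind="focal", source_location=(2.0, 4.0),
                 active_fraction=0.5, chaos_level=1.0, seed=3),
    art, duration=24.0)

maps = segment_flow(render_frames(segment(clean(rec))))
print(f"EGFC = {recording_egfc(maps):.3f}")
for s in detect_sources(maps):
    if classify_significance(s):
        print(f"source at {s.label}, SAC {s.sac:.0f}%")
```

prints

```
EGFC = 4.914
source at C4-D4, SAC 58%
```

The planted source fired in half of the twelve 2-s segments at grid position
(2.0, 4.0), with fibrillatory conduction in between; the pipeline recovers it
at the adjacent electrode pair C4-D4 with SAC 58% — above the 25%
significance threshold — and the EGFC in arbitrary units reflects the mixed
organized/fibrillatory flow. A purely planar recording under the same
artifacts scores EGFC ≈ 18 with no significant source; a fully fibrillatory
one scores ≈ 1.2.

The registry statistics are reproduced from the printed cohort tables:

```bash
egflow stats
```

emits every comparison (one-tailed pooled z / t) with its recomputed and
published p-value, e.g. freedom-from-AF in high- vs low-EGFC patients
(9/10 vs 5/11, p = 0.015).

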