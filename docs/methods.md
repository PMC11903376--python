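# Methods

`egflow` reconstructs atrial wavefront propagation from 64-channel unipolar
basket-catheter electrograms and derives the quantities used to phenotype
atrial-fibrillation (AF) patients: electrographic flow consistency (EGFC),
extra-pulmonary-vein source detection with source activity (SAC), per-electrode
near-field contact scores, and the accompanying cohort statistics. This note
records the model, the parameter choices, and what the synthetic validation
does and does not demonstrate.

## Geometry

The 64-pole basket (8 splines A–H × 8 rings 1–8) is unrolled into a 2-D chart:
x = spline index (periodic, period 8), y = ring (1–8), unit spacing on both
axes. Channel numbering is A1 = 1 … H8 = 64 (spline-major). Each electrode has
exactly four neighbors — adjacent splines at the same ring (A adjoins H), and
adjacent rings on the same spline, with two artificial polar nodes P1/P8
(means of the ring-1 and ring-8 electrodes) closing the topology at the
basket poles. True 3-D basket geometry, deployment deformation, and anatomical
registration are out of scope; all distances below are chart distances with
the spline axis wrapped.

## Signal model of the synthetic generator

Clinical registry recordings are not deposited, so a geometric generator
stands in for them:

* **Local activation**: each wavefront arrival deposits a biphasic
  derivative-of-Gaussian deflection (≈10 ms wide, 1 mV) on the contacting
  electrode. Arrival times follow closed-form geometry — planar: projection
  onto the propagation direction divided by conduction velocity; focal:
  chart distance from the source over velocity, only during "active" 2-s
  segments; fibrillatory: superposed circular wavelets with Poisson-seeded
  times, random origins and velocities (0.6–1.4× nominal).
* **Wavelet origins** are drawn from a domain extending three rings beyond
  the mapped chart: the basket samples a patch of a much larger atrium, so
  most fibrillatory wavelets pass through the mapped region rather than
  originating under an electrode. This keeps transient wavelet origins from
  masquerading as stable sources, which is exactly the distinction the SAC
  threshold is meant to draw.
* **Focal scenarios** superimpose a full-intensity fibrillatory background in
  the segments where the source is *not* firing (`chaos_level` scales it).
  While the driver fires it entrains the local tissue, so background wavelets
  are suppressed during active segments. Without this background, inactive
  segments would be electrically silent — something real AF never is — and
  contact scoring would (correctly, per its rule) call quiet electrodes
  non-contacting.
* **Artifacts** are strictly additive: a common-mode ventricular far-field
  deflection (biphasic RS-like wave, ≈90 ms, identical waveform and zero lag
  on every channel — the physical signature the near-field score exploits;
  its sharp central zero-crossing pins the cross-channel correlation peak at
  lag 0, as a real far-field's sharp edges do), sinusoidal baseline wander,
  and white noise. Non-contact electrodes receive only far-field + noise.
* **Defaults**: fs = 1 kHz, 60-s recordings, AF cycle length 180 ms (SR
  800 ms), conduction velocity 50 grid-units/s so that adjacent electrodes
  see ≈20 ms conduction delays, inside the 5–50 ms physiological window.
  Validation experiments use 12–36 s recordings (6–18 segments); this is the
  package's chosen desk-scale problem size and only coarsens SAC granularity,
  not the mechanics being tested. End-to-end phenotyping uses the 36-s end of
  that range because the SAC ≥ 25% significance rule presumes fine segment
  granularity: with few segments a transient fibrillatory cluster can reach
  25% with only three recurrences.

The generator is geometric, not biophysical: no ionic dynamics, no refractory
interactions (beyond the entrainment rule above), no anisotropic conduction,
no anatomically realistic atria. Passing tests therefore demonstrate that the
pipeline recovers planted wavefront structure under realistic artifact loads —
not that it would behave identically on clinical recordings.

## Preprocessing

The clinical cleaning algorithm is proprietary and unspecified; we use
standard electrogram practice: 4th-order zero-phase Butterworth high-pass at
1.0 Hz (baseline), low-pass at 400 Hz (broadband noise), optional 50/60 Hz
notch, and ventricular far-field cancellation by common-mode template
subtraction (beats detected on the smoothed cross-channel median with a
peak-amplitude-floored threshold — a sparse beat train defeats pure
MAD-based thresholds — and an average beat per channel subtracted at each
occurrence, Tukey-tapered). The cutoffs are chosen so the filters are
near-projections on the signal band: 10-ms atrial deflections carry
essentially no energy below 1 Hz or above 400 Hz, which keeps cleaning
both transparent to artifact-free signals and idempotent; forward-backward
filtering uses ~1 s of reflected padding so low-frequency edge transients
do not leak into short recordings. Recordings are cleaned before
segmentation into contiguous half-open 2-s windows; trailing partial
segments are dropped (60 s → 30 segments).

**Stage order matters**: near-field contact scoring runs on signals with the
far-field *retained* (baseline/noise removed only), because the zero-lag
instantaneous component it measures *is* the far-field; QRS subtraction is
applied afterwards, before interpolation and flow.

## Near-field contact score

Per channel and 2-s segment, signal energy is decomposed into conduction,
instantaneous, and fractionation ratios. The conduction component of a
channel–neighbor pair is the peak normalized cross-correlation over lags,
zeroed unless the best lag lies in 5–50 ms (faster ⇒ far-field, slower ⇒ not
conduction); the channel value is the mean of non-zero pair components.
Both orderings of each pair are evaluated and the overall peak taken — a
wavefront may reach either electrode first, and conduction is directionless.
The correlation window is N = len/2 samples, with the denominator energies
taken over the same windows as the numerator (the sliding-window form of
normalized cross-correlation). If no conduction is found, the instantaneous
component is the mean zero-lag correlation with all neighbors. The
per-segment mask is 1 iff the instantaneous ratio < 0.3; the per-electrode
score is the mask mean over segments, and contact is poor when the score
< 0.7 (the 0.7 boundary itself counts as good). An alternative
`caption_mode` rule — near-field iff some neighbor shows positive correlation
peaking inside the conduction window — is available in config; it differs on
pure-noise channels (the primary rule scores them near-field, the alternative
does not) and the primary rule is the default.

## Interpolation

Electrode amplitudes are interpolated with the 2-D biharmonic Green's
function g(r) = r²(ln r − 1), g(0) = 0: weights solve Gw = v with
G_ij = g(|xᵢ − xⱼ|), giving a minimum-curvature surface that passes exactly
through the node values. All distances use the wrapped spline-axis metric, so
the rendered field is exactly periodic across the A–H seam. (Replicating
nodes at ±1 period was considered and rejected: g grows with r, so truncated
replication leaves O(10⁻³) seam mismatch, while the periodic metric leaves
none.) Ill-conditioned systems (duplicate nodes) are retried with a small
ridge. Non-contact electrodes are excluded from the node set entirely.

The interpolated quantity is by default the **activation envelope** — moving
RMS of the cleaned signal over 20 ms — rather than the raw potential. A
passing wavefront then appears as a positive blob translating smoothly across
the chart. Raw-potential frames of a 10-ms biphasic deflection sampled by
electrodes one spacing apart do not translate; they blink from electrode to
electrode, which violates the brightness-constancy assumption optical flow
rests on. Frames default to 125/s at 16×16 resolution (2 pixels per electrode
spacing): at 50 grid-units/s the wavefront moves ≈0.8 px/frame, inside the
small-displacement regime of the flow estimator. Both are configurable.

## Optical flow and EGFC

Classic Horn–Schunck: central-difference spatial gradients averaged over the
frame pair, forward temporal difference, Jacobi iteration of the coupled
update with the standard 3×3 neighborhood-average stencil; α = 1.0 and 100
iterations by default (the original system's values are unpublished; both are
config). Per 2-s segment and electrode, instantaneous flow sampled bilinearly
at the electrode pixel is averaged over the segment's frames into one vector
in grid-units/s. **Raw vectors are averaged, not unit vectors**: repeatable
flow keeps its magnitude, disorganized flow cancels — reported EGFC values
above 1 rule out unit-vector averaging. EGFC of a recording is the mean
vector modulus pooled over (contacting electrode, segment) pairs, times a
global scale κ (default 1, arbitrary units); poor-contact electrodes are
excluded because their artificially small vectors bias EGFC downward.
Pooling pairs versus averaging segments first is identical for complete data;
we pool. Aggregation gives recordings equal weight within a position,
positions within an atrium, and the two atria within a patient. The absolute
EGFC scale is arbitrary — analyses use orderings and the cohort-median split,
never absolute values. SR→AF conversion is a linear map whose coefficients
must be supplied in config; none are bundled, and SR-only patients are left
unconverted with a warning otherwise.

## Source detection and SAC

Per segment, flow vectors on the 8×8 lattice (gaps filled by iterative
neighbor averaging) yield a divergence field via central differences,
periodic along splines, one-sided at ring edges. A candidate is a lattice
local maximum with divergence > τ_div = 0.2 (grid-units/s per unit) that
passes two outwardness gates computed around its divergence-weighted 3×3
centroid: (a) ≥ τ_cov = 75% of the surrounding lattice directions have a
positive radial flow component, and (b) every cardinal direction, sampled two
spacings out, points outward. The cardinal test at radius 2 rejects
divergence bumps on through-going waves (flow decelerating and re-accelerating
diverges without originating) while tolerating the near-zero, arbitrary-sign
vectors immediately beside a true singularity. Edge rings are excluded: a
wavefront leaving the mapped chart mimics divergence there with no opposing
neighbor to refute it. Candidates within 1.0 electrode spacing merge across
segments into one source; SAC is the percentage of segments with a candidate,
a source is clinically significant at SAC ≥ 25% (inclusive), and locations
are reported as the nearest electrode pair (e.g. "C5-C6"). τ_div and τ_cov
were calibrated on the simulator so that planar negative controls stay clean
while planted focal sources are recovered; both are config. The per-segment
"emanating flow" criterion is not quantitatively defined in the source
literature, so this operationalization is the package's own.

## Phenotyping

Type I = no significant source & EGFC ≥ cohort median; II = source & ≥
median; III = source & < median; IV = no source & < median. "No significant
source" means no recording of the patient carries a source with SAC ≥ 25
(pre-ablation maps only). Even-count medians are the midpoint of the central
pair. Both ≥ comparisons are inclusive at their boundaries.

## Voltage-map quantification

Map screenshots encode bipolar amplitude as color: purple > 0.5 mV (healthy),
grey < 0.1 mV (scar), a blue→red spectrum between. Pixels are classified by
HSV rules (background: value < 0.12; grey: saturation < 0.20; purple: hue
255–325°; intermediate: the rest), with palette boundaries in config since
clinical color scales are not standardized. The healthy-voltage percentage is
100·purple/(purple + intermediate) by default — grey scar pixels excluded so
the number is a true percentage of viable mapped surface — with the literal
ratio 100·purple/intermediate always reported alongside and a config flag to
include grey in the denominator.

## Statistics

Group comparisons are one-tailed in the direction of the observed difference:
pooled-proportion z without continuity correction, and pooled-variance t
(df = n₁+n₂−2) from summary statistics (Welch via flag). These inferred
choices reproduce the seven recomputable registry p-values to three decimals
(0.002, 0.005, 0.011, 0.013, 0.003, 0.015, 0.038); the de-novo-PAF (printed
0.017, recomputes 0.018) and de-novo-PeAF (printed 0.026, recomputes 0.027)
comparisons do not reproduce under any standard two-proportion test we tried
and are reported with their printed values for reference only. Regression is
ordinary least squares with r, r², and the slope F-test p.

## Numerical and degenerate-input choices

Zero-energy correlation windows return 0 and are flagged. Degenerate
proportion tests (pooled proportion 0 or 1) return p = 0.5. Zero pooled
variance returns p = 0.5 for equal means and p = 0 (flagged) otherwise.
Background-only voltage images return an undefined healthy percentage with a
flag rather than an error. Recordings shorter than one 2-s segment are
rejected. All generators and experiments are seeded; fixed seeds reproduce
recordings bit-for-bit.

## Known limitations

* The synthetic generator's realism bounds what validation can show (see
  above); in particular near-field scoring under the primary rule calls a
  pure-noise channel "near-field", a known quirk of the published rule that
  `caption_mode` avoids.
* Localization is validated for single stable sources over fibrillatory
  background; simultaneous multiple sources within a merge radius are not
  separated.
* The 2-D chart ignores true basket geometry, so grid-unit velocities and
  divergences are not physical units.
* SAC granularity is 100/n_segments; short validation recordings make it
  coarse (8.3 points at 24 s).
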