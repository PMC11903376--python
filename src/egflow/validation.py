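"""Validation experiments: seeded end-to-end checks of each pipeline claim.

The registry's clinical recordings are not public, so the pipeline's
quantitative claims are validated against the synthetic generator's ground
truth: interpolation exactness, optical-flow direction against an
independent phase-correlation oracle, the EGFC planar/fibrillatory ordering,
focal-source localization and SAC recovery with planar negative controls,
near-field discrimination of planted non-contact electrodes, phenotype
recovery, and voltage-map quantification.  Every experiment takes a seed
and reports summary numbers; problem sizes default to desk scale
(12-36 s recordings).
"""

from __future__ import annotations

import numpy as np

from .egfc import recording_egfc
from .flow import FlowParams, horn_schunck, segment_flow
from .geometry import N_CHANNELS
from .interpolate import evaluate_biharmonic, fit_biharmonic, render_frames
from .nearfield import NearFieldConfig, nearfield_score
from .phenotype import classify
from .pipeline import RunConfig, run_cohort
from .preprocess import CleanConfig, clean, segment
from .sources import SourceParams, detect_sources
from .synth import (ArtifactSpec, WaveScenario, generate_cohort,
                    simulate_recording, simulate_voltage_image)
from .voltage import analyze_image

#: artifact levels used across validation recordings
DEFAULT_ARTIFACTS = ArtifactSpec(qrs_amplitude=0.3, baseline_wander=0.2,
                                 noise_sd=0.02)

#: the seven registry comparisons whose printed p-values are recomputable
#: to three decimals under the inferred pooled one-tailed tests
TARGET_COMPARISONS = (
    "prior_ablation_paf_vs_peaf",
    "cardioversion_paf_vs_peaf",
    "sources_per_patient_paf_vs_peaf",
    "per_protocol_paf_vs_peaf",
    "ffaf_denovo_vs_redo",
    "ffaf_high_vs_low_egfc",
    "type_i_paf_vs_peaf",
)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _chart_dist(a, b) -> float:
    dx = (a[0] - b[0] + 4.0) % 8.0 - 4.0
    return float(np.hypot(dx, a[1] - b[1]))


def registry_pvalues() -> dict[str, dict]:
    """Recompute the registry comparisons; keys are comparison names."""
    from .stats import load_registry_tables, t_test_from_summary, two_prop_z

    tables = load_registry_tables()
    out = {}
    for c in tables["proportions"]:
        r = two_prop_z(c["k1"], c["n1"], c["k2"], c["n2"])
        out[c["name"]] = {"p": r.p_one_tailed, "n": c["n1"] + c["n2"]}
    for c in tables["means"]:
        r = t_test_from_summary(c["m1"], c["sd1"], c["n1"],
                                c["m2"], c["sd2"], c["n2"])
        out[c["name"]] = {"p": r.p_one_tailed, "n": c["n1"] + c["n2"]}
    return out


def interpolation_exactness(n_configs: int = 100, seed: int = 0,
                            n_nodes: int = 10) -> float:
    """Max |interpolant - value| at the nodes over random configurations."""
    worst = 0.0
    for s in _sub_seeds(seed, n_configs):
        rng = np.random.default_rng(s)
        xy = rng.uniform(0, 8, (n_nodes, 2))
        vals = rng.normal(size=n_nodes)
        w = fit_biharmonic(xy, vals)
        err = np.abs(evaluate_biharmonic(xy, w, xy) - vals).max()
        worst = max(worst, float(err))
    return worst


def flow_direction_errors(n_seeds: int = 20, seed: int = 0) -> list[float]:
    """Angular error (degrees) of Horn-Schunck mean flow on a translating
    Gaussian blob versus a phase-cross-correlation displacement oracle."""
    from skimage.registration import phase_cross_correlation

    errors = []
    for s in _sub_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        yy, xx = np.mgrid[0:48, 0:48].astype(float)
        cx, cy = rng.uniform(16, 28, 2)
        # uniform direction, magnitude bounded away from zero (a direction
        # comparison needs a well-defined displacement)
        ang = rng.uniform(0, 2 * np.pi)
        mag = rng.uniform(0.4, 1.2)
        dx, dy = mag * np.cos(ang), mag * np.sin(ang)
        sig = 3.0
        a = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
        b = np.exp(-((xx - cx - dx) ** 2 + (yy - cy - dy) ** 2) / (2 * sig**2))
        u, v = horn_schunck(a, b)
        w = a > 0.1
        hs_ang = np.arctan2(v[w].mean(), u[w].mean())
        # plain cross-correlation upsampling: spectral whitening amplifies
        # high-frequency noise on smooth band-limited images
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=100,
                                              normalization=None)
        # oracle shift is (row, col) of b relative to a, negated for flow
        or_ang = np.arctan2(-shift[0], -shift[1])
        d = np.degrees(np.abs(np.angle(np.exp(1j * (hs_ang - or_ang)))))
        errors.append(float(d))
    return errors


def egfc_ordering_experiment(n_pairs: int = 20, seed: int = 0,
                             duration: float = 12.0) -> dict:
    """EGFC of organized planar flow vs fibrillatory activity at matched
    mean wave speed, over seeded pairs."""
    planar_vals, fib_vals = [], []
    for s in _sub_seeds(seed, n_pairs):
        rng = np.random.default_rng(s)
        direction = rng.uniform(0, 2 * np.pi)
        rp = simulate_recording(
            WaveScenario(kind="planar", direction=direction, seed=s),
            DEFAULT_ARTIFACTS, duration=duration)
        rf = simulate_recording(
            WaveScenario(kind="fibrillatory", seed=s + 1),
            DEFAULT_ARTIFACTS, duration=duration)
        planar_vals.append(recording_egfc(segment_flow(render_frames(segment(clean(rp))))))
        fib_vals.append(recording_egfc(segment_flow(render_frames(segment(clean(rf))))))
    n_correct = int(sum(p > f for p, f in zip(planar_vals, fib_vals)))
    return {"n_pairs": n_pairs, "n_correct": n_correct,
            "planar_mean": float(np.mean(planar_vals)),
            "fibrillatory_mean": float(np.mean(fib_vals))}


def source_recovery_experiment(n_runs: int = 20, seed: int = 0,
                               duration: float = 24.0,
                               active_fraction: float = 0.5) -> dict:
    """Focal-source localization and SAC recovery plus planar negatives.

    Each focal run plants a source at a random location firing in half the
    segments over a fibrillatory background; each planar control must yield
    no source with SAC >= 25%.
    """
    loc_hits = sac_hits = planar_clean = 0
    params = SourceParams()
    for s in _sub_seeds(seed, n_runs):
        rng = np.random.default_rng(s)
        true_loc = (rng.uniform(0, 8), rng.uniform(2.5, 6.5))
        rec = simulate_recording(
            WaveScenario(kind="focal", source_location=true_loc,
                         active_fraction=active_fraction, chaos_level=1.0,
                         seed=s),
            DEFAULT_ARTIFACTS, duration=duration)
        maps = segment_flow(render_frames(segment(clean(rec))))
        srcs = detect_sources(maps, params)
        if srcs:
            best = min(srcs, key=lambda x: _chart_dist(x.location, true_loc))
            loc_hits += _chart_dist(best.location, true_loc) <= 1.0
            sac_hits += abs(best.sac - 100.0 * active_fraction) <= 10.0
        rp = simulate_recording(
            WaveScenario(kind="planar", direction=rng.uniform(0, 2 * np.pi),
                         seed=s + 1),
            DEFAULT_ARTIFACTS, duration=duration)
        mp = segment_flow(render_frames(segment(clean(rp))))
        planar_clean += not any(x.sac >= params.sac_threshold
                                for x in detect_sources(mp, params))
    return {"n_runs": n_runs, "localized_within_1": loc_hits,
            "sac_within_10": sac_hits, "planar_clean": planar_clean}


def nearfield_discrimination_experiment(n_seeds: int = 20, seed: int = 0,
                                        duration: float = 12.0,
                                        n_noncontact: int = 6) -> dict:
    """Sensitivity/specificity of the poor-contact call (score < 0.7) on
    recordings with planted non-contact channels."""
    tp = fn = tn = fp = 0
    for s in _sub_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        bad = frozenset(rng.choice(np.arange(1, N_CHANNELS + 1),
                                   size=n_noncontact, replace=False).tolist())
        art = ArtifactSpec(qrs_amplitude=DEFAULT_ARTIFACTS.qrs_amplitude,
                           baseline_wander=DEFAULT_ARTIFACTS.baseline_wander,
                           noise_sd=DEFAULT_ARTIFACTS.noise_sd,
                           noncontact_channels=bad)
        rec = simulate_recording(
            WaveScenario(kind="planar", direction=rng.uniform(0, 2 * np.pi),
                         seed=s),
            art, duration=duration)
        rc = clean(rec, CleanConfig(qrs_subtraction=False))
        nf = nearfield_score(segment(rc))
        truth_contact = np.array(rec.truth["contact"])
        poor_call = ~nf.contact
        tp += int(np.sum(poor_call & ~truth_contact))
        fn += int(np.sum(~poor_call & ~truth_contact))
        tn += int(np.sum(~poor_call & truth_contact))
        fp += int(np.sum(poor_call & truth_contact))
    return {"n_seeds": n_seeds,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan")}


def phenotype_truth_table() -> int:
    """Number of correct cells in the exhaustive 2x2 (x boundary) rule table."""
    med = 0.548
    cases = [
        (med + 0.1, 0.0, "I"), (med + 0.1, 24.9, "I"), (med, 0.0, "I"),
        (med + 0.1, 25.0, "II"), (med, 37.0, "II"),
        (med - 0.1, 25.0, "III"), (med - 0.1, 99.0, "III"),
        (med - 0.1, 0.0, "IV"), (med - 0.1, 24.9, "IV"),
    ]
    return sum(classify(e, s, med) == ph for e, s, ph in cases), len(cases)


def cohort_recovery_experiment(seed: int = 0, duration: float = 36.0) -> dict:
    """End-to-end phenotype recovery on a 4-patient synthetic cohort.

    Recordings are 36 s (18 segments): the SAC significance threshold
    presumes fine segment granularity, and shorter recordings let a
    transient fibrillatory cluster reach 25% with only 3 recurrences.
    """
    cohort = generate_cohort(4, seed=seed, duration=duration,
                             artifacts=DEFAULT_ARTIFACTS)
    records, median, _ = run_cohort(cohort, RunConfig())
    n_correct = sum(p.phenotype == c.true_phenotype
                    for p, c in zip(records, cohort))
    return {"n_patients": 4, "n_correct": int(n_correct),
            "cohort_median": float(median)}


def voltage_quantification_experiment(seed: int = 0) -> dict:
    """Recovered healthy-voltage % vs generator ground truth over a sweep of
    planted class fractions."""
    worst = 0.0
    cases = [(0.3, 0.2), (0.5, 0.0), (0.1, 0.4), (0.7, 0.1), (0.45, 0.25)]
    for i, (high, grey) in enumerate(cases):
        img = simulate_voltage_image(high, grey, size=(128, 128), seed=seed + i)
        res = analyze_image(img)
        expected = 100.0 * high / (high + (1.0 - high - grey))
        worst = max(worst, abs(res.healthy_percent - expected))
    return {"n_images": len(cases), "max_error_points": float(worst)}
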