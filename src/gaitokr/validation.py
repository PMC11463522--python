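"""Synthetic validation benchmarks: parameter recovery with known ground truth.

Each function simulates data with the generators in :mod:`gaitokr.synth`,
runs the corresponding analysis stage, and reports recovery/agreement
metrics.  These are the quantitative checks behind the package's claims that
its estimators are unbiased under the generators' assumptions; the test suite
asserts thresholds on their outputs and ``scripts/acceptance.py`` reports
them.

All randomness derives from the ``seed`` argument.
"""
from __future__ import annotations

import itertools
import math
import warnings

import numpy as np

from . import gait, oculomotor, pathology, pipeline, stats
from .synth import (MINJERK_PEAK_FACTOR, EyeSimParams, EyeTrace,
                    GaitSimParams, gen_eye_trace, gen_gait_track,
                    minimum_jerk)
from scipy.special import i0, i1


def _spawn(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]


# ---------------------------------------------------------------------------
# Saccade threshold contract
# ---------------------------------------------------------------------------

def saccade_threshold_contract(seed: int = 0) -> dict:
    """Sweep candidate events over amplitude 0.5-8 deg / velocity 40-400 deg/s.

    Builds a flat trace carrying one minimum-jerk step per (amplitude,
    velocity) combination and verifies the per-axis acceptance contract on
    everything the detector returns.
    """
    rng = np.random.default_rng(seed)
    amps = np.linspace(0.5, 8.0, 9)
    vels = np.linspace(40.0, 400.0, 9)
    combos = [(a * s, v) for a in amps for v in vels
              for s in (rng.choice([-1.0, 1.0]),)]
    fs = 200.0
    t = np.arange(0.0, len(combos) * 1.0 + 1.0, 1.0 / fs)
    pos = np.zeros_like(t)
    for i, (a, v) in enumerate(combos):
        d = MINJERK_PEAK_FACTOR * abs(a) / v
        pos = pos + a * minimum_jerk((t - (0.5 + i)) / d)
    out = {}
    for axis in ("horizontal", "vertical"):
        zero = np.zeros_like(pos)
        trace = EyeTrace(t, pos if axis == "horizontal" else zero,
                         pos if axis == "vertical" else zero, fs)
        events = oculomotor.detect_saccades(trace, axis=axis)
        amin, vmin = oculomotor.DEFAULT_THRESHOLDS[axis]
        out[axis] = {
            "n_candidates": len(combos),
            "n_retained": len(events),
            "min_retained_amplitude": min((abs(e.amplitude) for e in events),
                                          default=math.nan),
            "min_retained_velocity": min((e.peak_velocity for e in events),
                                         default=math.nan),
            "violations": sum(1 for e in events
                              if abs(e.amplitude) < amin
                              or e.peak_velocity < vmin),
        }
    return out


# ---------------------------------------------------------------------------
# OKR gain recovery
# ---------------------------------------------------------------------------

def okr_gain_recovery(seed: int = 0) -> dict:
    """Gain identity/linearity over gains x frequencies, plus trial exclusion.

    Noiseless tracking traces at gains {0, 0.35, 0.7, 1.0} across the five
    drum frequencies; separately, a gain-0.7 recording contaminated with
    spontaneous saccades, where the detected events must be excluded without
    biasing the mean gain.
    """
    gains = (0.0, 0.35, 0.7, 1.0)
    freqs = (0.2, 0.4, 0.6, 0.8, 1.0)
    max_err = 0.0
    for g in gains:
        for f in freqs:
            params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=g,
                                  oscillation_frequency=f, n_trials=3,
                                  seed=seed)
            trace, schedule, _ = gen_eye_trace(params)
            mean_gain, _ = oculomotor.compute_okr_gain(trace, schedule, [])
            max_err = max(max_err, abs(float(mean_gain[f]) - g))

    params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=0.7,
                          n_trials=15, quick_phase_rate=0.04, seed=seed + 1)
    trace, schedule, gt = gen_eye_trace(params)
    events = oculomotor.detect_saccades(trace, axis="horizontal")
    mean_gain, cycles = oculomotor.compute_okr_gain(trace, schedule, events)
    return {
        "max_abs_gain_error_noiseless": max_err,
        "contaminated_mean_gain": float(mean_gain.iloc[0]),
        "contaminated_gain_bias": abs(float(mean_gain.iloc[0]) - 0.7),
        "n_injected_saccades": int(len(gt.events)),
        "n_excluded_trials": int(cycles.loc[cycles.excluded, "trial"].nunique()),
    }


# ---------------------------------------------------------------------------
# Gait parameter recovery
# ---------------------------------------------------------------------------

def gait_parameter_recovery(seed: int = 0, n_runs: int = 100,
                            n_strides: int = 15) -> dict:
    """Recovery error over runs spanning the generator's parameter ranges.

    Cadence 2-5 strides/s, stance fraction 0.5-0.75, stride length 40-80 mm,
    interlimb phase noise kappa in {5, 20, inf}, 0.5 mm coordinate noise.
    Also checks the stepping-variability estimator against the von Mises
    closed form sqrt(-2 ln(I1(k)/I0(k))) at 200 strides.
    """
    rng = np.random.default_rng(seed)
    errs = {"cadence": [], "stride_length": [], "stance_fraction": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_runs):
            params = GaitSimParams(
                n_strides=n_strides,
                cadence=float(rng.uniform(2.0, 5.0)),
                stance_fraction=float(rng.uniform(0.5, 0.75)),
                stride_length=float(rng.uniform(40.0, 80.0)),
                phase_noise_kappa=float(rng.choice([5.0, 20.0, np.inf])),
                coord_noise_sd=0.5,
                seed=int(rng.integers(2**31)))
            track, _ = gen_gait_track(params)
            res = gait.analyze_track(track)
            errs["cadence"].append(
                abs(res.summary["cadence"] - params.cadence) / params.cadence)
            errs["stride_length"].append(
                abs(res.summary["stride_length"] - params.stride_length)
                / params.stride_length)
            errs["stance_fraction"].append(
                abs(res.summary["stance_fraction"] - params.stance_fraction))

        von_mises = {}
        for kappa in (5.0, 20.0):
            params = GaitSimParams(n_strides=200, cadence=3.13,
                                   phase_noise_kappa=kappa,
                                   seed=int(rng.integers(2**31)))
            track, _ = gen_gait_track(params)
            res = gait.analyze_track(track)
            closed = math.sqrt(-2.0 * math.log(i1(kappa) / i0(kappa)))
            von_mises[kappa] = {"recovered": res.variability.mean,
                                "closed_form": closed,
                                "abs_error": abs(res.variability.mean - closed)}
    return {
        "n_runs": n_runs,
        "median_cadence_rel_error": float(np.median(errs["cadence"])),
        "median_stride_length_rel_error": float(np.median(errs["stride_length"])),
        "median_stance_fraction_abs_error": float(
            np.median(errs["stance_fraction"])),
        "von_mises": von_mises,
    }


# ---------------------------------------------------------------------------
# Detector precision / recall
# ---------------------------------------------------------------------------

def _match(detected: list[float], injected: list[float],
           tol_s: float = 0.025) -> tuple[int, int, int]:
    remaining = sorted(injected)
    tp = 0
    for t in sorted(detected):
        hit = next((i for i, g in enumerate(remaining)
                    if abs(g - t) <= tol_s), None)
        if hit is not None:
            remaining.pop(hit)
            tp += 1
    return tp, len(detected) - tp, len(remaining)


def detector_performance(seed: int = 0) -> dict:
    """Precision/recall vs ground truth at 130 and 200 Hz, 0.1 deg noise."""
    out = {}
    for fs, sub_seed in zip((130.0, 200.0), _spawn(seed, 2)):
        params = EyeSimParams(assay="unidirectional_dome", axis="horizontal",
                              quick_phase_rate=0.3, amplitude_range=(3.5, 8.0),
                              position_noise_sd=0.1, sample_rate=fs,
                              seed=sub_seed)
        trace, _, gt = gen_eye_trace(params)
        events = oculomotor.detect_saccades(trace, axis="horizontal")
        tp, fp, fn = _match([e.onset_t for e in events],
                            list(gt.events.onset_t))
        out[int(fs)] = {"n_injected": int(len(gt.events)),
                        "n_detected": len(events),
                        "precision": tp / max(tp + fp, 1),
                        "recall": tp / max(tp + fn, 1)}
    return out


# ---------------------------------------------------------------------------
# Main-sequence CI coverage
# ---------------------------------------------------------------------------

def main_sequence_coverage(seed: int = 0, n_sim: int = 100,
                           n_events: int = 100, slope: float = 12.0,
                           intercept: float = 50.0,
                           noise_sd: float = 10.0) -> dict:
    """Fraction of simulations whose fitted 95% CI covers the injected slope."""
    covered = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_sim):
        amps = rng.uniform(3.5, 8.0, n_events)
        vels = slope * amps + intercept + rng.normal(0.0, noise_sd, n_events)
        events = [oculomotor.SaccadeEvent(
            onset_t=float(i), offset_t=float(i) + 0.03, amplitude=float(a),
            peak_velocity=float(v), axis="horizontal", direction="nasal")
            for i, (a, v) in enumerate(zip(amps, vels))]
        fit = oculomotor.fit_main_sequence(events)
        if fit.slope_ci[0] <= slope <= fit.slope_ci[1]:
            covered += 1
    return {"n_simulations": n_sim, "n_covered": covered,
            "coverage": covered / n_sim}


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def _brute_force_mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating every group assignment."""
    def u_stat(x, y):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                   for xi in x for yj in y)

    a, b = list(a), list(b)
    u_obs = u_stat(a, b)
    pooled = a + b
    n1 = len(a)
    mid = n1 * len(b) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        rest = [i for i in range(len(pooled)) if i not in idx]
        u = u_stat([pooled[i] for i in idx], [pooled[i] for i in rest])
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def statistics_oracle_agreement(seed: int = 0, n_mwu_cases: int = 500,
                                n_mc_permutations: int = 100_000) -> dict:
    """Exact-test agreement with brute-force enumeration.

    Mann-Whitney: random tie-free inputs at all group sizes <= 5, comparing
    the package's exact p against full enumeration of group assignments.
    Pearson: for n <= 6, the package's exhaustive-permutation p against an
    independent Monte-Carlo permutation estimate.
    """
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    agree = 0
    sizes = [(n1, n2) for n1 in range(1, 6) for n2 in range(1, 6)]
    for k in range(n_mwu_cases):
        n1, n2 = sizes[k % len(sizes)]
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        res = stats.mann_whitney_u(a, b)
        p_ref = _brute_force_mwu_p(a, b)
        dev = abs(res.p_value - p_ref)
        max_dev = max(max_dev, dev)
        agree += dev < 1e-9

    pearson = []
    for n in (4, 5, 6):
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        r, p_exact, method = pathology.pearson_with_p(x, y)
        perm_rs = np.empty(n_mc_permutations)
        for i in range(n_mc_permutations):
            perm_rs[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_mc = float(np.mean(np.abs(perm_rs) >= abs(r) - 1e-12))
        pearson.append({"n": n, "p_exact": p_exact, "p_monte_carlo": p_mc,
                        "abs_diff": abs(p_exact - p_mc)})
    return {
        "mwu_cases": n_mwu_cases,
        "mwu_agreement_rate": agree / n_mwu_cases,
        "mwu_max_abs_p_deviation": max_dev,
        "pearson_small_n": pearson,
        "pearson_max_abs_diff": max(c["abs_diff"] for c in pearson),
    }


# ---------------------------------------------------------------------------
# End-to-end cohort power
# ---------------------------------------------------------------------------

def cohort_power(seed: int = 0, n_reruns: int = 50,
                 alpha: float = 0.05) -> dict:
    """Detection power for the injected group effects and pooled false-positive
    rate on null measures, over seeded cohort reruns."""
    sub_seeds = _spawn(seed, n_reruns)
    effect_hits = {m: 0 for m in pipeline.EFFECT_MEASURES}
    effect_hits["dcn_downward_correlation"] = 0
    null_trials = 0
    null_hits = 0
    per_null = {m: 0 for m in pipeline.NULL_MEASURES}
    null_corr_trials = null_corr_hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in sub_seeds:
            cohort = pipeline.simulate_cohort(seed=s)
            res = pipeline.analyze_cohort(cohort, alpha=alpha)
            comp = res.comparisons.set_index("measure")
            for m in pipeline.EFFECT_MEASURES:
                effect_hits[m] += int(comp.loc[m, "p_value"] < alpha)
            for m in pipeline.NULL_MEASURES:
                hit = int(comp.loc[m, "p_value"] < alpha)
                per_null[m] += hit
                null_hits += hit
                null_trials += 1
            corr = res.correlations
            dcn = corr[(corr.region == "DCN")
                       & (corr.behavior_measure == "downward_qp_freq")]
            effect_hits["dcn_downward_correlation"] += int(
                (dcn.p_value.iloc[0] < alpha) and (dcn.pearson_r.iloc[0] < 0))
            null_corr = corr[(corr.region != "DCN")
                             & (corr.behavior_measure == "downward_qp_freq")]
            null_corr_hits += int((null_corr.p_value < alpha).sum())
            null_corr_trials += int(len(null_corr))
    power = {m: h / n_reruns for m, h in effect_hits.items()}
    return {
        "n_reruns": n_reruns,
        "power": power,
        "min_power": min(power.values()),
        "null_false_positive_rate": null_hits / max(null_trials, 1),
        "per_null_measure_rate": {m: h / n_reruns for m, h in per_null.items()},
        "null_correlation_false_positive_rate":
            null_corr_hits / max(null_corr_trials, 1),
        "pooled_null_false_positive_rate":
            (null_hits + null_corr_hits)
            / max(null_trials + null_corr_trials, 1),
    }
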