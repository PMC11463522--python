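"""Stride segmentation and interlimb-coordination statistics from limb pose tracks.

The pipeline mirrors standard linear-track gait analysis: limb trajectories
are projected onto the nose–tail body axis, stance onsets are the local maxima
of the anteroposterior (AP) coordinate (paw closest to the nose), swing onsets
the local minima between them (paw farthest from the nose).  Per-stride
metrics (cadence, stride length, stance/swing fraction, walking speed) and
circular interlimb phases relative to the left forelimb follow.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synth import LIMBS, NON_REFERENCE_LIMBS, PoseTrack

REFERENCE_LIMB = "LF"


class DegenerateAxisError(ValueError):
    """Nose and tail base coincide on some frame; the body axis is undefined."""


class DataIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationConfig:
    """Extremum-detection safeguards for stride segmentation.

    The stance-onset criterion (trajectory maximum) is applied on a
    low-pass-filtered copy of the AP trajectory to suppress tracker jitter;
    extremum locations are then refined on the unfiltered trajectory so the
    filter cannot bias event times.
    """

    lowpass_hz: float = 10.0
    min_separation_s: float = 0.1
    min_prominence_frac: float = 0.1   # fraction of the trajectory's run-range
    plateau_tol_frac: float = 0.03     # of run-range; anchors events to the
    #                                    steep side of flat-topped extrema
    likelihood_threshold: float = 0.9
    max_interp_gap: int = 5            # frames


@dataclass(frozen=True)
class Stride:
    limb: str
    stance_onset: int        # frame index
    swing_onset: int
    next_stance_onset: int

    def __post_init__(self):
        if not (self.stance_onset < self.swing_onset < self.next_stance_onset):
            raise DataIntegrityError(
                "stride requires stance_onset < swing_onset < next_stance_onset")


@dataclass(frozen=True)
class StraightRun:
    start_frame: int
    end_frame: int
    mean_heading: float   # radians
    mean_speed: float     # mm/s


@dataclass
class SteppingVariability:
    per_limb: dict[str, float]   # circular SD, radians
    mean: float


def interpolate_low_likelihood(track: PoseTrack,
                               config: SegmentationConfig = SegmentationConfig()
                               ) -> PoseTrack:
    """Linearly interpolate low-confidence frames over gaps <= max_interp_gap.

    Longer gaps are left as NaN; downstream run isolation splits around them.
    """
    data = track.data.copy()
    parts = data.columns.get_level_values(0).unique()
    for part in parts:
        bad = data[(part, "likelihood")].to_numpy() < config.likelihood_threshold
        if not bad.any():
            continue
        for coord in ("x", "y"):
            s = data[(part, coord)].copy()
            s[bad] = np.nan
            data[(part, coord)] = s.interpolate(
                method="linear", limit=config.max_interp_gap,
                limit_area="inside")
    return PoseTrack(data=data, frame_rate=track.frame_rate,
                     px_per_mm=track.px_per_mm)


def normalize_to_body_axis(track: PoseTrack) -> pd.DataFrame:
    """Project limb positions onto the nose–tail axis, relative to its midpoint.

    Returns a DataFrame (one column per limb) of anteroposterior coordinates
    in mm, positive toward the nose.  This projection makes the analysis
    invariant to the image coordinate convention.
    """
    nose = track.part("nose")
    tail = track.part("tail_base")
    axis = nose - tail
    norm = np.linalg.norm(axis, axis=1)
    if np.any(norm < 1e-9):
        raise DegenerateAxisError("nose and tail base coincide on some frame")
    unit = axis / norm[:, None]
    mid = 0.5 * (nose + tail)
    out = {}
    for limb in LIMBS:
        rel = track.part(limb) - mid
        out[limb] = np.einsum("ij,ij->i", rel, unit) / track.px_per_mm
    return pd.DataFrame(out)


def body_midpoint(track: PoseTrack) -> np.ndarray:
    """(n, 2) nose–tail midpoint in pixels."""
    return 0.5 * (track.part("nose") + track.part("tail_base"))


def segment_strides(ap: np.ndarray, frame_rate: float, limb: str = REFERENCE_LIMB,
                    config: SegmentationConfig = SegmentationConfig()
                    ) -> list[Stride]:
    """Segment one limb's AP trajectory into strides.

    Stance onsets are local maxima (paw closest to the nose); the swing onset
    is the minimum between consecutive maxima; strides are the half-open
    intervals between consecutive maxima.  Candidate maxima are found on a
    zero-phase low-pass filtered copy and refined on the raw trajectory.
    """
    ap = np.asarray(ap, dtype=float)
    n = len(ap)
    if n < 3:
        warnings.warn("trajectory too short to segment strides")
        return []
    nyq = frame_rate / 2.0
    if config.lowpass_hz < nyq:
        b, a = signal.butter(4, config.lowpass_hz / nyq)
        filt = signal.filtfilt(b, a, ap)
    else:
        filt = ap
    rng_range = float(np.nanmax(filt) - np.nanmin(filt))
    if rng_range <= 0:
        warnings.warn("constant trajectory: no strides")
        return []
    distance = max(1, int(round(config.min_separation_s * frame_rate)))
    peaks, _ = signal.find_peaks(filt, distance=distance,
                                 prominence=config.min_prominence_frac * rng_range)
    if len(peaks) < 2:
        warnings.warn(f"fewer than 2 stance onsets found for {limb}")
        return []
    # refine each maximum on the unfiltered trajectory
    half = max(1, distance // 2)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        refined.append(lo + int(np.nanargmax(ap[lo:hi])))
    refined = sorted(set(refined))
    # the paw dwells near its extremes (end of swing decelerates into stance;
    # the planted paw leaves the minimum slowly), so argmax/argmin drift into
    # the flat side of each extremum; anchor events to the steep side instead
    tol = config.plateau_tol_frac * rng_range
    onsets = []
    for i, m in enumerate(refined):
        limit = refined[i + 1] if i + 1 < len(refined) else n
        j = m
        while j + 1 < limit and ap[j + 1] >= ap[m] - tol:
            j += 1
        onsets.append(j)
    onsets = sorted(set(onsets))
    strides = []
    for m0, m1 in zip(onsets[:-1], onsets[1:]):
        if m1 - m0 < 2:
            continue
        k = m0 + 1 + int(np.nanargmin(ap[m0 + 1:m1]))
        vmin = ap[k]
        while k - 1 > m0 and ap[k - 1] <= vmin + tol:
            k -= 1
        strides.append(Stride(limb=limb, stance_onset=m0, swing_onset=k,
                              next_stance_onset=m1))
    return strides


def segment_all_limbs(ap: pd.DataFrame, frame_rate: float,
                      config: SegmentationConfig = SegmentationConfig()
                      ) -> dict[str, list[Stride]]:
    """Apply the identical segmentation to every limb."""
    return {limb: segment_strides(ap[limb].to_numpy(), frame_rate, limb, config)
            for limb in LIMBS}


def compute_stride_metrics(strides: list[Stride], track: PoseTrack) -> pd.DataFrame:
    """Per-stride gait metrics.

    cadence = 1/stride duration; stride_length = arena-frame paw displacement
    between consecutive stance onsets (mm); stance_fraction = stance duration
    over stride duration; walking_speed = arena-frame body-midpoint
    displacement over the stride duration (mm/s).
    """
    if not strides:
        raise DataIntegrityError("empty stride list")
    mid = body_midpoint(track)
    rows = []
    for s in strides:
        n_frames = s.next_stance_onset - s.stance_onset
        if n_frames <= 0:
            raise DataIntegrityError("zero-duration stride")
        dur = n_frames / track.frame_rate
        paw = track.part(s.limb)
        length = float(np.linalg.norm(paw[s.next_stance_onset] - paw[s.stance_onset])
                       ) / track.px_per_mm
        stance_fraction = (s.swing_onset - s.stance_onset) / n_frames
        speed = float(np.linalg.norm(mid[s.next_stance_onset] - mid[s.stance_onset])
                      ) / track.px_per_mm / dur
        rows.append({"limb": s.limb, "stance_onset": s.stance_onset,
                     "cadence": 1.0 / dur, "stride_length": length,
                     "stance_fraction": stance_fraction,
                     "swing_fraction": 1.0 - stance_fraction,
                     "walking_speed": speed, "duration_s": dur})
    return pd.DataFrame(rows)


def compute_phase_samples(strides_by_limb: dict[str, list[Stride]],
                          frame_rate: float) -> pd.DataFrame:
    """Circular phase of each limb's stance onset within the LF stride.

    For each reference (LF) stride, the phase of limb L is
    2*pi*(t_stance(L) - t_stance(LF)) / LF stride duration, wrapped to
    [0, 2*pi), using the first stance onset of L at or after the LF onset.
    Limbs with no stance onset inside an LF stride are skipped.
    """
    ref = strides_by_limb.get(REFERENCE_LIMB, [])
    rows = []
    for i, rs in enumerate(ref):
        t0 = rs.stance_onset / frame_rate
        t1 = rs.next_stance_onset / frame_rate
        dur = t1 - t0
        for limb in NON_REFERENCE_LIMBS:
            onsets = [s.stance_onset / frame_rate for s in strides_by_limb.get(limb, [])]
            cand = [t for t in onsets if t0 <= t < t1]
            if not cand:
                continue
            phase = (2.0 * math.pi * (cand[0] - t0) / dur) % (2.0 * math.pi)
            rows.append({"stride_index": i, "limb": limb, "phase": phase,
                         "stride_duration": dur})
    return pd.DataFrame(rows, columns=["stride_index", "limb", "phase",
                                       "stride_duration"])


def circular_sd(phases: np.ndarray, formula: str = "sqrt_neg2lnR") -> float:
    """Circular standard deviation of angles (radians).

    Default sqrt(-2 ln Rbar); the angular deviation sqrt(2(1-Rbar)) is
    available as an alternative.  Rbar = 0 (uniform phases) returns +inf.
    """
    phases = np.asarray(phases, dtype=float)
    if len(phases) == 0:
        raise DataIntegrityError("no phases")
    rbar = min(float(np.abs(np.mean(np.exp(1j * phases)))), 1.0)
    if rbar < 1e-12:
        warnings.warn("mean resultant length is 0; circular SD is infinite")
        return math.inf
    if formula == "sqrt_neg2lnR":
        return math.sqrt(max(-2.0 * math.log(rbar), 0.0))
    if formula == "angular_deviation":
        return math.sqrt(2.0 * (1.0 - rbar))
    raise ValueError(f"unknown circular SD formula {formula!r}")


def stepping_variability(samples: pd.DataFrame,
                         formula: str = "sqrt_neg2lnR") -> SteppingVariability:
    """Per-limb circular SD of stance phases, averaged across the three limbs."""
    per_limb = {}
    for limb in NON_REFERENCE_LIMBS:
        ph = samples.loc[samples["limb"] == limb, "phase"].to_numpy()
        if len(ph) < 2:
            continue
        per_limb[limb] = circular_sd(ph, formula)
    if not per_limb:
        raise DataIntegrityError("need >= 2 phase samples for at least one limb")
    return SteppingVariability(per_limb=per_limb,
                               mean=float(np.mean(list(per_limb.values()))))


def find_straight_runs(track: PoseTrack, window_s: float = 0.5,
                       heading_sd_max_deg: float = 15.0,
                       min_speed_mm_s: float = 50.0,
                       min_duration_s: float = 0.7) -> list[StraightRun]:
    """Automatically isolate straight, sustained walking bouts.

    A frame is accepted when, over a centered window, the heading circular SD
    is below ``heading_sd_max_deg`` and the body-midpoint speed exceeds
    ``min_speed_mm_s``; contiguous accepted stretches of at least
    ``min_duration_s`` become runs.  A manual run-annotation table, when
    supplied to the pipeline, overrides this criterion.
    """
    mid = body_midpoint(track) / track.px_per_mm  # mm
    n = len(mid)
    if n < 3:
        return []
    w = max(3, int(round(window_s * track.frame_rate)) | 1)
    vel = np.gradient(mid, 1.0 / track.frame_rate, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    heading = np.arctan2(vel[:, 1], vel[:, 0])
    kernel = np.ones(w) / w
    c = np.convolve(np.cos(heading), kernel, mode="same")
    s = np.convolve(np.sin(heading), kernel, mode="same")
    rbar = np.hypot(c, s)
    with np.errstate(divide="ignore"):
        head_sd = np.degrees(np.sqrt(np.maximum(-2.0 * np.log(np.clip(rbar, 1e-12, 1.0)), 0.0)))
    smooth_speed = np.convolve(speed, kernel, mode="same")
    good = (head_sd < heading_sd_max_deg) & (smooth_speed > min_speed_mm_s)
    runs = []
    i = 0
    min_len = int(round(min_duration_s * track.frame_rate))
    while i < n:
        if good[i]:
            j = i
            while j < n and good[j]:
                j += 1
            if j - i >= min_len:
                runs.append(StraightRun(
                    start_frame=i, end_frame=j - 1,
                    mean_heading=float(np.arctan2(np.mean(np.sin(heading[i:j])),
                                                  np.mean(np.cos(heading[i:j])))),
                    mean_speed=float(np.mean(speed[i:j]))))
            i = j
        else:
            i += 1
    return runs


def crop_track(track: PoseTrack, start: int, end: int) -> PoseTrack:
    data = track.data.iloc[start:end + 1].reset_index(drop=True)
    return PoseTrack(data=data, frame_rate=track.frame_rate,
                     px_per_mm=track.px_per_mm)


@dataclass
class GaitAnalysis:
    metrics: pd.DataFrame          # one row per stride (all limbs)
    phase_samples: pd.DataFrame
    variability: SteppingVariability
    summary: dict[str, float]      # stride-weighted per-animal means


def analyze_track(track: PoseTrack,
                  runs: list[StraightRun] | None = None,
                  config: SegmentationConfig = SegmentationConfig(),
                  sd_formula: str = "sqrt_neg2lnR") -> GaitAnalysis:
    """Full gait analysis of one pose track.

    When ``runs`` is None the whole track is treated as a single run (the
    synthetic generator emits clean straight traverses); otherwise each run is
    segmented independently and per-stride results are pooled.
    """
    track = interpolate_low_likelihood(track, config)
    if runs is None:
        runs = [StraightRun(0, track.n_frames - 1, 0.0, 0.0)]
    all_metrics, all_phases = [], []
    offset = 0
    for run in runs:
        sub = crop_track(track, run.start_frame, run.end_frame)
        ap = normalize_to_body_axis(sub)
        strides_by_limb = segment_all_limbs(ap, sub.frame_rate, config)
        strides_flat = [s for ss in strides_by_limb.values() for s in ss]
        if not strides_flat:
            continue
        all_metrics.append(compute_stride_metrics(strides_flat, sub))
        ph = compute_phase_samples(strides_by_limb, sub.frame_rate)
        if len(ph):
            ph = ph.assign(stride_index=ph["stride_index"] + offset)
            offset = int(ph["stride_index"].max()) + 1
            all_phases.append(ph)
    if not all_metrics:
        raise DataIntegrityError("no strides found in any run")
    metrics = pd.concat(all_metrics, ignore_index=True)
    phases = (pd.concat(all_phases, ignore_index=True) if all_phases
              else pd.DataFrame(columns=["stride_index", "limb", "phase",
                                         "stride_duration"]))
    variability = stepping_variability(phases, sd_formula)
    summary = {
        "cadence": float(metrics["cadence"].mean()),
        "stride_length": float(metrics["stride_length"].mean()),
        "stance_fraction": float(metrics["stance_fraction"].mean()),
        "swing_fraction": float(metrics["swing_fraction"].mean()),
        "walking_speed": float(metrics["walking_speed"].mean()),
        "stepping_variability": variability.mean,
        "n_strides": float(len(metrics)),
    }
    return GaitAnalysis(metrics=metrics, phase_samples=phases,
                        variability=variability, summary=summary)
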