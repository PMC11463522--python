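"""Eye-trace calibration, OKR gain, saccade detection and main-sequence fits.

Conventions: the left eye is recorded; azimuth is positive toward the nose
(nasal), elevation positive upward (dorsal).  Rapid eye movements — whether
spontaneous saccades or the resetting quick phases of optokinetic nystagmus —
are detected with a two-threshold scheme: candidate intervals are bounded by a
low onset/offset velocity threshold, then accepted against the per-axis
amplitude and peak-velocity minima (horizontal 3 deg / 100 deg/s, vertical
1 deg / 100 deg/s).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import (DIRECTION_AXIS, DIRECTION_SIGN, OPPOSITE_DIRECTION,
                    Epoch, EyeTrace, StimulusSchedule)

CALIBRATION_ROTATION_DEG = 10.0

#: per-axis (min_amplitude deg, min_velocity deg/s) acceptance thresholds
DEFAULT_THRESHOLDS = {"horizontal": (3.0, 100.0), "vertical": (1.0, 100.0)}


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Pupil-displacement-to-angle model anchored on the corneal reflection.

    ``rotation_radius_px`` is the effective radius Rp such that a rotation by
    angle a displaces the CR-referenced pupil center by Rp * sin(a) pixels.
    """

    rotation_radius_px: float

    def __post_init__(self):
        if not (self.rotation_radius_px > 0):
            raise ValueError("rotation radius must be > 0")


def calibrate(rotation_displacements_px: np.ndarray,
              rotation_deg: float = CALIBRATION_ROTATION_DEG) -> CalibrationModel:
    """Fit the rotation radius from camera-rotation measurements.

    Each measurement is the pixel displacement of (pupil - CR) produced by
    rotating the camera by ``rotation_deg``; Rp = mean |displacement| /
    sin(rotation).
    """
    d = np.abs(np.asarray(rotation_displacements_px, dtype=float))
    if d.size == 0:
        raise InsufficientDataError("need at least one rotation measurement")
    return CalibrationModel(rotation_radius_px=float(d.mean())
                            / math.sin(math.radians(rotation_deg)))


def angular_position(delta_px: np.ndarray, model: CalibrationModel
                     ) -> tuple[np.ndarray, np.ndarray]:
    """CR-referenced pupil displacement (px) -> eye angle (deg).

    angle = arcsin(delta / Rp).  Displacements beyond Rp are clipped to
    +/-90 deg and flagged in the returned boolean mask.
    """
    ratio = np.asarray(delta_px, dtype=float) / model.rotation_radius_px
    clipped = np.abs(ratio) > 1.0
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} samples exceed the rotation radius; "
                      "clipped to +/-90 deg")
    return np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0))), clipped


# ---------------------------------------------------------------------------
# Velocity and saccade detection
# ---------------------------------------------------------------------------

def estimate_velocity(position: np.ndarray, sample_rate: float,
                      smooth_window_s: float = 0.010) -> np.ndarray:
    """Central-difference velocity after a short moving-average smooth.

    The 10 ms default window resolves 20 ms events at both 130 and 200 Hz.
    """
    pos = np.asarray(position, dtype=float)
    w = max(1, int(round(smooth_window_s * sample_rate)))
    if w > 1:
        kernel = np.ones(w) / w
        pos = np.convolve(pos, kernel, mode="same")
    return np.gradient(pos, 1.0 / sample_rate)


def supra_threshold_intervals(velocity: np.ndarray, threshold: float
                              ) -> list[tuple[int, int]]:
    """Maximal index intervals [i0, i1] where |velocity| > threshold."""
    above = np.abs(np.asarray(velocity)) > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above) - 1)
    return list(zip(starts, stops))


@dataclass(frozen=True)
class SaccadeEvent:
    onset_t: float
    offset_t: float
    amplitude: float      # deg, signed (sign encodes direction on the axis)
    peak_velocity: float  # deg/s, > 0
    axis: str             # horizontal | vertical
    direction: str        # nasal | temporal | dorsal | ventral

    def __post_init__(self):
        if not self.offset_t > self.onset_t:
            raise ValueError("offset must follow onset")


def _direction(axis: str, amplitude: float) -> str:
    if axis == "horizontal":
        return "nasal" if amplitude > 0 else "temporal"
    return "dorsal" if amplitude > 0 else "ventral"


def detect_saccades(trace: EyeTrace, axis: str = "horizontal",
                    min_amplitude: float | None = None,
                    min_velocity: float | None = None,
                    onset_threshold: float = 30.0,
                    merge_gap_s: float = 0.020,
                    smooth_window_s: float = 0.010,
                    amplitude_pad_s: float = 0.010) -> list[SaccadeEvent]:
    """Detect rapid eye movements on one axis.

    Candidates are maximal intervals with |velocity| above
    ``onset_threshold``; candidates closer than ``merge_gap_s`` are merged
    (differentiation noise can split one event).  A candidate is kept iff its
    position change from onset to offset is at least ``min_amplitude`` in
    magnitude AND its peak |velocity| is at least ``min_velocity``.

    Amplitude is measured between positions ``amplitude_pad_s`` before the
    onset crossing and after the offset crossing (the pre/post-movement rest
    positions): the sub-threshold velocity tails carry real displacement that
    the crossings alone would truncate at these sample rates.
    """
    if axis not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown axis {axis!r}")
    d_amp, d_vel = DEFAULT_THRESHOLDS[axis]
    min_amplitude = d_amp if min_amplitude is None else min_amplitude
    min_velocity = d_vel if min_velocity is None else min_velocity
    if min_amplitude <= 0 or min_velocity <= 0:
        raise ValueError("thresholds must be > 0")
    if trace.sample_rate < 100:
        warnings.warn("sample rate below 100 Hz cannot resolve 20 ms events")

    pos = trace.azimuth if axis == "horizontal" else trace.elevation
    vel = estimate_velocity(pos, trace.sample_rate, smooth_window_s)
    intervals = supra_threshold_intervals(vel, onset_threshold)
    if not intervals:
        return []
    # merge events split by brief sub-threshold dips
    gap = merge_gap_s * trace.sample_rate
    merged = [list(intervals[0])]
    for i0, i1 in intervals[1:]:
        if i0 - merged[-1][1] < gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    pad = max(1, int(round(amplitude_pad_s * trace.sample_rate)))
    n = len(pos)
    events = []
    for k, (i0, i1) in enumerate(merged):
        # pad up to the neighboring candidate, never past it
        lo = max(0, i0 - pad, merged[k - 1][1] + 1 if k > 0 else 0)
        hi = min(n - 1, i1 + pad,
                 merged[k + 1][0] - 1 if k + 1 < len(merged) else n - 1)
        amp = float(pos[hi] - pos[lo])
        pv = float(np.max(np.abs(vel[i0:i1 + 1])))
        if abs(amp) >= min_amplitude and pv >= min_velocity:
            events.append(SaccadeEvent(
                onset_t=float(trace.time[i0]), offset_t=float(trace.time[i1]),
                amplitude=amp, peak_velocity=pv, axis=axis,
                direction=_direction(axis, amp)))
    return events


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events],
                        columns=["onset_t", "offset_t", "amplitude",
                                 "peak_velocity", "axis", "direction"])


# ---------------------------------------------------------------------------
# OKR gain
# ---------------------------------------------------------------------------

def _overlaps(event: SaccadeEvent, epoch: Epoch) -> bool:
    return event.onset_t < epoch.stop and event.offset_t > epoch.start


def compute_okr_gain(trace: EyeTrace, schedule: StimulusSchedule,
                     events: list[SaccadeEvent] | None = None,
                     estimator: str = "position"
                     ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-cycle OKR gain for the oscillating-drum assay.

    Trials (moving epochs) overlapping any detected saccade are excluded
    entirely.  Remaining trials are divided into whole sinusoidal cycles;
    per-cycle gain is the eye peak-to-peak over the drum peak-to-peak
    (``estimator='position'``, the default), or the analogous velocity
    peak-to-peak ratio (``estimator='velocity'``).  Returns the mean gain per
    oscillation frequency and the per-cycle table.
    """
    if schedule.assay != "oscillating_drum":
        raise ValueError("compute_okr_gain requires the oscillating_drum assay")
    if estimator not in ("position", "velocity"):
        raise ValueError(f"unknown gain estimator {estimator!r}")
    events = events or []
    vel = (estimate_velocity(trace.azimuth, trace.sample_rate)
           if estimator == "velocity" else None)
    rows = []
    for ti, epoch in enumerate(schedule.moving_epochs()):
        freq, amp = epoch.frequency, epoch.amplitude
        contaminated = any(_overlaps(e, epoch) for e in events)
        n_cycles = int(math.floor(epoch.duration * freq))
        for c in range(n_cycles):
            c0 = epoch.start + c / freq
            c1 = c0 + 1.0 / freq
            m = (trace.time >= c0) & (trace.time < c1)
            if contaminated or not m.any():
                rows.append({"trial": ti, "frequency": freq, "cycle": c,
                             "gain": np.nan, "excluded": True,
                             "reason": "saccade in trial" if contaminated
                             else "no samples"})
                continue
            if estimator == "position":
                eye_pp = float(np.max(trace.azimuth[m]) - np.min(trace.azimuth[m]))
                gain = eye_pp / (2.0 * amp)
            else:
                eye_vpp = float(np.max(vel[m]) - np.min(vel[m]))
                gain = eye_vpp / (2.0 * (2.0 * math.pi * freq * amp))
            rows.append({"trial": ti, "frequency": freq, "cycle": c,
                         "gain": gain, "excluded": False, "reason": ""})
    cycles = pd.DataFrame(rows, columns=["trial", "frequency", "cycle", "gain",
                                         "excluded", "reason"])
    retained = cycles.loc[~cycles["excluded"]]
    all_freqs = sorted({e.frequency for e in schedule.moving_epochs()})
    mean_gain = retained.groupby("frequency")["gain"].mean().reindex(all_freqs)
    if mean_gain.isna().any():
        warnings.warn("all trials excluded at some frequency; gain missing there")
    return mean_gain, cycles


def compute_slow_phase_gain(trace: EyeTrace, schedule: StimulusSchedule,
                            events: list[SaccadeEvent],
                            excise_pad_s: float = 0.025) -> pd.Series:
    """Per-direction slow-phase gain for the unidirectional dome assay.

    Within each moving epoch, quick-phase intervals (padded by
    ``excise_pad_s``) are excised; the slow-phase velocity is the median of
    the smoothed eye velocity over the remaining samples, and gain is that
    velocity over the signed stimulus velocity.  Epochs fully consumed by
    excision yield a missing value.
    """
    if schedule.assay != "unidirectional_dome":
        raise ValueError("requires the unidirectional_dome assay")
    vel_cache: dict[str, np.ndarray] = {}
    per_dir: dict[str, list[float]] = {}
    for epoch in schedule.moving_epochs():
        d = epoch.direction
        axis = DIRECTION_AXIS[d]
        if axis not in vel_cache:
            pos = trace.azimuth if axis == "horizontal" else trace.elevation
            vel_cache[axis] = estimate_velocity(pos, trace.sample_rate)
        vel = vel_cache[axis]
        m = (trace.time >= epoch.start) & (trace.time < epoch.stop)
        for e in events:
            if e.axis == axis and _overlaps(e, epoch):
                m &= ~((trace.time >= e.onset_t - excise_pad_s)
                       & (trace.time <= e.offset_t + excise_pad_s))
        if not m.any():
            warnings.warn(f"epoch at {epoch.start}s fully excised")
            per_dir.setdefault(d, []).append(np.nan)
            continue
        slow_v = float(np.median(vel[m]))
        gain = slow_v / (DIRECTION_SIGN[d] * epoch.speed)
        if gain < 0:
            warnings.warn(f"slow phase opposes stimulus in {d} epoch")
        per_dir.setdefault(d, []).append(gain)
    return pd.Series({d: float(np.nanmean(v)) for d, v in per_dir.items()},
                     dtype=float).sort_index()


# ---------------------------------------------------------------------------
# Main sequence and quick-phase frequency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MainSequenceFit:
    slope: float           # 1/s
    intercept: float       # deg/s
    r_squared: float
    slope_ci: tuple[float, float]  # 95% CI
    n: int


def fit_main_sequence(events: list[SaccadeEvent]) -> MainSequenceFit:
    """OLS of peak velocity on |amplitude| with a 95% CI on the slope."""
    if len(events) < 3:
        raise InsufficientDataError("main-sequence fit needs >= 3 events")
    x = np.array([abs(e.amplitude) for e in events])
    y = np.array([e.peak_velocity for e in events])
    if np.ptp(x) == 0:
        raise InsufficientDataError("all amplitudes identical; fit is singular")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(events) - 2)
    return MainSequenceFit(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue ** 2),
                           slope_ci=(float(res.slope - tcrit * res.stderr),
                                     float(res.slope + tcrit * res.stderr)),
                           n=len(events))


@dataclass(frozen=True)
class QuickPhaseFrequency:
    direction: str            # of the quick phases themselves
    events_per_second: float
    total_moving_time: float
    n_events: int


def quick_phase_frequency(events: list[SaccadeEvent],
                          schedule: StimulusSchedule) -> dict[str, QuickPhaseFrequency]:
    """Directional resetting-saccade frequency during dome stimulation.

    For each stimulus direction, counts the detected events inside its moving
    epochs whose direction opposes the slow phase (i.e. equals the resetting
    direction), divided by the summed moving time.  Keyed by the quick-phase
    direction.
    """
    if schedule.assay != "unidirectional_dome":
        raise ValueError("requires the unidirectional_dome assay")
    out: dict[str, QuickPhaseFrequency] = {}
    by_stim: dict[str, list[Epoch]] = {}
    for epoch in schedule.moving_epochs():
        by_stim.setdefault(epoch.direction, []).append(epoch)
    for stim_dir, epochs in by_stim.items():
        total = sum(e.duration for e in epochs)
        if total <= 0:
            raise ValueError(f"zero moving time for stimulus {stim_dir}")
        reset_dir = OPPOSITE_DIRECTION[stim_dir]
        count = sum(1 for e in events
                    if e.direction == reset_dir
                    and any(ep.start <= e.onset_t < ep.stop for ep in epochs))
        out[reset_dir] = QuickPhaseFrequency(direction=reset_dir,
                                             events_per_second=count / total,
                                             total_moving_time=total,
                                             n_events=count)
    return out
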