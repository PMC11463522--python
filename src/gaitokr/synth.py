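"""Synthetic gait tracks, eye traces and pathology tables with known ground truth.

Every generator is a deterministic function of its parameter set (including
the seed), so downstream segmentation, detection and correlation stages can be
validated against the exact injected values.  All kinematic quantities are in
physical units (mm, deg, s); the pose writer converts to pixels via
``px_per_mm``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LIMBS = ("LF", "RF", "LH", "RH")
NON_REFERENCE_LIMBS = ("RF", "LH", "RH")
BODY_PARTS = LIMBS + ("nose", "tail_base")

#: direction that a resetting quick phase takes, given the stimulus direction
OPPOSITE_DIRECTION = {
    "temporal": "nasal",
    "nasal": "temporal",
    "dorsal": "ventral",
    "ventral": "dorsal",
}

#: sign of stimulus/eye motion on its axis (azimuth: + nasal; elevation: + dorsal)
DIRECTION_SIGN = {"nasal": 1.0, "temporal": -1.0, "dorsal": 1.0, "ventral": -1.0}
DIRECTION_AXIS = {
    "nasal": "horizontal",
    "temporal": "horizontal",
    "dorsal": "vertical",
    "ventral": "vertical",
}


class ParameterError(ValueError):
    """A simulation parameter is non-finite or out of range."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]: 10u^3 - 15u^4 + 6u^5."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


# peak of d/du minimum_jerk(u) — so a step of amplitude A over duration D has
# peak velocity MINJERK_PEAK_FACTOR * A / D
MINJERK_PEAK_FACTOR = 1.875


# ---------------------------------------------------------------------------
# Gait
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitSimParams:
    """Parameters of the simulated linear-track walk.

    The body-frame anteroposterior (AP) waveform of each paw is a
    piecewise cycle: during stance the paw is planted in the arena, so in the
    body frame it drifts backward linearly; during swing it returns forward
    along a minimum-jerk profile.  Inter-limb timing is set by
    ``phase_offsets`` (radians relative to the left forelimb) jittered per
    stride by von Mises noise of concentration ``phase_noise_kappa``
    (``inf`` means noiseless).
    """

    n_strides: int = 20
    cadence: float = 3.0                 # strides/s
    stance_fraction: float = 0.6
    stride_length: float = 60.0          # mm, paw advance per cycle
    phase_offsets: tuple[float, float, float] = (math.pi, math.pi, 0.0)  # RF, LH, RH
    phase_noise_kappa: float = math.inf
    frame_rate: float = 60.0             # Hz
    coord_noise_sd: float = 0.0          # mm, i.i.d. Gaussian on every coordinate
    px_per_mm: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_strides >= 1, "n_strides must be >= 1")
        _require(np.isfinite(self.cadence) and self.cadence > 0, "cadence must be > 0")
        _require(0.0 < self.stance_fraction < 1.0, "stance_fraction must be in (0, 1)")
        _require(np.isfinite(self.stride_length) and self.stride_length > 0,
                 "stride_length must be > 0")
        _require(len(self.phase_offsets) == 3, "phase_offsets is (RF, LH, RH)")
        for off in self.phase_offsets:
            _require(0.0 <= off < 2.0 * math.pi, "phase offsets must lie in [0, 2pi)")
        _require(self.phase_noise_kappa > 0, "phase_noise_kappa must be > 0 (inf = none)")
        _require(self.frame_rate > 0, "frame_rate must be > 0")
        _require(self.coord_noise_sd >= 0, "coord_noise_sd must be >= 0")
        _require(self.px_per_mm > 0, "px_per_mm must be > 0")


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates, DeepLabCut-style.

    ``data`` has a two-level column index ``(bodypart, {'x','y','likelihood'})``
    with coordinates in pixels (image convention: origin top-left, y down).
    """

    data: pd.DataFrame
    frame_rate: float
    px_per_mm: float

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def part(self, name: str) -> np.ndarray:
        """(n, 2) pixel coordinates of one body part."""
        return self.data[name][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, name: str) -> np.ndarray:
        return self.data[(name, "likelihood")].to_numpy(dtype=float)


@dataclass
class GaitGroundTruth:
    """Injected gait parameters and exact per-stride event times."""

    params: GaitSimParams
    #: columns: limb, stride, stance_onset_t, swing_onset_t, next_stance_onset_t,
    #: stance_onset_frame, swing_onset_frame, next_stance_onset_frame, phase
    strides: pd.DataFrame
    #: body-frame AP coordinate (mm) per limb per frame, as commanded
    body_frame_ap: dict[str, np.ndarray]
    walking_speed: float  # mm/s


def _limb_onsets(params: GaitSimParams, offset: float, jitter: np.ndarray,
                 t_start: float) -> np.ndarray:
    """Stance-onset times for strides k = -1 .. n_strides+1 (padded)."""
    period = 1.0 / params.cadence
    k = np.arange(-1, params.n_strides + 2, dtype=float)
    frac = (offset + jitter) / (2.0 * math.pi)
    return t_start + (k + frac) * period


def _limb_waveform(t: np.ndarray, onsets: np.ndarray, amplitude: float,
                   stance_fraction: float) -> np.ndarray:
    """Evaluate the stance/swing AP cycle at times ``t`` given onset times."""
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 2)
    t0 = onsets[idx]
    dur = onsets[idx + 1] - t0
    u = (t - t0) / dur
    ap = np.empty_like(t)
    in_stance = u <= stance_fraction
    # stance: planted paw retreats linearly from +A/2 to -A/2 in the body frame
    ap[in_stance] = amplitude * (0.5 - u[in_stance] / stance_fraction)
    w = (u[~in_stance] - stance_fraction) / (1.0 - stance_fraction)
    ap[~in_stance] = amplitude * (minimum_jerk(w) - 0.5)
    return ap


def gen_gait_track(params: GaitSimParams) -> tuple[PoseTrack, GaitGroundTruth]:
    """Simulate a straight traverse of the linear track.

    Returns the pose table (six tracked parts, pixel coordinates, likelihood
    1.0) and the exact ground truth: per-stride stance/swing boundaries per
    limb and the commanded body-frame waveforms.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    period = 1.0 / params.cadence
    t_start = 0.35 * period
    t_end = t_start + params.n_strides * period + 0.35 * period
    times = np.arange(0.0, t_end, 1.0 / params.frame_rate)
    n = len(times)

    speed = params.cadence * params.stride_length          # mm/s
    amplitude = params.stride_length * params.stance_fraction  # body-frame AP range

    # per-limb stance-onset schedules; LF is the noiseless reference
    n_events = params.n_strides + 3
    onsets: dict[str, np.ndarray] = {
        "LF": _limb_onsets(params, 0.0, np.zeros(n_events), t_start)
    }
    jitters: dict[str, np.ndarray] = {"LF": np.zeros(n_events)}
    for limb, off in zip(NON_REFERENCE_LIMBS, params.phase_offsets):
        if math.isinf(params.phase_noise_kappa):
            jit = np.zeros(n_events)
        else:
            jit = rng.vonmises(0.0, params.phase_noise_kappa, size=n_events)
        jitters[limb] = jit
        onsets[limb] = _limb_onsets(params, off, jit, t_start)

    body_frame_ap = {
        limb: _limb_waveform(times, onsets[limb], amplitude, params.stance_fraction)
        for limb in LIMBS
    }

    # arena-frame layout (mm): body midpoint advances at the walking speed
    x_mid = 30.0 + speed * times
    home_ap = {"LF": 20.0, "RF": 20.0, "LH": -20.0, "RH": -20.0}
    lateral = {"LF": 22.0, "RF": 38.0, "LH": 22.0, "RH": 38.0}

    coords_mm: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        xy = np.column_stack([x_mid + home_ap[limb] + body_frame_ap[limb],
                              np.full(n, lateral[limb])])
        coords_mm[limb] = xy
    coords_mm["nose"] = np.column_stack([x_mid + 45.0, np.full(n, 30.0)])
    coords_mm["tail_base"] = np.column_stack([x_mid - 45.0, np.full(n, 30.0)])

    if params.coord_noise_sd > 0:
        for part in BODY_PARTS:
            coords_mm[part] = coords_mm[part] + rng.normal(
                0.0, params.coord_noise_sd, size=coords_mm[part].shape)

    columns = pd.MultiIndex.from_product([BODY_PARTS, ("x", "y", "likelihood")],
                                         names=["bodyparts", "coords"])
    data = pd.DataFrame(0.0, index=pd.RangeIndex(n), columns=columns)
    for part in BODY_PARTS:
        data[(part, "x")] = coords_mm[part][:, 0] * params.px_per_mm
        data[(part, "y")] = coords_mm[part][:, 1] * params.px_per_mm
        data[(part, "likelihood")] = 1.0
    track = PoseTrack(data=data, frame_rate=params.frame_rate,
                      px_per_mm=params.px_per_mm)

    records = []
    for limb in LIMBS:
        on = onsets[limb]
        offs = dict(zip(NON_REFERENCE_LIMBS, params.phase_offsets)).get(limb, 0.0)
        for k in range(len(on) - 1):
            t0, t1 = on[k], on[k + 1]
            if t0 < 0.0 or t1 > times[-1]:
                continue
            dur = t1 - t0
            t_swing = t0 + params.stance_fraction * dur
            records.append({
                "limb": limb,
                "stride": k - 1,
                "stance_onset_t": t0,
                "swing_onset_t": t_swing,
                "next_stance_onset_t": t1,
                "stance_onset_frame": int(round(t0 * params.frame_rate)),
                "swing_onset_frame": int(round(t_swing * params.frame_rate)),
                "next_stance_onset_frame": int(round(t1 * params.frame_rate)),
                "phase": (offs + jitters[limb][k]) % (2.0 * math.pi),
            })
    strides = pd.DataFrame.from_records(records).sort_values(
        ["limb", "stance_onset_t"]).reset_index(drop=True)

    gt = GaitGroundTruth(params=params, strides=strides,
                         body_frame_ap=body_frame_ap, walking_speed=speed)
    return track, gt


# ---------------------------------------------------------------------------
# Eye movements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeSimParams:
    """Parameters of a simulated eye-movement recording.

    Two assays are supported:

    ``oscillating_drum``
        Horizontal sinusoidal drum (default ±5 deg) presented in trials of
        10 s of motion flanked by 4 s of static grating; the eye tracks the
        drum at ``slow_phase_gain``.  ``quick_phase_rate`` here is the rate of
        spontaneous saccades (Poisson over the whole recording).
    ``unidirectional_dome``
        Full-field grating drifting at ``grating_speed`` in 6 epochs
        (5 s static / 30 s moving / 5 s static); the slow phase integrates
        ``slow_phase_gain`` x stimulus velocity and is interrupted by
        resetting quick phases opposing the stimulus, arriving as a thinned
        Poisson process at ``quick_phase_rate`` per second of motion.

    Every injected rapid eye movement is a minimum-jerk step whose duration is
    set by the commanded main-sequence law: peak velocity
    = ``main_sequence_slope`` x amplitude + ``main_sequence_intercept``.
    """

    assay: str = "oscillating_drum"
    # drum assay
    drum_amplitude: float = 5.0          # deg (oscillation is +/- this)
    oscillation_frequency: float = 0.4   # Hz
    n_trials: int = 15
    drum_static_s: float = 4.0
    drum_moving_s: float = 10.0
    # dome assay
    grating_speed: float = 10.0          # deg/s
    axis: str = "horizontal"             # which axis the dome session stimulates
    epoch_directions: tuple[str, ...] | None = None  # default: 3+3 alternating
    dome_static_s: float = 5.0
    dome_moving_s: float = 30.0
    # eye dynamics
    slow_phase_gain: float = 0.7
    quick_phase_rate: float = 0.0        # events/s (see class docstring)
    quick_phase_rate_by_direction: dict[str, float] | None = None  # dome override
    amplitude_range: tuple[float, float] = (3.0, 8.0)  # deg, uniform
    main_sequence_slope: float = 60.0    # 1/s
    main_sequence_intercept: float = 0.0  # deg/s
    min_event_separation_s: float = 0.1
    sample_rate: float | None = None     # default 200 (drum) / 130 (dome)
    position_noise_sd: float = 0.0       # deg
    seed: int = 0

    @property
    def resolved_sample_rate(self) -> float:
        if self.sample_rate is not None:
            return self.sample_rate
        return 200.0 if self.assay == "oscillating_drum" else 130.0

    def validate(self) -> None:
        if self.assay not in ("oscillating_drum", "unidirectional_dome"):
            raise ParameterError(f"unknown assay {self.assay!r}")
        _require(self.slow_phase_gain >= 0, "slow_phase_gain must be >= 0")
        _require(self.quick_phase_rate >= 0, "quick_phase_rate must be >= 0")
        _require(self.resolved_sample_rate > 0, "sample_rate must be > 0")
        _require(self.drum_amplitude > 0, "drum_amplitude must be > 0")
        _require(self.grating_speed > 0, "grating_speed must be > 0")
        _require(self.main_sequence_slope > 0, "main_sequence_slope must be > 0")
        _require(self.main_sequence_intercept >= 0,
                 "main_sequence_intercept must be >= 0")
        lo, hi = self.amplitude_range
        _require(0 < lo <= hi, "amplitude_range must satisfy 0 < lo <= hi")
        _require(self.position_noise_sd >= 0, "position_noise_sd must be >= 0")
        _require(self.axis in ("horizontal", "vertical"), "axis must be horizontal/vertical")


@dataclass
class EyeTrace:
    """Calibrated angular eye position on a uniform time grid (deg)."""

    time: np.ndarray
    azimuth: np.ndarray     # + nasal (left eye recorded)
    elevation: np.ndarray   # + dorsal
    sample_rate: float


@dataclass(frozen=True)
class Epoch:
    start: float
    stop: float
    moving: bool
    direction: str | None = None      # dome epochs
    speed: float | None = None        # deg/s, dome
    frequency: float | None = None    # Hz, drum
    amplitude: float | None = None    # deg, drum

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class StimulusSchedule:
    assay: str
    epochs: list[Epoch]

    def moving_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.moving]


@dataclass
class EyeGroundTruth:
    """Injected eye-trace parameters and the exact list of rapid events."""

    params: EyeSimParams
    #: columns: onset_t, offset_t, amplitude (signed deg), peak_velocity
    #: (deg/s), axis, direction, epoch (index into schedule.epochs, -1 if
    #: outside any moving epoch)
    events: pd.DataFrame
    drum_position: np.ndarray | None = None   # deg, drum assay only
    slow_phase_position: np.ndarray | None = None  # deg, dome assay


_EVENT_COLUMNS = ["onset_t", "offset_t", "amplitude", "peak_velocity",
                  "axis", "direction", "epoch"]


def _poisson_arrivals(rng: np.random.Generator, start: float, stop: float,
                      rate: float, min_sep: float) -> list[float]:
    """Poisson arrivals on [start, stop) thinned to a minimum separation."""
    if rate <= 0:
        return []
    t = start
    out: list[float] = []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= stop:
            return out
        if not out or t - out[-1] >= min_sep:
            out.append(t)


def _event_step(times: np.ndarray, onset: float, amplitude: float,
                duration: float) -> np.ndarray:
    """Signed minimum-jerk position step starting at ``onset``."""
    return amplitude * minimum_jerk((times - onset) / duration)


def _drum_trace(params: EyeSimParams, rng: np.random.Generator):
    fs = params.resolved_sample_rate
    trial_len = 2 * params.drum_static_s + params.drum_moving_s
    total = params.n_trials * trial_len + params.drum_static_s
    times = np.arange(0.0, total, 1.0 / fs)

    epochs: list[Epoch] = []
    drum = np.zeros_like(times)
    for i in range(params.n_trials):
        t0 = i * trial_len
        m0, m1 = t0 + params.drum_static_s, t0 + params.drum_static_s + params.drum_moving_s
        epochs.append(Epoch(t0, m0, moving=False))
        epochs.append(Epoch(m0, m1, moving=True,
                            frequency=params.oscillation_frequency,
                            amplitude=params.drum_amplitude))
        epochs.append(Epoch(m1, t0 + trial_len, moving=False))
    for e in epochs:
        if e.moving:
            m = (times >= e.start) & (times < e.stop)
            drum[m] = params.drum_amplitude * np.sin(
                2.0 * math.pi * params.oscillation_frequency * (times[m] - e.start))

    azimuth = params.slow_phase_gain * drum

    # spontaneous saccades anywhere in the recording
    records = []
    for onset in _poisson_arrivals(rng, 0.0, total, params.quick_phase_rate,
                                   params.min_event_separation_s):
        amp = rng.uniform(*params.amplitude_range) * rng.choice([-1.0, 1.0])
        vp = params.main_sequence_slope * abs(amp) + params.main_sequence_intercept
        dur = MINJERK_PEAK_FACTOR * abs(amp) / vp
        azimuth = azimuth + _event_step(times, onset, amp, dur)
        epoch_idx = next((j for j, e in enumerate(epochs)
                          if e.moving and e.start <= onset < e.stop), -1)
        records.append({"onset_t": onset, "offset_t": onset + dur,
                        "amplitude": amp, "peak_velocity": vp,
                        "axis": "horizontal",
                        "direction": "nasal" if amp > 0 else "temporal",
                        "epoch": epoch_idx})

    if params.position_noise_sd > 0:
        azimuth = azimuth + rng.normal(0, params.position_noise_sd, len(times))
    elevation = (rng.normal(0, params.position_noise_sd, len(times))
                 if params.position_noise_sd > 0 else np.zeros_like(times))

    trace = EyeTrace(times, azimuth, elevation, fs)
    schedule = StimulusSchedule("oscillating_drum", epochs)
    events = pd.DataFrame.from_records(records, columns=_EVENT_COLUMNS)
    gt = EyeGroundTruth(params=params, events=events.sort_values("onset_t",
                        ignore_index=True), drum_position=drum)
    return trace, schedule, gt


def _dome_trace(params: EyeSimParams, rng: np.random.Generator):
    fs = params.resolved_sample_rate
    if params.epoch_directions is not None:
        directions = params.epoch_directions
    elif params.axis == "vertical":
        directions = ("dorsal", "ventral") * 3
    else:
        directions = ("temporal", "nasal") * 3
    for d in directions:
        if d not in DIRECTION_SIGN:
            raise ParameterError(f"unknown stimulus direction {d!r}")

    epoch_len = 2 * params.dome_static_s + params.dome_moving_s
    total = len(directions) * epoch_len
    times = np.arange(0.0, total, 1.0 / fs)

    epochs: list[Epoch] = []
    stim_vel = np.zeros_like(times)
    for i, d in enumerate(directions):
        t0 = i * epoch_len
        m0, m1 = t0 + params.dome_static_s, t0 + params.dome_static_s + params.dome_moving_s
        epochs.append(Epoch(t0, m0, moving=False, direction=d))
        epochs.append(Epoch(m0, m1, moving=True, direction=d,
                            speed=params.grating_speed))
        epochs.append(Epoch(m1, t0 + epoch_len, moving=False, direction=d))
        m = (times >= m0) & (times < m1)
        stim_vel[m] = DIRECTION_SIGN[d] * params.grating_speed

    slow = np.cumsum(params.slow_phase_gain * stim_vel) / fs
    pos = slow.copy()

    rates = params.quick_phase_rate_by_direction or {}
    records = []
    for j, e in enumerate(epochs):
        if not e.moving:
            continue
        rate = rates.get(e.direction, params.quick_phase_rate)
        reset_sign = -DIRECTION_SIGN[e.direction]
        for onset in _poisson_arrivals(rng, e.start, e.stop, rate,
                                       params.min_event_separation_s):
            amp = reset_sign * rng.uniform(*params.amplitude_range)
            vp = params.main_sequence_slope * abs(amp) + params.main_sequence_intercept
            dur = MINJERK_PEAK_FACTOR * abs(amp) / vp
            pos = pos + _event_step(times, onset, amp, dur)
            axis = DIRECTION_AXIS[e.direction]
            direction = ("nasal" if amp > 0 else "temporal") if axis == "horizontal" \
                else ("dorsal" if amp > 0 else "ventral")
            records.append({"onset_t": onset, "offset_t": onset + dur,
                            "amplitude": amp, "peak_velocity": vp,
                            "axis": axis, "direction": direction, "epoch": j})

    noise = (rng.normal(0, params.position_noise_sd, len(times))
             if params.position_noise_sd > 0 else np.zeros_like(times))
    other = (rng.normal(0, params.position_noise_sd, len(times))
             if params.position_noise_sd > 0 else np.zeros_like(times))
    if params.axis == "vertical":
        trace = EyeTrace(times, other, pos + noise, fs)
    else:
        trace = EyeTrace(times, pos + noise, other, fs)
    schedule = StimulusSchedule("unidirectional_dome", epochs)
    events = pd.DataFrame.from_records(records, columns=_EVENT_COLUMNS)
    gt = EyeGroundTruth(params=params, events=events.sort_values("onset_t",
                        ignore_index=True), slow_phase_position=slow)
    return trace, schedule, gt


def gen_eye_trace(params: EyeSimParams) -> tuple[EyeTrace, StimulusSchedule, EyeGroundTruth]:
    """Simulate an eye-position recording for the configured assay."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    if params.assay == "oscillating_drum":
        return _drum_trace(params, rng)
    return _dome_trace(params, rng)


# ---------------------------------------------------------------------------
# Pathology / behavior tables
# ---------------------------------------------------------------------------

REGIONS = ("MCtx", "SCm", "ZI", "SNr", "STN", "CUN", "PPN", "VN", "DCN")


@dataclass
class PathologyGroundTruth:
    coupled_region: str
    behavior_measure: str
    slope: float
    noise_sd: float
    #: population Pearson r implied by slope, noise_sd and unit-variance covariate
    target_r: float
    behavior: pd.DataFrame


def gen_pathology_table(
    n_animals: int,
    regions: tuple[str, ...] = REGIONS,
    slope: float = -2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    coupled_region: str = "DCN",
    behavior_measure: str = "stepping_variability",
    behavior_values: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PathologyGroundTruth]:
    """Synthesize a per-animal region density table plus a behavior summary.

    One region's density is linearly coupled to the behavioral covariate
    (``density = base + slope * z + noise``, covariate standardized);
    remaining regions are independent draws.  Counts and areas are synthesized
    so that pooled density exactly reproduces the commanded density (counts
    are idealized real values, not integers).
    """
    if n_animals < 3:
        raise ParameterError("n_animals must be >= 3 (correlation undefined below)")
    if coupled_region not in regions:
        raise ParameterError(f"coupled_region {coupled_region!r} not in regions")
    rng = np.random.default_rng(seed)

    animals = [f"m{i:02d}" for i in range(n_animals)]
    if behavior_values is None:
        behavior_values = rng.normal(0.5, 0.15, n_animals)
    behavior_values = np.asarray(behavior_values, dtype=float)
    z = ((behavior_values - behavior_values.mean()) / behavior_values.std()
         if behavior_values.std() > 0 else np.zeros(n_animals))

    base = 5.0
    records = []
    for j, region in enumerate(regions):
        if region == coupled_region:
            # baseline scales with |slope| so densities stay non-negative
            # without clipping (clipping would break the exact linearity)
            dens = (base + 3.0 * abs(slope) + slope * z
                    + (rng.normal(0, noise_sd, n_animals)
                       if noise_sd > 0 else 0.0))
        else:
            dens = np.abs(rng.normal(base, 2.0, n_animals))
        dens = np.maximum(dens, 0.0) if region != coupled_region else dens
        for i, a in enumerate(animals):
            area = rng.uniform(2e4, 6e4)  # um^2 total over sections
            records.append({"animal_id": a, "region": region,
                            "at8_count": dens[i] * area / 1e4,
                            "area_um2": area, "density": dens[i]})
    density_table = pd.DataFrame.from_records(records)

    behavior = pd.DataFrame({"animal_id": animals,
                             behavior_measure: behavior_values})
    denom = math.hypot(slope, noise_sd)
    target_r = 0.0 if denom == 0 else slope / denom
    gt = PathologyGroundTruth(coupled_region=coupled_region,
                              behavior_measure=behavior_measure,
                              slope=slope, noise_sd=noise_sd,
                              target_r=target_r, behavior=behavior)
    return density_table, behavior, gt
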