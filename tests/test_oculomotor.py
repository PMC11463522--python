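"""Oculomotor stage: calibration, detection, gains, main sequence, frequencies."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitokr import oculomotor as om
from gaitokr.synth import (MINJERK_PEAK_FACTOR, Epoch, EyeSimParams, EyeTrace,
                           StimulusSchedule, gen_eye_trace, minimum_jerk)
from conftest import match_events


def make_trace(position, sample_rate=200.0, axis="horizontal") -> EyeTrace:
    position = np.asarray(position, dtype=float)
    t = np.arange(len(position)) / sample_rate
    zero = np.zeros_like(position)
    if axis == "horizontal":
        return EyeTrace(t, position, zero, sample_rate)
    return EyeTrace(t, zero, position, sample_rate)


def trace_with_events(specs, sample_rate=200.0, duration=None, axis="horizontal"):
    """Flat trace plus minimum-jerk steps; specs = [(onset, amp, peak_vel)]."""
    duration = duration or (max(s[0] for s in specs) + 1.0)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    pos = np.zeros_like(t)
    for onset, amp, pv in specs:
        d = MINJERK_PEAK_FACTOR * abs(amp) / pv
        pos = pos + amp * minimum_jerk((t - onset) / d)
    return make_trace(pos, sample_rate, axis)


class TestCalibration:
    def test_rotation_radius_from_displacement(self):
        # Rp = d / sin(10 deg) = 5.759 d
        model = om.calibrate(np.array([7.0]))
        assert model.rotation_radius_px == pytest.approx(7.0 * 5.7588, rel=1e-4)

    def test_calibration_inverts_to_ten_degrees(self):
        model = om.calibrate(np.array([12.0, 12.0]))
        delta = model.rotation_radius_px * math.sin(math.radians(10.0))
        ang, clipped = om.angular_position(np.array([delta]), model)
        assert ang[0] == pytest.approx(10.0, abs=1e-9)
        assert not clipped.any()

    def test_zero_displacement_is_zero_angle(self):
        model = om.calibrate(np.array([5.0]))
        ang, _ = om.angular_position(np.array([0.0]), model)
        assert ang[0] == 0.0

    def test_overrange_displacement_clipped_and_flagged(self):
        model = om.calibrate(np.array([5.0]))
        with pytest.warns(UserWarning):
            ang, clipped = om.angular_position(
                np.array([2 * model.rotation_radius_px]), model)
        assert ang[0] == pytest.approx(90.0)
        assert clipped[0]


class TestSaccadeDetection:
    def test_small_amplitude_rejected_horizontal(self):
        # 2 deg at 200 deg/s: fast enough but below the 3 deg floor
        tr = trace_with_events([(0.5, 2.0, 200.0)])
        assert om.detect_saccades(tr, axis="horizontal") == []

    def test_slow_event_rejected(self):
        # 4 deg at 80 deg/s peak: large enough but below 100 deg/s
        tr = trace_with_events([(0.5, 4.0, 80.0)])
        assert om.detect_saccades(tr, axis="horizontal") == []

    def test_constant_trace_yields_nothing(self):
        assert om.detect_saccades(make_trace(np.ones(1000))) == []

    def test_vertical_axis_uses_one_degree_floor(self):
        tr = trace_with_events([(0.5, 1.5, 150.0)], axis="vertical")
        events = om.detect_saccades(tr, axis="vertical")
        assert len(events) == 1
        assert events[0].direction == "dorsal"
        # same event is too small for the horizontal criterion
        tr_h = trace_with_events([(0.5, 1.5, 150.0)], axis="horizontal")
        assert om.detect_saccades(tr_h, axis="horizontal") == []

    def test_direction_follows_sign(self):
        tr = trace_with_events([(0.5, -5.0, 300.0)])
        (event,) = om.detect_saccades(tr, axis="horizontal")
        assert event.direction == "temporal"
        assert event.amplitude < 0
        assert event.peak_velocity > 0

    @pytest.mark.parametrize("sample_rate", [130.0, 200.0])
    def test_precision_recall_on_noisy_injected_events(self, sample_rate):
        params = EyeSimParams(assay="unidirectional_dome", axis="horizontal",
                              quick_phase_rate=0.3,
                              amplitude_range=(3.5, 8.0),
                              position_noise_sd=0.1,
                              sample_rate=sample_rate, seed=13)
        trace, _, gt = gen_eye_trace(params)
        events = om.detect_saccades(trace, axis="horizontal")
        tp, fp, fn = match_events([e.onset_t for e in events],
                                  gt.events.onset_t.to_numpy())
        assert len(gt.events) >= 30
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95

    def test_low_sample_rate_warns(self):
        tr = make_trace(np.zeros(500), sample_rate=60.0)
        with pytest.warns(UserWarning, match="100 Hz"):
            om.detect_saccades(tr)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_threshold_semantics_never_violated(self, seed):
        # no returned event may undercut its axis's minima, whatever the trace
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 0.3, 800))
        for k in range(rng.integers(0, 4)):
            onset = rng.uniform(0.2, 3.0)
            amp = rng.uniform(-6, 6)
            pv = rng.uniform(50, 400)
            t = np.arange(800) / 200.0
            d = MINJERK_PEAK_FACTOR * max(abs(amp), 1e-3) / pv
            pos = pos + amp * minimum_jerk((t - onset) / d)
        tr = make_trace(pos)
        for axis, (amin, vmin) in om.DEFAULT_THRESHOLDS.items():
            for e in om.detect_saccades(make_trace(pos, axis=axis), axis=axis):
                assert abs(e.amplitude) >= amin
                assert e.peak_velocity >= vmin

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_candidate_intervals_match_brute_force_scan(self, seed):
        # detector/oracle equivalence on short traces
        rng = np.random.default_rng(seed)
        vel = rng.normal(0, 40, rng.integers(50, 2000))
        got = om.supra_threshold_intervals(vel, 30.0)
        # brute force: enumerate maximal supra-threshold stretches sample by
        # sample
        expected = []
        i = 0
        while i < len(vel):
            if abs(vel[i]) > 30.0:
                j = i
                while j + 1 < len(vel) and abs(vel[j + 1]) > 30.0:
                    j += 1
                expected.append((i, j))
                i = j + 1
            else:
                i += 1
        assert got == expected


class TestOkrGain:
    def test_identity_tracking_gain_one(self, drum_identity):
        _, trace, schedule, _ = drum_identity
        mean_gain, _ = om.compute_okr_gain(trace, schedule, [])
        assert mean_gain[0.4] == pytest.approx(1.0, abs=1e-3)

    def test_scaled_tracking_gain(self):
        params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=0.35,
                              n_trials=4)
        trace, schedule, _ = gen_eye_trace(params)
        mean_gain, _ = om.compute_okr_gain(trace, schedule, [])
        assert mean_gain[0.4] == pytest.approx(0.35, abs=1e-3)

    def test_flat_eye_gain_zero(self):
        params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=0.0,
                              n_trials=3)
        trace, schedule, _ = gen_eye_trace(params)
        mean_gain, _ = om.compute_okr_gain(trace, schedule, [])
        assert mean_gain[0.4] == pytest.approx(0.0, abs=1e-9)

    def test_contaminated_trials_excluded_without_bias(self):
        params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=0.7,
                              n_trials=15, quick_phase_rate=0.04, seed=3)
        trace, schedule, _ = gen_eye_trace(params)
        events = om.detect_saccades(trace, axis="horizontal")
        assert events  # the generator did inject saccades
        mean_gain, cycles = om.compute_okr_gain(trace, schedule, events)
        assert cycles.excluded.any()
        assert mean_gain[0.4] == pytest.approx(0.7, abs=0.01)

    def test_exclusion_does_not_touch_other_trials(self, drum_identity):
        # adding a saccade inside one trial never changes gains computed from
        # the remaining trials
        _, trace, schedule, _ = drum_identity
        _, cycles_before = om.compute_okr_gain(trace, schedule, [])
        epoch = schedule.moving_epochs()[1]
        fake = om.SaccadeEvent(onset_t=epoch.start + 1.0,
                               offset_t=epoch.start + 1.05, amplitude=5.0,
                               peak_velocity=300.0, axis="horizontal",
                               direction="nasal")
        _, cycles_after = om.compute_okr_gain(trace, schedule, [fake])
        kept = cycles_after[cycles_after.trial != 1]
        ref = cycles_before[cycles_before.trial != 1]
        assert np.allclose(kept.gain.to_numpy(), ref.gain.to_numpy())
        assert cycles_after[cycles_after.trial == 1].excluded.all()

    @pytest.mark.parametrize("freq", [0.2, 0.4, 0.6, 0.8, 1.0])
    @pytest.mark.parametrize("alpha", [0.0, 0.35, 0.7, 1.0, 1.2])
    def test_gain_linearity_across_frequencies(self, freq, alpha):
        params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=alpha,
                              oscillation_frequency=freq, n_trials=2)
        trace, schedule, _ = gen_eye_trace(params)
        mean_gain, _ = om.compute_okr_gain(trace, schedule, [])
        assert mean_gain[freq] == pytest.approx(alpha, abs=0.005)

    def test_velocity_estimator_alternative(self, drum_identity):
        _, trace, schedule, _ = drum_identity
        mean_gain, _ = om.compute_okr_gain(trace, schedule, [],
                                           estimator="velocity")
        assert mean_gain[0.4] == pytest.approx(1.0, abs=0.05)


class TestSlowPhaseGain:
    def test_perfect_tracking_gain_one(self):
        params = EyeSimParams(assay="unidirectional_dome", axis="vertical",
                              slow_phase_gain=1.0, quick_phase_rate=0.0)
        trace, schedule, _ = gen_eye_trace(params)
        gains = om.compute_slow_phase_gain(trace, schedule, [])
        assert gains["dorsal"] == pytest.approx(1.0, abs=0.01)
        assert gains["ventral"] == pytest.approx(1.0, abs=0.01)

    def test_stationary_eye_gain_zero(self):
        params = EyeSimParams(assay="unidirectional_dome", axis="vertical",
                              slow_phase_gain=0.0, quick_phase_rate=0.0)
        trace, schedule, _ = gen_eye_trace(params)
        gains = om.compute_slow_phase_gain(trace, schedule, [])
        assert np.allclose(gains.to_numpy(), 0.0, atol=1e-9)

    def test_gain_recovered_with_quick_phases(self, dome_vertical):
        params, trace, schedule, _ = dome_vertical
        events = om.detect_saccades(trace, axis="vertical")
        gains = om.compute_slow_phase_gain(trace, schedule, events)
        for d in ("dorsal", "ventral"):
            assert gains[d] == pytest.approx(0.6, abs=0.05)


class TestMainSequence:
    def test_exact_linearity(self):
        events = [om.SaccadeEvent(onset_t=i * 1.0, offset_t=i * 1.0 + 0.03,
                                  amplitude=a, peak_velocity=10.0 * a,
                                  axis="horizontal", direction="nasal")
                  for i, a in enumerate([3.0, 4.0, 5.0, 6.5, 8.0])]
        fit = om.fit_main_sequence(events)
        assert fit.slope == pytest.approx(10.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_events_insufficient(self):
        events = [om.SaccadeEvent(onset_t=float(i), offset_t=i + 0.03,
                                  amplitude=3.0 + i, peak_velocity=200.0,
                                  axis="horizontal", direction="nasal")
                  for i in range(2)]
        with pytest.raises(om.InsufficientDataError):
            om.fit_main_sequence(events)

    def test_identical_amplitudes_singular(self):
        events = [om.SaccadeEvent(onset_t=float(i), offset_t=i + 0.03,
                                  amplitude=4.0, peak_velocity=200.0 + i,
                                  axis="horizontal", direction="nasal")
                  for i in range(5)]
        with pytest.raises(om.InsufficientDataError):
            om.fit_main_sequence(events)

    def test_ci_covers_injected_slope(self):
        # nominal 95% CI should cover the truth in >= 90/100 simulations
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            amps = rng.uniform(3.5, 8.0, 100)
            vels = 12.0 * amps + 50.0 + rng.normal(0, 10.0, 100)
            events = [om.SaccadeEvent(onset_t=float(i), offset_t=i + 0.03,
                                      amplitude=float(a),
                                      peak_velocity=float(v),
                                      axis="horizontal", direction="nasal")
                      for i, (a, v) in enumerate(zip(amps, vels))]
            fit = om.fit_main_sequence(events)
            if fit.slope_ci[0] <= 12.0 <= fit.slope_ci[1]:
                covered += 1
        assert covered >= 90


class TestQuickPhaseFrequency:
    def test_frequency_arithmetic(self):
        sched = StimulusSchedule("unidirectional_dome", [
            Epoch(0.0, 30.0, moving=True, direction="dorsal", speed=10.0)])
        events = [om.SaccadeEvent(onset_t=1.0 + i * 1.5,
                                  offset_t=1.03 + i * 1.5, amplitude=-2.0,
                                  peak_velocity=150.0, axis="vertical",
                                  direction="ventral") for i in range(15)]
        freqs = om.quick_phase_frequency(events, sched)
        assert freqs["ventral"].events_per_second == pytest.approx(0.5)

    def test_zero_events_zero_frequency(self):
        sched = StimulusSchedule("unidirectional_dome", [
            Epoch(0.0, 30.0, moving=True, direction="ventral", speed=10.0)])
        freqs = om.quick_phase_frequency([], sched)
        assert freqs["dorsal"].events_per_second == 0.0

    def test_only_resetting_direction_counted(self):
        # dorsal stimulus -> only ventral (downward) events are resetting
        sched = StimulusSchedule("unidirectional_dome", [
            Epoch(0.0, 30.0, moving=True, direction="dorsal", speed=10.0)])
        events = [
            om.SaccadeEvent(onset_t=1.0, offset_t=1.03, amplitude=-2.0,
                            peak_velocity=150.0, axis="vertical",
                            direction="ventral"),
            om.SaccadeEvent(onset_t=2.0, offset_t=2.03, amplitude=2.0,
                            peak_velocity=150.0, axis="vertical",
                            direction="dorsal"),
        ]
        freqs = om.quick_phase_frequency(events, sched)
        assert freqs["ventral"].n_events == 1

    def test_recovered_rate_within_poisson_band(self):
        params = EyeSimParams(assay="unidirectional_dome", axis="vertical",
                              slow_phase_gain=0.6, quick_phase_rate=0.3,
                              amplitude_range=(2.0, 5.0), seed=17)
        trace, schedule, gt = gen_eye_trace(params)
        events = om.detect_saccades(trace, axis="vertical")
        freqs = om.quick_phase_frequency(events, schedule)
        for d in ("dorsal", "ventral"):
            # 95% Poisson band around 0.3/s over 90 s of motion
            lo = (0.3 * 90 - 1.96 * math.sqrt(0.3 * 90)) / 90
            hi = (0.3 * 90 + 1.96 * math.sqrt(0.3 * 90)) / 90
            assert lo <= freqs[d].events_per_second <= hi

    def test_detected_resetting_direction_bookkeeping(self, dome_vertical):
        # direction of detected events opposes the slow phase on synthetic data
        params, trace, schedule, gt = dome_vertical
        events = om.detect_saccades(trace, axis="vertical")
        assert events
        for e in events:
            epoch = next((ep for ep in schedule.moving_epochs()
                          if ep.start <= e.onset_t < ep.stop), None)
            if epoch is None:
                continue
            assert e.direction != epoch.direction
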