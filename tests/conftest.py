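import math

import numpy as np
import pytest

from gaitokr.synth import (EyeSimParams, GaitSimParams, gen_eye_trace,
                           gen_gait_track)


@pytest.fixture(scope="session")
def clean_gait():
    """Noiseless trot at 3 strides/s: exact ground truth for segmentation."""
    params = GaitSimParams(n_strides=10, cadence=3.0, stance_fraction=0.6,
                           stride_length=60.0,
                           phase_noise_kappa=math.inf, coord_noise_sd=0.0,
                           seed=0)
    track, gt = gen_gait_track(params)
    return params, track, gt


@pytest.fixture(scope="session")
def drum_identity():
    """Eye trace identical to the drum (gain 1, no saccades, no noise)."""
    params = EyeSimParams(assay="oscillating_drum", slow_phase_gain=1.0,
                          n_trials=4, oscillation_frequency=0.4, seed=0)
    return (params,) + gen_eye_trace(params)


@pytest.fixture(scope="session")
def dome_vertical():
    """Vertical dome session with resetting quick phases."""
    params = EyeSimParams(assay="unidirectional_dome", axis="vertical",
                          slow_phase_gain=0.6, quick_phase_rate=0.4,
                          amplitude_range=(2.0, 5.0), position_noise_sd=0.05,
                          seed=7)
    return (params,) + gen_eye_trace(params)


def match_events(detected_onsets: np.ndarray, injected_onsets: np.ndarray,
                 tol_s: float = 0.025) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to injected events by onset time.

    Returns (true positives, false positives, false negatives).
    """
    detected = sorted(detected_onsets)
    remaining = list(sorted(injected_onsets))
    tp = 0
    for t in detected:
        hit = next((i for i, g in enumerate(remaining) if abs(g - t) <= tol_s),
                   None)
        if hit is not None:
            remaining.pop(hit)
            tp += 1
    fp = len(detected) - tp
    fn = len(remaining)
    return tp, fp, fn
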