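import numpy as np
import pytest

from uef import motor, synth


@pytest.fixture
def clean_params():
    """Noise-free half-sine trial: amplitude 300 deg/s, 1.5 Hz cycles."""
    return synth.MotorSimParams(
        peak_velocity=300.0,
        cycle_frequency=1.5,
        decline_pct=0.0,
        cycle_cv=0.0,
        noise_sd=0.0,
        drift_amp=0.0,
        seed=1,
    )


@pytest.fixture
def clean_trial(clean_params):
    trial, truth = synth.gen_flexion_trial(clean_params)
    return trial, truth


@pytest.fixture
def inertia_anthro():
    """Anthropometrics with an explicitly pinned segment inertia."""
    return motor.Anthropometrics(forearm_hand_inertia=0.06)


def match_beats(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.05):
    """Greedy one-to-one beat matching; returns (tp, sensitivity, ppv)."""
    used = set()
    tp = 0
    for t in truth:
        d = np.abs(detected - t)
        j = int(np.argmin(d))
        if d[j] <= tol_s and j not in used:
            tp += 1
            used.add(j)
    return tp, tp / len(truth), tp / len(detected)
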