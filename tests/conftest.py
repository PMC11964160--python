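import numpy as np
import pytest

from sensillum import synth


@pytest.fixture(scope="session")
def short_design():
    """Three stimuli, 30 s apart, first at 1 s; 1.5 min recording."""
    return synth.CohortDesign(
        groups=[("ctrl", "ZT1-3", 1)],
        stimulus_interval=30.0,
        recording_duration=1.5,
        first_stimulus=1.0,
    )


@pytest.fixture(scope="session")
def noiseless_gt():
    return synth.GroundTruthParams(
        noise_sd=0.0, spontaneous_rate=0.1, llpr_duration=20.0
    )


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_gt, short_design):
    return synth.generate_recording(noiseless_gt, short_design, seed=42)


def match_spikes(detected: np.ndarray, truth: np.ndarray, tol: float = 5e-4):
    """Greedy 1:1 matching; returns (tp, fp, fn)."""
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        i = np.searchsorted(detected, t)
        for j in (i - 1, i):
            if 0 <= j < detected.size and not used[j] and abs(detected[j] - t) <= tol:
                used[j] = True
                tp += 1
                break
    return tp, detected.size - tp, truth.size - tp


def f1_score(detected: np.ndarray, truth: np.ndarray, tol: float = 5e-4) -> float:
    tp, fp, fn = match_spikes(detected, truth, tol)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
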