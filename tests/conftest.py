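import numpy as np
import pytest

from pedalerp.paradigm import ParadigmSpec
from pedalerp.simulate import preset_profiles, synthesize_recording
from pedalerp.preprocessing import (
    apply_filters,
    baseline_correct,
    detect_emg_onsets,
    segment,
)

SEED = 20170623


@pytest.fixture(scope="session")
def small_spec():
    """All five conditions, 3 trials each (168 s session)."""
    return ParadigmSpec(trials_per_condition=3)


@pytest.fixture(scope="session")
def foot_rest_spec():
    """Foot execution + rest only, 12 trials each: enough power, fast."""
    return ParadigmSpec(conditions=("foot_exec", "rest"), trials_per_condition=12)


@pytest.fixture(scope="session")
def responder_profile():
    return preset_profiles()["healthy_responder"]


@pytest.fixture(scope="session")
def clean_responder_profile(responder_profile):
    """Responder with every artifact source and jitter off, full trial response."""
    from dataclasses import replace

    return replace(responder_profile, blink_rate=0.0, eye_movement_rate=0.0,
                   bad_channel_episode_rate=0.0, trial_response_probability=1.0,
                   emg_onset_jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_responder_recording(small_spec, responder_profile):
    return synthesize_recording(small_spec, responder_profile, SEED)


@pytest.fixture(scope="session")
def preprocessed(small_responder_recording):
    """Filtered recording with EMG onsets merged into the event stream."""
    filt = apply_filters(small_responder_recording)
    filt.events = sorted(filt.events + detect_emg_onsets(filt))
    return filt


@pytest.fixture(scope="session")
def stim_segments(preprocessed):
    return baseline_correct(segment(preprocessed, "stimulus"))


@pytest.fixture(scope="session")
def emg_segments(preprocessed):
    return baseline_correct(segment(preprocessed, "emg"))


@pytest.fixture(scope="session")
def foot_rest_emg_segments(foot_rest_spec, clean_responder_profile):
    """EMG-locked foot-execution epochs from a 12-trial clean responder session."""
    rec = synthesize_recording(foot_rest_spec, clean_responder_profile, SEED)
    filt = apply_filters(rec)
    filt.events = sorted(filt.events + detect_emg_onsets(filt))
    return baseline_correct(segment(filt, "emg"))


def brute_force_window_ptp(x: np.ndarray, window: int) -> np.ndarray:
    """Exhaustive O(n*w) moving-window range scan: the detector oracle."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.size - window + 1)
    for i in range(out.size):
        w = x[i:i + window]
        out[i] = w.max() - w.min()
    return out
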