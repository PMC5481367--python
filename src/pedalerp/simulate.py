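"""Synthetic EEG/EMG/EOG/ECG session generator.

Emulates the statistical structure the downstream analysis assumes: a
movement-locked ~1 Hz high-amplitude potential maximal at Pz during cued
repetitive foot movement (one damped oscillation cycle per cue, decaying in
amplitude across the six movements of a trial), EMG bursts of the tibialis
anterior time-locked to the low tones with Gaussian onset jitter, ocular and
transient high-amplitude channel artifacts, 1/f background noise, and a set of
subject profiles spanning healthy responders, non-responders and profiles
modeled on chronic spinal-cord-injury recordings (absent potential; noisy,
flat, sporadically bursting or weakly rhythmic EMG).

Recordings are generated as if referenced to Cz: the Cz channel itself is flat
until re-referencing, as in a Cz-referenced acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.signal.windows import hann, tukey

from .exceptions import ConfigurationError
from .paradigm import (
    CHANNELS,
    ParadigmSpec,
    Recording,
    generate_event_schedule,
    make_recording,
)

EMG_MODES: Tuple[str, ...] = (
    "normal_bursts", "noise_only", "flat", "spastic_sporadic", "rhythmic_weak",
)

#: recorded (Cz-referenced) projection of the movement-locked component
DEFAULT_RESPONSE_CHANNELS: Dict[str, float] = {
    "Pz": 1.0, "M1": 0.12, "M2": 0.12, "F3": 0.03, "F4": 0.03,
}


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one simulated subject.

    ``oscillation_amplitude_uV`` is the single-trial peak of the movement-locked
    Pz component for the first movement of a trial; movement ``k`` is scaled by
    ``amplitude_decay**(k-1)``.  ``trial_response_probability`` is the fraction
    of foot-execution trials that carry the component at all (the potential is
    not present in every trial even in strong responders).
    """

    label: str
    oscillation_amplitude_uV: float = 0.0
    amplitude_decay: float = 0.85
    oscillation_polarity: str = "positive_first"
    response_channels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_CHANNELS))
    trial_response_probability: float = 1.0
    component_peak_latency_s: float = 0.15   # component peak relative to EMG onset
    emg_mode: str = "normal_bursts"
    emg_reaction_time_s: float = 0.2         # cue -> EMG onset, mean
    emg_onset_jitter_sd: float = 0.05
    emg_burst_amplitude_uV: float = 80.0
    emg_burst_duration_s: float = 0.2
    emg_baseline_noise_uV: float = 2.0
    blink_rate: float = 2.0                  # events / min
    eye_movement_rate: float = 1.0
    blink_amplitude_uV: float = 160.0
    eye_movement_amplitude_uV: float = 150.0
    bad_channel_episode_rate: float = 0.2
    bad_channel_amplitude_uV: float = 300.0
    background_noise_scale: float = 12.0     # EEG background RMS, uV

    def __post_init__(self) -> None:
        if not 0.0 <= self.trial_response_probability <= 1.0:
            raise ConfigurationError("trial_response_probability must be in [0, 1]")
        if not 0.0 < self.amplitude_decay <= 1.0:
            raise ConfigurationError("amplitude_decay must be in (0, 1]")
        if self.oscillation_polarity not in ("positive_first", "negative_first"):
            raise ConfigurationError("unknown oscillation_polarity")
        if self.emg_mode not in EMG_MODES:
            raise ConfigurationError(f"unknown emg_mode {self.emg_mode!r}")
        for name in ("blink_rate", "eye_movement_rate", "bad_channel_episode_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.oscillation_amplitude_uV < 0 or self.background_noise_scale < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.emg_onset_jitter_sd < 0:
            raise ConfigurationError("emg_onset_jitter_sd must be >= 0")


def preset_profiles() -> Dict[str, SubjectProfile]:
    """Named subject profiles spanning the phenomenology the analysis targets."""
    return {
        "healthy_responder": SubjectProfile(
            label="healthy_responder", oscillation_amplitude_uV=80.0,
            amplitude_decay=0.85, trial_response_probability=0.9,
            emg_mode="normal_bursts"),
        "healthy_nonresponder": SubjectProfile(
            label="healthy_nonresponder", oscillation_amplitude_uV=0.0,
            emg_mode="normal_bursts"),
        "sci_no_emg": SubjectProfile(
            label="sci_no_emg", oscillation_amplitude_uV=0.0,
            emg_mode="flat", blink_rate=4.0, eye_movement_rate=3.0),
        "sci_spastic": SubjectProfile(
            label="sci_spastic", oscillation_amplitude_uV=0.0,
            emg_mode="spastic_sporadic", blink_rate=4.0, eye_movement_rate=3.0),
        "sci_rhythmic_emg": SubjectProfile(
            label="sci_rhythmic_emg", oscillation_amplitude_uV=0.0,
            emg_mode="rhythmic_weak", blink_rate=4.0, eye_movement_rate=3.0),
        "sci_artifact_heavy": SubjectProfile(
            label="sci_artifact_heavy", oscillation_amplitude_uV=0.0,
            emg_mode="noise_only", blink_rate=15.0, eye_movement_rate=12.0,
            bad_channel_episode_rate=0.5),
    }


# ---------------------------------------------------------------------------
# primitive signal generators


def pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float,
               knee_hz: float = 0.5) -> np.ndarray:
    """1/f-weighted Gaussian noise (flat below ``knee_hz``), scaled to ``rms``."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    weight = 1.0 / np.sqrt(np.maximum(f, knee_hz) / knee_hz)
    weight[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * weight, n)
    sd = shaped.std()
    return shaped * (rms / sd) if sd > 0 else shaped


def synthesize_noise_epochs(n_epochs: int, n_samples: int, fs: float,
                            rms: float, seed: int) -> np.ndarray:
    """Independent 1/f background-noise epochs (the generator's noise model).

    Used for null-calibration studies of the permutation test: both "condition"
    and "rest" groups drawn from this identical process carry no real effect.
    """
    rng = np.random.default_rng(seed)
    return np.stack([pink_noise(rng, n_samples, fs, rms) for _ in range(n_epochs)])


def _component_cycle(fs: float, period: float, polarity: str) -> Tuple[np.ndarray, int]:
    """One damped oscillation cycle, unit peak; returns (waveform, peak index)."""
    n = int(round(period * fs))
    t = np.arange(n) / fs
    w = np.sin(2 * np.pi * t / period) * np.exp(-2.0 * t / period)
    w /= np.abs(w).max()
    if polarity == "negative_first":
        w = -w
    return w, int(np.abs(w).argmax())


def _emg_burst(rng: np.random.Generator, fs: float, duration: float,
               amplitude: float) -> np.ndarray:
    """A rectifiable broadband burst: white noise under a flat-topped envelope."""
    n = max(int(round(duration * fs)), 2)
    burst = rng.standard_normal(n) * tukey(n, alpha=0.25)
    peak = np.abs(burst).max()
    return burst * (amplitude / peak) if peak > 0 else burst


def _blink_template(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic vertical-EOG transient, ~350 ms, dominant positive lobe."""
    n_pos, n_neg = int(round(0.25 * fs)), int(round(0.10 * fs))
    return amplitude * np.concatenate([hann(n_pos), -0.25 * hann(n_neg)])


def _eye_movement_template(fs: float, amplitude: float) -> np.ndarray:
    """Step-like horizontal-EOG deflection: 100 ms rise, 300 ms hold, 100 ms fall."""
    r, h = int(round(0.1 * fs)), int(round(0.3 * fs))
    rise = np.linspace(0.0, 1.0, r, endpoint=False)
    return amplitude * np.concatenate([rise, np.ones(h), rise[::-1]])


def _bad_channel_template(fs: float, amplitude: float) -> np.ndarray:
    """High-amplitude 18 Hz transient, 250 ms."""
    n = int(round(0.25 * fs))
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * 18.0 * t) * hann(n)


def _qrs_template(fs: float, amplitude: float = 600.0) -> np.ndarray:
    n = max(int(round(0.04 * fs)), 3)
    tri = 1.0 - np.abs(np.linspace(-1, 1, n))
    return amplitude * tri


def _add(trace: np.ndarray, template: np.ndarray, start: int) -> None:
    """Add ``template`` into ``trace`` starting at ``start``, clipped to bounds."""
    n = trace.shape[-1]
    a, b = max(start, 0), min(start + template.size, n)
    if a < b:
        trace[a:b] += template[a - start:b - start]


# ---------------------------------------------------------------------------
# session synthesis


def synthesize_recording(spec: ParadigmSpec, profile: SubjectProfile,
                         seed: int) -> Recording:
    """Generate one complete continuous session for ``profile``.

    Deterministic: identical (spec, profile, seed) gives a bit-identical
    recording.  A single seed drives named sub-streams (background noise,
    per-trial responses, ocular artifacts, channel episodes, ECG) so each
    source of variability is independently reproducible.
    """
    fs = spec.sampling_rate
    n = spec.n_samples
    events = generate_event_schedule(spec, seed)

    ss = np.random.SeedSequence(seed)
    s_bg, s_trial, s_ocular, s_bad, s_ecg, s_emg = ss.spawn(6)
    rng_bg = np.random.default_rng(s_bg)
    rng_ocular = np.random.default_rng(s_ocular)
    rng_bad = np.random.default_rng(s_bad)
    rng_ecg = np.random.default_rng(s_ecg)
    rng_emg = np.random.default_rng(s_emg)

    labels = list(CHANNELS)
    sig = np.zeros((len(labels), n))
    idx = {c: i for i, c in enumerate(labels)}

    # background: 1/f on scalp/EOG channels; Cz is the reference -> flat
    for c in ("Pz", "F3", "F4", "M1", "M2"):
        sig[idx[c]] = pink_noise(rng_bg, n, fs, profile.background_noise_scale)
    for c in ("VEOG", "HEOG"):
        sig[idx[c]] = pink_noise(rng_bg, n, fs, 0.6 * profile.background_noise_scale)

    # EMG baseline noise level depends on mode
    emg_rms = {"normal_bursts": 1.0, "rhythmic_weak": 1.0, "spastic_sporadic": 1.0,
               "noise_only": 4.0, "flat": 0.1}[profile.emg_mode]
    emg = sig[idx["EMG_tibialis"]]
    emg += rng_emg.standard_normal(n) * (emg_rms * profile.emg_baseline_noise_uV)

    # movement-locked component + cue-locked EMG bursts, trial by trial
    cycle, peak_off = _component_cycle(fs, spec.cue_period, profile.oscillation_polarity)
    foot_starts = [e for e in events if e.kind == "condition_start" and e.condition == "foot_exec"]
    trial_seeds = s_trial.spawn(max(len(foot_starts), 1))
    for ev, ts in zip(foot_starts, trial_seeds):
        rng_t = np.random.default_rng(ts)
        responds = rng_t.random() < profile.trial_response_probability
        for k in range(spec.movements_per_trial):
            cue = ev.onset_sample + int(round(k * spec.cue_period * fs))
            jitter = rng_t.normal(0.0, profile.emg_onset_jitter_sd)
            jitter = float(np.clip(jitter, -3 * profile.emg_onset_jitter_sd,
                                   3 * profile.emg_onset_jitter_sd))
            emg_onset = cue + int(round((profile.emg_reaction_time_s + jitter) * fs))
            if profile.emg_mode == "normal_bursts":
                _add(emg, _emg_burst(rng_t, fs, profile.emg_burst_duration_s,
                                     profile.emg_burst_amplitude_uV), emg_onset)
            if responds and profile.oscillation_amplitude_uV > 0:
                amp = profile.oscillation_amplitude_uV * profile.amplitude_decay ** k
                start = emg_onset + int(round(profile.component_peak_latency_s * fs)) - peak_off
                for ch, w in profile.response_channels.items():
                    if ch in idx:
                        _add(sig[idx[ch]], amp * w * cycle, start)

    # alternative EMG regimes
    if profile.emg_mode == "rhythmic_weak":
        for ev in foot_starts:
            for k in range(spec.movements_per_trial):
                cue = ev.onset_sample + int(round(k * spec.cue_period * fs))
                onset = cue + int(round(profile.emg_reaction_time_s * fs))
                _add(emg, _emg_burst(rng_emg, fs, profile.emg_burst_duration_s,
                                     0.15 * profile.emg_burst_amplitude_uV), onset)
    elif profile.emg_mode == "spastic_sporadic":
        n_jerks = rng_emg.poisson(2.0 * spec.total_duration / 60.0)
        for t in np.sort(rng_emg.uniform(0, spec.total_duration - 1.0, n_jerks)):
            _add(emg, _emg_burst(rng_emg, fs, 0.3, profile.emg_burst_amplitude_uV),
                 int(round(t * fs)))

    # ocular artifacts
    minutes = spec.total_duration / 60.0
    veog, heog = sig[idx["VEOG"]], sig[idx["HEOG"]]
    blink = _blink_template(fs, profile.blink_amplitude_uV)
    for t in np.sort(rng_ocular.uniform(0, spec.total_duration - 0.5,
                                        rng_ocular.poisson(profile.blink_rate * minutes))):
        s = int(round(t * fs))
        _add(veog, blink, s)
        _add(sig[idx["F3"]], 0.3 * blink, s)
        _add(sig[idx["F4"]], 0.3 * blink, s)
    eyem = _eye_movement_template(fs, profile.eye_movement_amplitude_uV)
    for t in np.sort(rng_ocular.uniform(0, spec.total_duration - 0.6,
                                        rng_ocular.poisson(profile.eye_movement_rate * minutes))):
        s = int(round(t * fs))
        sign = 1.0 if rng_ocular.random() < 0.5 else -1.0
        _add(heog, sign * eyem, s)
        _add(sig[idx["F3"]], 0.2 * sign * eyem, s)
        _add(sig[idx["F4"]], -0.2 * sign * eyem, s)

    # transient bad-channel episodes on random scalp channels (never the reference)
    episode = _bad_channel_template(fs, profile.bad_channel_amplitude_uV)
    candidates = ["Pz", "F3", "F4", "M1", "M2"]
    for t in np.sort(rng_bad.uniform(0, spec.total_duration - 0.3,
                                     rng_bad.poisson(profile.bad_channel_episode_rate * minutes))):
        ch = candidates[rng_bad.integers(len(candidates))]
        _add(sig[idx[ch]], episode, int(round(t * fs)))

    # ECG: ~72 bpm spike train with slight beat-to-beat jitter (never analyzed)
    qrs = _qrs_template(fs)
    t = float(rng_ecg.uniform(0, 0.8))
    while t < spec.total_duration - 0.1:
        _add(sig[idx["ECG"]], qrs, int(round(t * fs)))
        t += float(rng_ecg.normal(60.0 / 72.0, 0.02))

    return make_recording(
        sig, spec, events,
        meta={"subject": profile.label, "seed": int(seed)},
    )


__all__ = [
    "EMG_MODES", "DEFAULT_RESPONSE_CHANNELS", "SubjectProfile",
    "preset_profiles", "synthesize_recording", "synthesize_noise_epochs",
    "pink_noise", "replace",
]
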