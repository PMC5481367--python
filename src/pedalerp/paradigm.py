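"""Experimental paradigm description, event schedule and the core recording container.

The paradigm is a cued repetitive-movement task: each trial plays a spoken
instruction (3 s), pauses 1 s, then cues six movements at 1 Hz over a 6 s task
window (a low tone to lift the forefoot / clench the hand, a higher tone 500 ms
later to release), followed by a 1 s inter-trial pause.  Five conditions (foot
and hand execution and imagination, plus rest) of 25 trials each are presented
in random order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError, DataError

#: canonical condition codes, in presentation-deck order
CONDITIONS: Tuple[str, ...] = ("foot_exec", "foot_imag", "hand_exec", "hand_imag", "rest")

#: the reduced 10-channel montage: every channel the analysis touches
CHANNELS: Tuple[str, ...] = (
    "Pz", "Cz", "F3", "F4", "M1", "M2", "VEOG", "HEOG", "EMG_tibialis", "ECG",
)

#: channel label -> role; mastoids are scalp (eeg-role) electrodes
DEFAULT_ROLES: Dict[str, str] = {
    "Pz": "eeg", "Cz": "eeg", "F3": "eeg", "F4": "eeg", "M1": "eeg", "M2": "eeg",
    "VEOG": "eog", "HEOG": "eog", "EMG_tibialis": "emg", "ECG": "ecg",
}

EVENT_KINDS: Tuple[str, ...] = ("condition_start", "low_tone", "high_tone", "emg_onset")


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and bookkeeping of the cued-movement paradigm.

    Defaults reproduce the study conditions: 250 Hz sampling, five conditions,
    25 trials each, six 1 Hz-cued movements in a 6 s task window.
    """

    sampling_rate: float = 250.0
    conditions: Tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 25
    instruction_duration: float = 3.0
    pre_task_pause: float = 1.0
    task_duration: float = 6.0
    cue_period: float = 1.0
    second_tone_offset: float = 0.5
    inter_trial_pause: float = 1.0
    movements_per_trial: int = 6
    randomize_order: bool = True
    lead_in: float = 1.0
    lead_out: float = 2.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.trials_per_condition < 0:
            raise ConfigurationError("trials_per_condition must be >= 0")
        for name in ("instruction_duration", "pre_task_pause", "task_duration",
                     "cue_period", "inter_trial_pause"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.second_tone_offset < 0 or self.second_tone_offset >= self.cue_period:
            raise ConfigurationError("second_tone_offset must lie within one cue period")
        if not math.isclose(self.movements_per_trial * self.cue_period,
                            self.task_duration, rel_tol=1e-9):
            raise ConfigurationError(
                "movements_per_trial x cue_period must equal task_duration")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("duplicate condition codes")

    @property
    def trial_duration(self) -> float:
        """Seconds from trial start (instruction onset) to the next trial start."""
        return (self.instruction_duration + self.pre_task_pause
                + self.task_duration + self.inter_trial_pause)

    @property
    def n_trials_total(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    @property
    def total_duration(self) -> float:
        return self.lead_in + self.n_trials_total * self.trial_duration + self.lead_out

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))


@dataclass(frozen=True, order=True)
class EventMarker:
    """A timestamped, typed annotation; 0-based sample index."""

    onset_sample: int
    kind: str
    condition: str
    trial_index: int

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ConfigurationError("onset_sample must be >= 0")
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")


@dataclass
class Recording:
    """A continuous multichannel recording in microvolts.

    ``signal`` is ``(n_channels, n_samples)``; the synthetic sessions are
    generated as if referenced to Cz, so the Cz channel itself is flat until
    re-referencing.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]
    channel_roles: Mapping[str, str]
    reference: str = "Cz"
    events: List[EventMarker] = field(default_factory=list)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise DataError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise DataError("channel_labels length does not match signal rows")
        self.events = sorted(self.events)
        n = self.signal.shape[1]
        for ev in self.events:
            if ev.onset_sample >= n:
                raise DataError(f"event at sample {ev.onset_sample} beyond recording end {n}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_labels).index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not present") from None

    def get(self, label: str) -> np.ndarray:
        return self.signal[self.channel_index(label)]

    def channels_with_role(self, role: str) -> List[str]:
        return [c for c in self.channel_labels if self.channel_roles.get(c) == role]

    def events_of_kind(self, kind: str, condition: str | None = None) -> List[EventMarker]:
        return [e for e in self.events
                if e.kind == kind and (condition is None or e.condition == condition)]

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            channel_roles=dict(self.channel_roles),
            reference=self.reference,
            events=list(self.events),
            meta=dict(self.meta),
        )


def trial_start_times(spec: ParadigmSpec) -> np.ndarray:
    """Instruction-onset time (s) of each of the ``n_trials_total`` trials."""
    return spec.lead_in + np.arange(spec.n_trials_total) * spec.trial_duration


def generate_event_schedule(spec: ParadigmSpec, seed: int) -> List[EventMarker]:
    """Build the full marker stream for one session.

    The 125-trial deck (25 per condition by default) is shuffled with the given
    seed when ``randomize_order`` is set.  Each trial contributes one
    ``condition_start`` marker (the first low tone — the stimulus used for
    segmentation), ``movements_per_trial`` low tones at ``cue_period`` spacing
    and as many high tones offset by ``second_tone_offset``.
    """
    fs = spec.sampling_rate
    deck = [cond for cond in spec.conditions for _ in range(spec.trials_per_condition)]
    if spec.randomize_order:
        rng = np.random.default_rng(seed)
        deck = [deck[i] for i in rng.permutation(len(deck))]

    counters = {cond: 0 for cond in spec.conditions}
    events: List[EventMarker] = []
    starts = trial_start_times(spec)
    for t0, cond in zip(starts, deck):
        idx = counters[cond]
        counters[cond] += 1
        task_t0 = t0 + spec.instruction_duration + spec.pre_task_pause
        events.append(EventMarker(int(round(task_t0 * fs)), "condition_start", cond, idx))
        for k in range(spec.movements_per_trial):
            cue_t = task_t0 + k * spec.cue_period
            events.append(EventMarker(int(round(cue_t * fs)), "low_tone", cond, idx))
            events.append(EventMarker(
                int(round((cue_t + spec.second_tone_offset) * fs)), "high_tone", cond, idx))
    return sorted(events)


def make_recording(signal: np.ndarray, spec: ParadigmSpec,
                   events: Sequence[EventMarker] | None = None,
                   meta: Mapping[str, object] | None = None) -> Recording:
    """Wrap a (10, n) signal matrix in the default montage."""
    return Recording(
        signal=signal,
        sampling_rate=spec.sampling_rate,
        channel_labels=list(CHANNELS),
        channel_roles=dict(DEFAULT_ROLES),
        reference="Cz",
        events=list(events or []),
        meta=dict(meta or {}),
    )


__all__ = [
    "CONDITIONS", "CHANNELS", "DEFAULT_ROLES", "EVENT_KINDS",
    "ParadigmSpec", "EventMarker", "Recording",
    "generate_event_schedule", "trial_start_times", "make_recording", "replace",
]
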