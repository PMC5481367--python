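"""Filtering, re-referencing, EMG onset detection, epoching and baseline correction.

Pipeline order: filter -> detect EMG onsets -> segment -> baseline-correct ->
re-reference per use (linked mastoids for visual inspection, common average for
statistics).  Epochs span 2 s before the lock event to 6 s after it (8 s,
half-open ``[start, start + 8 s)``), and the first 2 s serve as baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, DataError
from .paradigm import EventMarker, Recording

logger = logging.getLogger(__name__)

PRE_S = 2.0    # epoch span relative to the lock event
POST_S = 6.0

Lock = Literal["stimulus", "emg"]


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass cascade: recursive (IIR) highpass + linear-phase FIR lowpass.

    Defaults: 1st-order Butterworth highpass at 0.1 Hz and a Hamming-windowed
    FIR lowpass with a 30 -> 37.5 Hz transition band, both applied
    forward-backward for zero phase (component latency is analysis-relevant).
    """

    highpass_hz: float = 0.1
    highpass_order: int = 1
    lowpass_hz: float = 30.0
    lowpass_transition_hz: float = 7.5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ConfigurationError("need 0 < highpass_hz < lowpass_hz")
        if self.highpass_order < 1 or self.lowpass_transition_hz <= 0:
            raise ConfigurationError("invalid filter design parameters")

    def design(self, fs: float) -> Tuple[np.ndarray, np.ndarray]:
        """Return (sos highpass, FIR lowpass taps) for sampling rate ``fs``."""
        if self.lowpass_hz + self.lowpass_transition_hz > fs / 2:
            raise ConfigurationError(
                f"lowpass transition band exceeds Nyquist ({fs / 2} Hz)")
        sos = sps.butter(self.highpass_order, self.highpass_hz, "highpass",
                         fs=fs, output="sos")
        # Hamming-window FIR: ~3.3/(normalized transition width) taps, odd
        numtaps = int(np.ceil(3.3 * fs / self.lowpass_transition_hz)) | 1
        taps = sps.firwin(numtaps, self.lowpass_hz + self.lowpass_transition_hz / 2,
                          window="hamming", fs=fs)
        return sos, taps

    def magnitude_response(self, freqs: Sequence[float], fs: float) -> np.ndarray:
        """|H(f)| of the full cascade as applied (squared if zero-phase)."""
        sos, taps = self.design(fs)
        w = np.asarray(freqs, dtype=float)
        _, h_hp = sps.sosfreqz(sos, worN=w, fs=fs)
        _, h_lp = sps.freqz(taps, worN=w, fs=fs)
        mag = np.abs(h_hp) * np.abs(h_lp)
        return mag ** 2 if self.zero_phase else mag


def apply_filters(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Filter all EEG/EOG/EMG channels; ECG, events and sample count untouched."""
    fs = recording.sampling_rate
    if fs <= 2 * spec.lowpass_hz:
        raise ConfigurationError("sampling rate must exceed twice the lowpass cutoff")
    sos, taps = spec.design(fs)
    out = recording.copy()
    # the 0.1 Hz highpass has a ~1.6 s time constant: reflect-pad several
    # time constants so edge transients stay inside the padding
    pad_iir = min(recording.n_samples - 1, int(round(3.0 * fs / spec.highpass_hz)))
    for label in recording.channel_labels:
        if recording.channel_roles.get(label) not in ("eeg", "eog", "emg"):
            continue
        i = out.channel_index(label)
        x = out.signal[i]
        if spec.zero_phase:
            x = sps.sosfiltfilt(sos, x, padlen=pad_iir)
            x = sps.filtfilt(taps, [1.0], x)
        else:
            x = sps.sosfilt(sos, x)
            x = sps.lfilter(taps, [1.0], x)
        out.signal[i] = x
    out.meta["filter"] = {
        "highpass_hz": spec.highpass_hz, "lowpass_hz": spec.lowpass_hz,
        "zero_phase": spec.zero_phase,
    }
    return out


# ---------------------------------------------------------------------------
# re-referencing


def _rereference_matrix(data: np.ndarray, labels: Sequence[str],
                        roles: Dict[str, str], scheme: str) -> np.ndarray:
    eeg_idx = [i for i, c in enumerate(labels) if roles.get(c) == "eeg"]
    if not eeg_idx:
        raise DataError("no EEG-role channels to re-reference")
    if scheme == "linked_mastoids":
        for m in ("M1", "M2"):
            if m not in labels:
                raise DataError(f"mastoid channel {m!r} missing")
        ref = 0.5 * (data[list(labels).index("M1")] + data[list(labels).index("M2")])
    elif scheme == "common_average":
        ref = data[eeg_idx].mean(axis=0)
    else:
        raise ConfigurationError(f"unknown reference scheme {scheme!r}")
    out = data.copy()
    out[eeg_idx] = data[eeg_idx] - ref
    return out


def rereference(recording: Recording, scheme: str) -> Recording:
    """Re-express EEG channels against the requested reference.

    No-op (idempotent) when the recording already carries that reference tag.
    EOG/EMG/ECG channels are never touched.
    """
    if recording.reference == scheme:
        return recording.copy()
    out = recording.copy()
    out.signal = _rereference_matrix(out.signal, list(out.channel_labels),
                                     dict(out.channel_roles), scheme)
    out.reference = scheme
    return out


# ---------------------------------------------------------------------------
# EMG onset detection (algorithmic stand-in for manual marker placement)


@dataclass(frozen=True)
class EmgDetectorParams:
    """Rectify -> moving-average smooth -> threshold at baseline mean + k*SD."""

    smooth_s: float = 0.05
    threshold_k: float = 3.0
    sustain_s: float = 0.05
    baseline_s: float = 1.0     # pre-task pause preceding the first cue
    emg_channel: str = "EMG_tibialis"


def _envelope(x: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    w = max(int(round(smooth_s * fs)), 1)
    kernel = np.full(w, 1.0 / w)
    return np.convolve(np.abs(x), kernel, mode="same")


def detect_emg_onsets(recording: Recording, condition: str = "foot_exec",
                      params: EmgDetectorParams = EmgDetectorParams(),
                      task_duration_s: float | None = None) -> List[EventMarker]:
    """Per trial, the first sustained supra-threshold sample of the EMG envelope.

    Baseline statistics come from the ``baseline_s`` window before the trial's
    first cue; the search window is the task period (first cue to last cue +
    one cue period, inferred from the low-tone markers unless given).  Trials
    with no sustained crossing yield no marker — they are later dropped from
    EMG-locked segmentation, mirroring trials excluded for insufficient muscle
    activity.
    """
    if params.emg_channel not in recording.channel_labels:
        raise DataError(f"EMG channel {params.emg_channel!r} missing")
    fs = recording.sampling_rate
    env = _envelope(recording.get(params.emg_channel), fs, params.smooth_s)
    sustain = max(int(round(params.sustain_s * fs)), 1)
    n_base = int(round(params.baseline_s * fs))

    onsets: List[EventMarker] = []
    starts = recording.events_of_kind("condition_start", condition)
    if not starts:
        raise DataError(f"no trials for condition {condition!r}")
    for ev in starts:
        cues = [e.onset_sample for e in recording.events
                if e.kind == "low_tone" and e.condition == condition
                and e.trial_index == ev.trial_index]
        if task_duration_s is not None:
            t_end = ev.onset_sample + int(round(task_duration_s * fs))
        elif cues:
            period = (cues[1] - cues[0]) if len(cues) > 1 else int(round(fs))
            t_end = max(cues) + period
        else:
            t_end = ev.onset_sample + int(round(6.0 * fs))
        t_end = min(t_end, recording.n_samples)
        base = env[max(ev.onset_sample - n_base, 0):ev.onset_sample]
        if base.size == 0:
            continue
        thresh = base.mean() + params.threshold_k * base.std()
        seg = env[ev.onset_sample:t_end]
        above = seg >= thresh
        # first run of >= sustain consecutive supra-threshold samples
        onset = None
        run = 0
        for j, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= sustain:
                onset = j - sustain + 1
                break
        if onset is not None:
            onsets.append(EventMarker(ev.onset_sample + onset, "emg_onset",
                                      condition, ev.trial_index))
        else:
            logger.info("no EMG onset for %s trial %d", condition, ev.trial_index)
    return onsets


# ---------------------------------------------------------------------------
# epoching


@dataclass
class Segment:
    """One fixed-length epoch; the lock event sits at ``t0_sample`` (2 s in)."""

    data: np.ndarray
    lock: Lock
    t0_sample: int
    condition: str
    trial_index: int
    annotations: Dict[str, object] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentSet:
    """Condition-grouped epochs sharing montage, rate and lock scheme."""

    segments: List[Segment]
    lock: Lock
    sampling_rate: float
    channel_labels: List[str]
    channel_roles: Dict[str, str]
    reference: str
    provenance: Dict[str, object] = field(default_factory=dict)
    dropped: List[Tuple[str, int, str]] = field(default_factory=list)

    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for s in self.segments:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def by_condition(self, condition: str) -> List[Segment]:
        return [s for s in self.segments if s.condition == condition]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not present") from None

    def condition_array(self, condition: str, channel: str) -> np.ndarray:
        """(n_trials, n_samples) matrix of one channel across a condition."""
        segs = self.by_condition(condition)
        i = self.channel_index(channel)
        return np.stack([s.data[i] for s in segs]) if segs else np.empty((0, 0))

    def copy(self) -> "SegmentSet":
        return SegmentSet(
            segments=[Segment(s.data.copy(), s.lock, s.t0_sample, s.condition,
                              s.trial_index, dict(s.annotations))
                      for s in self.segments],
            lock=self.lock, sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            channel_roles=dict(self.channel_roles), reference=self.reference,
            provenance=dict(self.provenance), dropped=list(self.dropped),
        )


def segment(recording: Recording, lock: Lock,
            emg_condition: str = "foot_exec") -> SegmentSet:
    """Cut 8 s epochs spanning [lock event - 2 s, lock event + 6 s).

    ``lock="stimulus"`` epochs every condition on its condition-start stimulus;
    ``lock="emg"`` epochs only the EMG-bearing condition on its ``emg_onset``
    markers (which must already be in ``recording.events``).  Epochs that would
    cross the recording bounds are dropped with a recorded reason.
    """
    if lock not in ("stimulus", "emg"):
        raise ConfigurationError(f"unknown lock scheme {lock!r}")
    fs = recording.sampling_rate
    pre = int(round(PRE_S * fs))
    length = int(round((PRE_S + POST_S) * fs))
    if lock == "stimulus":
        locks = recording.events_of_kind("condition_start")
    else:
        locks = recording.events_of_kind("emg_onset", emg_condition)

    segs: List[Segment] = []
    dropped: List[Tuple[str, int, str]] = []
    for ev in locks:
        a = ev.onset_sample - pre
        b = a + length
        if a < 0 or b > recording.n_samples:
            reason = "window out of recording bounds"
            logger.warning("dropping %s trial %d: %s", ev.condition, ev.trial_index, reason)
            dropped.append((ev.condition, ev.trial_index, reason))
            continue
        segs.append(Segment(recording.signal[:, a:b].copy(), lock, pre,
                            ev.condition, ev.trial_index))
    return SegmentSet(
        segments=segs, lock=lock, sampling_rate=fs,
        channel_labels=list(recording.channel_labels),
        channel_roles=dict(recording.channel_roles),
        reference=recording.reference,
        provenance={"source": recording.meta.get("subject"),
                    "seed": recording.meta.get("seed"),
                    "filter": recording.meta.get("filter")},
        dropped=dropped,
    )


def baseline_correct(segments: SegmentSet, baseline_s: float = PRE_S) -> SegmentSet:
    """Subtract each channel's mean over the first ``baseline_s`` seconds.

    Idempotent; returns a corrected copy.
    """
    out = segments.copy()
    nb = int(round(baseline_s * out.sampling_rate))
    if out.segments and nb > out.segments[0].n_samples:
        raise ConfigurationError("baseline window longer than segment")
    for s in out.segments:
        s.data -= s.data[:, :nb].mean(axis=1, keepdims=True)
    out.provenance["baseline_s"] = baseline_s
    return out


def rereference_segments(segments: SegmentSet, scheme: str) -> SegmentSet:
    """Per-use re-referencing of epochs (mastoids for plots, average for stats)."""
    if segments.reference == scheme:
        return segments.copy()
    out = segments.copy()
    for s in out.segments:
        s.data = _rereference_matrix(s.data, out.channel_labels,
                                     out.channel_roles, scheme)
    out.reference = scheme
    return out


__all__ = [
    "PRE_S", "POST_S", "FilterSpec", "EmgDetectorParams", "Segment", "SegmentSet",
    "apply_filters", "rereference", "rereference_segments", "detect_emg_onsets",
    "segment", "baseline_correct", "replace",
]
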