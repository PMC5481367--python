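"""Amplitude-threshold artifact detection and the strict/lenient exclusion policies.

A channel is marked bad when its peak-to-peak range inside a 100 ms moving
window exceeds 200 uV (strict inequality — a range exactly at threshold does
not flag).  Ocular artifacts use the same windowed-range machinery on the
vertical (blink) and horizontal (eye movement) EOG channels at 100 uV.  The
strict policy drops a segment on any ocular artifact or a bad target channel;
the lenient policy only on a bad target channel — so strict inclusion is
always a subset of lenient inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .exceptions import ConfigurationError, DataError
from .preprocessing import Segment, SegmentSet

POLICIES = ("strict", "lenient")

#: study table columns -> (lock scheme, condition)
TABLE_COLUMNS: Dict[str, Tuple[str, str]] = {
    "BEWG": ("emg", "foot_exec"),
    "MFOT": ("stimulus", "foot_exec"),
    "MHND": ("stimulus", "hand_exec"),
    "IFOT": ("stimulus", "foot_imag"),
    "IHND": ("stimulus", "hand_imag"),
    "REST": ("stimulus", "rest"),
}


@dataclass(frozen=True)
class ArtifactThresholds:
    bad_channel_uV: float = 200.0
    bad_channel_window_s: float = 0.1
    ocular_uV: float = 100.0
    ocular_method: str = "window_ptp"   # or "absolute": |amplitude| > threshold

    def __post_init__(self) -> None:
        if min(self.bad_channel_uV, self.bad_channel_window_s, self.ocular_uV) <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.ocular_method not in ("window_ptp", "absolute"):
            raise ConfigurationError("ocular_method must be window_ptp or absolute")


def moving_window_ptp(x: np.ndarray, window: int) -> np.ndarray:
    """Peak-to-peak range of every fully-contained length-``window`` window.

    Dense scan, stride 1, via running max/min filters; the exhaustive
    O(n*w) scan is kept as the test oracle.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window > x.size:
        raise ConfigurationError("window must be in [1, len(x)]")
    hi = maximum_filter1d(x, size=window, mode="nearest")
    lo = minimum_filter1d(x, size=window, mode="nearest")
    # filters center the window; valid positions are those fully inside
    rng = hi - lo
    left = window // 2
    return rng[left:left + (x.size - window + 1)]


def max_window_ptp(x: np.ndarray, window: int) -> float:
    return float(moving_window_ptp(x, window).max())


def detect_bad_channels(seg: Segment, channel_labels: List[str],
                        channel_roles: Mapping[str, str],
                        thresholds: ArtifactThresholds = ArtifactThresholds(),
                        sampling_rate: float | None = None) -> Set[str]:
    """EEG-role channels whose max 100 ms windowed range exceeds the threshold."""
    fs = sampling_rate if sampling_rate is not None else seg.annotations.get("fs")
    if fs is None:
        raise ConfigurationError("sampling_rate required")
    w = int(round(thresholds.bad_channel_window_s * fs))
    if w > seg.n_samples:
        raise ConfigurationError("window longer than segment")
    bad: Set[str] = set()
    for i, label in enumerate(channel_labels):
        if channel_roles.get(label) != "eeg":
            continue
        if max_window_ptp(seg.data[i], w) > thresholds.bad_channel_uV:
            bad.add(label)
    return bad


def detect_ocular(seg: Segment, channel_labels: List[str],
                  thresholds: ArtifactThresholds = ArtifactThresholds(),
                  sampling_rate: float | None = None) -> Dict[str, bool]:
    """Blink (VEOG) and eye-movement (HEOG) flags at the ocular threshold."""
    for ch in ("VEOG", "HEOG"):
        if ch not in channel_labels:
            raise DataError(f"EOG channel {ch!r} missing")
    flags = {}
    for name, ch in (("blink", "VEOG"), ("eye_movement", "HEOG")):
        x = seg.data[channel_labels.index(ch)]
        if thresholds.ocular_method == "absolute":
            flags[name] = bool(np.abs(x).max() > thresholds.ocular_uV)
        else:
            if sampling_rate is None:
                raise ConfigurationError("sampling_rate required")
            w = int(round(thresholds.bad_channel_window_s * sampling_rate))
            w = min(w, seg.n_samples)
            flags[name] = bool(max_window_ptp(x, w) > thresholds.ocular_uV)
    return flags


@dataclass
class ArtifactReport:
    """Per-policy inclusion accounting with per-segment reasons."""

    policy: str
    target_channel: str
    lock: str
    per_condition: Dict[str, Dict[str, int]] = field(default_factory=dict)
    reasons: List[Tuple[str, int, Tuple[str, ...]]] = field(default_factory=list)

    def included(self, condition: str) -> int:
        return self.per_condition.get(condition, {}).get("included", 0)

    def total(self, condition: str) -> int:
        return self.per_condition.get(condition, {}).get("total", 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"condition": c, **counts} for c, counts in self.per_condition.items()]
        return pd.DataFrame(rows)


def annotate_segments(segments: SegmentSet,
                      thresholds: ArtifactThresholds = ArtifactThresholds()) -> SegmentSet:
    """Fill per-segment artifact annotations (bad channels, blink, eye movement)."""
    out = segments.copy()
    for s in out.segments:
        s.annotations["bad_channels"] = detect_bad_channels(
            s, out.channel_labels, out.channel_roles, thresholds, out.sampling_rate)
        s.annotations.update(detect_ocular(s, out.channel_labels, thresholds,
                                           out.sampling_rate))
    return out


def apply_policy(segments: SegmentSet, policy: str, target_channel: str = "Pz",
                 thresholds: ArtifactThresholds = ArtifactThresholds(),
                 ) -> Tuple[SegmentSet, ArtifactReport]:
    """Exclude artifact-contaminated segments under the chosen policy.

    strict: drop on blink OR eye movement OR bad target channel;
    lenient: drop only on a bad target channel.
    """
    if policy not in POLICIES:
        raise ConfigurationError(f"unknown policy {policy!r}")
    annotated = annotate_segments(segments, thresholds)
    report = ArtifactReport(policy=policy, target_channel=target_channel,
                            lock=segments.lock)
    kept = []
    for s in annotated.segments:
        why: List[str] = []
        if target_channel in s.annotations["bad_channels"]:
            why.append(f"{target_channel}_bad")
        if policy == "strict":
            if s.annotations["blink"]:
                why.append("blink")
            if s.annotations["eye_movement"]:
                why.append("eye_movement")
        counts = report.per_condition.setdefault(
            s.condition, {"included": 0, "excluded": 0, "total": 0})
        counts["total"] += 1
        if why:
            counts["excluded"] += 1
            report.reasons.append((s.condition, s.trial_index, tuple(why)))
        else:
            counts["included"] += 1
            kept.append(s)
    out = annotated.copy()
    out.segments = [Segment(s.data.copy(), s.lock, s.t0_sample, s.condition,
                            s.trial_index, dict(s.annotations)) for s in kept]
    out.provenance["artifact_policy"] = policy
    return out, report


def tabulate_inclusion(subject: str, reports: List[ArtifactReport]) -> pd.DataFrame:
    """One study-table row: included counts per condition/lock column.

    Columns follow the study layout — BEWG (EMG-locked foot execution), MFOT,
    MHND, IFOT, IHND, REST (stimulus-locked).  ``attrs["totals"]`` carries the
    recorded-segment totals behind each cell.
    """
    row: Dict[str, int] = {}
    totals: Dict[str, int] = {}
    for col, (lock, cond) in TABLE_COLUMNS.items():
        value = 0
        total = 0
        for rep in reports:
            if rep.lock == lock and cond in rep.per_condition:
                value = rep.included(cond)
                total = rep.total(cond)
        row[col] = value
        totals[col] = total
    frame = pd.DataFrame([row], index=[subject])
    frame.attrs["totals"] = totals
    return frame


def format_inclusion_row(frame: pd.DataFrame, expected_total: int = 25) -> pd.DataFrame:
    """Render cells as 'n (N)' when the recorded total differs from the default."""
    totals = frame.attrs.get("totals", {})
    out = frame.astype(object).copy()
    for col in out.columns:
        n = int(frame[col].iloc[0])
        total = totals.get(col, expected_total)
        out[col] = f"{n} ({total})" if total != expected_total else str(n)
    return out


__all__ = [
    "POLICIES", "TABLE_COLUMNS", "ArtifactThresholds", "ArtifactReport",
    "moving_window_ptp", "max_window_ptp", "detect_bad_channels", "detect_ocular",
    "annotate_segments", "apply_policy", "tabulate_inclusion", "format_inclusion_row",
]
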