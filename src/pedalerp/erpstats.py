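"""Trial averaging, ERP features, and the single-subject Monte-Carlo permutation test.

The statistical question is single-subject and trial-level: do the epochs of
an experimental condition differ from the rest-condition epochs on one channel
(Pz) at any time point?  The test follows the nonparametric cluster framework:
a per-sample two-sample statistic is thresholded, contiguous supra-threshold
samples of equal sign form clusters scored by their summed statistic (cluster
mass), and the Monte-Carlo null of the maximum |mass| is built from random
relabelings of the trials.  When the number of distinct relabelings does not
exceed the requested partitions the test switches to exact enumeration.

`ErpPermutationTest` is the model object; `fit()` returns a
`PermutationResult` with clusters, p-values, significant intervals and a
`summary()` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .exceptions import ConfigurationError, DataError, EmptyInputError
from .preprocessing import SegmentSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ERP container and features


@dataclass
class Erp:
    """Per-channel trial average for one condition."""

    data: np.ndarray              # (n_channels, n_samples), uV
    n_trials: int
    condition: str
    lock: str
    reference: str
    sampling_rate: float
    channel_labels: List[str]
    t0_sample: int                # lock event position within the epoch

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise DataError(f"channel {label!r} not present") from None

    def time(self) -> np.ndarray:
        """Time axis in seconds relative to the lock event."""
        return (np.arange(self.data.shape[1]) - self.t0_sample) / self.sampling_rate

    def _window_slice(self, window: Tuple[float, float]) -> slice:
        a = self.t0_sample + int(round(window[0] * self.sampling_rate))
        b = self.t0_sample + int(round(window[1] * self.sampling_rate))
        if a < 0 or b > self.data.shape[1] or b <= a:
            raise ConfigurationError(f"window {window} outside segment")
        return slice(a, b)

    def plot(self, channel: str = "Pz", ax=None):
        """Plot the averaged waveform of one channel (lock event at 0 s)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time(), self.channel(channel), lw=1)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time relative to lock (s)")
        ax.set_ylabel("amplitude (uV)")
        ax.set_title(f"{self.condition} ({self.lock}-locked, n={self.n_trials})")
        return ax


def average(segments: SegmentSet, condition: str) -> Erp:
    """Pointwise mean across the included segments of one condition."""
    segs = segments.by_condition(condition)
    if not segs:
        raise EmptyInputError(f"no segments for condition {condition!r}")
    data = np.mean([s.data for s in segs], axis=0)
    return Erp(data=data, n_trials=len(segs), condition=condition,
               lock=segments.lock, reference=segments.reference,
               sampling_rate=segments.sampling_rate,
               channel_labels=list(segments.channel_labels),
               t0_sample=segs[0].t0_sample)


def count_peaks(erp: Erp, channel: str, window: Tuple[float, float] = (0.0, 6.0),
                prominence_fraction: float = 0.15,
                min_prominence_uv: float = 1.0) -> int:
    """Positive local maxima above a prominence floor within the window.

    The floor is ``prominence_fraction`` of the windowed peak-to-peak range
    (never below ``min_prominence_uv``), so small noise ripples riding on the
    oscillation do not count as movement peaks.
    """
    x = erp.channel(channel)[erp._window_slice(window)]
    ptp = float(x.max() - x.min())
    prom = max(prominence_fraction * ptp, min_prominence_uv)
    peaks, _ = sps.find_peaks(x, height=0.0, prominence=prom)
    return int(peaks.size)


def dominant_frequency(erp: Erp, channel: str,
                       window: Tuple[float, float] = (0.0, 6.0),
                       band: Tuple[float, float] = (0.25, 15.0)) -> float:
    """Frequency (Hz) of maximum spectral power over the window.

    Linear detrend, Hann taper, rFFT without zero padding: resolution is
    1/window-length Hz (1/6 Hz for the 6 s task window).
    """
    if window[1] - window[0] < 2.0:
        raise ConfigurationError("dominant_frequency needs a window of >= 2 s")
    x = erp.channel(channel)[erp._window_slice(window)]
    x = sps.detrend(x, type="linear") * np.hanning(x.size)
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / erp.sampling_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ConfigurationError("no frequency bins inside the search band")
    return float(freqs[mask][np.argmax(power[mask])])


def peak_amplitude(erp: Erp, channel: str,
                   window: Tuple[float, float] = (0.0, 6.0)) -> float:
    """Signed extremum of largest magnitude within the window (uV)."""
    x = erp.channel(channel)[erp._window_slice(window)]
    return float(x[np.argmax(np.abs(x))])


# ---------------------------------------------------------------------------
# permutation test


@dataclass(frozen=True)
class PermutationSpec:
    """Settings of the trial-level Monte-Carlo permutation test.

    Defaults follow the study: alpha 0.05, 2000 random partitions; the
    per-sample statistic and the multiple-comparison correction are design
    choices (two-sided two-sample t with cluster-mass correction by default).
    """

    n_partitions: int = 2000
    alpha: float = 0.05
    statistic: str = "per_sample_t"        # or "per_sample_mean_diff"
    tail: str = "two_sided"
    cluster_forming_alpha: float = 0.05
    correction: str = "cluster_mass"       # or "pointwise" (max-statistic)
    seed: int | None = None
    force_monte_carlo: bool = False        # skip the exact-enumeration switch

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ConfigurationError("n_partitions must be >= 1")
        if not 0 < self.alpha < 1 or not 0 < self.cluster_forming_alpha < 1:
            raise ConfigurationError("alpha levels must be in (0, 1)")
        if self.statistic not in ("per_sample_t", "per_sample_mean_diff"):
            raise ConfigurationError(f"unknown statistic {self.statistic!r}")
        if self.tail != "two_sided":
            raise ConfigurationError("only two_sided is implemented")
        if self.correction not in ("cluster_mass", "pointwise"):
            raise ConfigurationError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p_value: float


def _t_track(s1: np.ndarray, q1: np.ndarray, n1: int,
             s2: np.ndarray, q2: np.ndarray, n2: int) -> np.ndarray:
    """Pooled-variance two-sample t from per-group sums and sums of squares."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = (q1 - n1 * m1 ** 2) / (n1 - 1)
    v2 = (q2 - n2 * m2 ** 2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(np.maximum(sp2, 1e-300) * (1.0 / n1 + 1.0 / n2))
    return (m1 - m2) / denom


def _clusters_1d(track: np.ndarray, threshold_track: np.ndarray,
                 tc: float) -> List[Tuple[int, int, float]]:
    """(start, stop, mass) of signed supra-threshold runs; mass sums ``track``."""
    sign = np.zeros(track.size, dtype=np.int8)
    sign[threshold_track > tc] = 1
    sign[threshold_track < -tc] = -1
    out: List[Tuple[int, int, float]] = []
    boundaries = np.flatnonzero(np.diff(sign)) + 1
    edges = np.concatenate([[0], boundaries, [sign.size]])
    for a, b in zip(edges[:-1], edges[1:]):
        if sign[a] != 0:
            out.append((int(a), int(b), float(track[a:b].sum())))
    return out


def _max_cluster_mass(track_mat: np.ndarray, thresh_mat: np.ndarray,
                      tc: float) -> np.ndarray:
    """Per row: max |cluster mass|; 0 when a row has no supra-threshold sample.

    Rows are separated by a sentinel zero column so all runs can be found in
    one flattened pass.
    """
    p, t = track_mat.shape
    sign = np.zeros((p, t + 1), dtype=np.int8)
    sign[:, :t][thresh_mat > tc] = 1
    sign[:, :t][thresh_mat < -tc] = -1
    vals = np.zeros((p, t + 1))
    vals[:, :t] = np.where(sign[:, :t] != 0, track_mat, 0.0)
    flat_s = sign.ravel()
    flat_v = vals.ravel()
    csum = np.concatenate([[0.0], np.cumsum(flat_v)])
    boundaries = np.flatnonzero(np.diff(flat_s)) + 1
    edges = np.concatenate([[0], boundaries, [flat_s.size]])
    starts, stops = edges[:-1], edges[1:]
    live = flat_s[starts] != 0
    starts, stops = starts[live], stops[live]
    masses = np.abs(csum[stops] - csum[starts])
    rows = starts // (t + 1)
    out = np.zeros(p)
    np.maximum.at(out, rows, masses)
    return out


@dataclass
class PermutationResult:
    """Observed statistic track, cluster inventory and significant intervals."""

    channel: str
    times: np.ndarray                 # s relative to lock
    observed: np.ndarray              # per-sample statistic track
    clusters: List[Cluster]
    spec: PermutationSpec
    seed: int | None
    n_cond: int
    n_rest: int
    n_partitions_used: int
    exact: bool
    cluster_forming_threshold: float

    @property
    def significant_intervals(self) -> List[Tuple[float, float]]:
        iv = sorted((c.start_s, c.end_s) for c in self.clusters
                    if c.p_value < self.spec.alpha)
        merged: List[Tuple[float, float]] = []
        for a, b in iv:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start_s": c.start_s, "end_s": c.end_s, "mass": c.mass,
              "p_value": c.p_value} for c in self.clusters])

    def summary(self) -> str:
        lines = [
            "Trial-level Monte-Carlo permutation test",
            "=" * 56,
            f"channel: {self.channel}    statistic: {self.spec.statistic}",
            f"trials: {self.n_cond} condition vs {self.n_rest} rest",
            f"partitions: {self.n_partitions_used}"
            f" ({'exact enumeration' if self.exact else 'Monte-Carlo'})",
            f"cluster-forming |t| > {self.cluster_forming_threshold:.3f}"
            f" (alpha={self.spec.cluster_forming_alpha})",
            f"alpha: {self.spec.alpha}",
            "-" * 56,
        ]
        if self.clusters:
            lines.append(f"{'start_s':>8} {'end_s':>8} {'mass':>12} {'p':>8}")
            for c in sorted(self.clusters, key=lambda c: c.start_s):
                star = " *" if c.p_value < self.spec.alpha else ""
                lines.append(f"{c.start_s:8.3f} {c.end_s:8.3f} "
                             f"{c.mass:12.2f} {c.p_value:8.4f}{star}")
        else:
            lines.append("no supra-threshold clusters")
        lines.append("-" * 56)
        sig = self.significant_intervals
        lines.append("significant intervals: "
                     + (", ".join(f"[{a:.3f}, {b:.3f}] s" for a, b in sig)
                        if sig else "none"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Statistic track with significant intervals shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.observed, lw=1)
        tc = self.cluster_forming_threshold
        ax.axhline(tc, color="gray", ls="--", lw=0.5)
        ax.axhline(-tc, color="gray", ls="--", lw=0.5)
        for a, b in self.significant_intervals:
            ax.axvspan(a, b, color="0.8", zorder=0)
        ax.set_xlabel("time relative to lock (s)")
        ax.set_ylabel(self.spec.statistic)
        return ax


class ErpPermutationTest:
    """Model object: condition epochs vs rest epochs on one channel.

    Accepts either two `SegmentSet`s (with the channel to test) or two raw
    ``(n_trials, n_samples)`` arrays.  All epochs are mean-corrected internally
    (each trial's own mean over the full epoch is removed) before the statistic
    is computed.
    """

    def __init__(self, cond, rest, channel: str = "Pz",
                 spec: PermutationSpec = PermutationSpec(),
                 condition: str | None = None,
                 sampling_rate: float | None = None,
                 t0_sample: int = 0):
        if isinstance(cond, SegmentSet):
            condition = condition or (cond.conditions[0] if cond.conditions else None)
            if condition is None:
                raise EmptyInputError("condition segment set is empty")
            x1 = cond.condition_array(condition, channel)
            x2 = rest.condition_array("rest", channel)
            sampling_rate = cond.sampling_rate
            t0_sample = cond.segments[0].t0_sample if cond.segments else 0
        else:
            x1 = np.asarray(cond, dtype=float)
            x2 = np.asarray(rest, dtype=float)
            if sampling_rate is None:
                raise ConfigurationError("sampling_rate required with raw arrays")
        if x1.ndim != 2 or x2.ndim != 2:
            raise DataError("epochs must be 2-D (trials x samples)")
        if x1.shape[0] < 2 or x2.shape[0] < 2:
            raise EmptyInputError("need at least 2 trials per group")
        if x1.shape[1] != x2.shape[1]:
            raise DataError("condition and rest epochs differ in length")
        # mean-correction: remove each trial's own epoch mean
        self.x1 = x1 - x1.mean(axis=1, keepdims=True)
        self.x2 = x2 - x2.mean(axis=1, keepdims=True)
        self.channel = channel
        self.spec = spec
        self.sampling_rate = float(sampling_rate)
        self.t0_sample = int(t0_sample)

    # -- internals ---------------------------------------------------------

    def _tracks(self, part: np.ndarray, X: np.ndarray, Xsq: np.ndarray,
                tot: np.ndarray, tot_sq: np.ndarray, n1: int, n2: int
                ) -> Tuple[np.ndarray, np.ndarray]:
        """(statistic track, t track) for each partition row (indicator matrix)."""
        s1 = part @ X
        q1 = part @ Xsq
        s2, q2 = tot - s1, tot_sq - q1
        t = _t_track(s1, q1, n1, s2, q2, n2)
        if self.spec.statistic == "per_sample_mean_diff":
            return s1 / n1 - s2 / n2, t
        return t, t

    def fit(self, seed: int | None = None) -> PermutationResult:
        spec = self.spec
        seed = spec.seed if seed is None else seed
        n1, n2 = self.x1.shape[0], self.x2.shape[0]
        n, t_len = n1 + n2, self.x1.shape[1]
        X = np.vstack([self.x1, self.x2])
        Xsq = X ** 2
        tot, tot_sq = X.sum(axis=0), Xsq.sum(axis=0)
        df = n - 2
        tc = float(sstats.t.ppf(1.0 - spec.cluster_forming_alpha / 2.0, df))

        obs_ind = np.zeros((1, n))
        obs_ind[0, :n1] = 1.0
        obs_track, obs_t = self._tracks(obs_ind, X, Xsq, tot, tot_sq, n1, n2)
        obs_track, obs_t = obs_track[0], obs_t[0]

        n_distinct = comb(n, n1)
        exact = n_distinct <= spec.n_partitions and not spec.force_monte_carlo
        if exact:
            logger.info("switching to exact enumeration (%d partitions)", n_distinct)
            rows = np.zeros((n_distinct, n))
            for r, sel in enumerate(combinations(range(n), n1)):
                rows[r, list(sel)] = 1.0
            n_used = n_distinct
        else:
            rng = np.random.default_rng(seed)
            rows = np.zeros((spec.n_partitions, n))
            for r in range(spec.n_partitions):
                rows[r, rng.choice(n, size=n1, replace=False)] = 1.0
            n_used = spec.n_partitions

        null_track, null_t = self._tracks(rows, X, Xsq, tot, tot_sq, n1, n2)

        if spec.correction == "pointwise":
            null_max = np.abs(null_track).max(axis=1)
            crit = float(np.quantile(null_max, 1.0 - spec.alpha))
            runs = _clusters_1d(obs_track, obs_track, crit)
            clusters = []
            for a, b, mass in runs:
                peak = float(np.abs(obs_track[a:b]).max())
                ge = int((null_max >= peak).sum())
                p = ge / n_used if exact else (1 + ge) / (n_used + 1)
                clusters.append((a, b, mass, p))
        else:
            null_max = _max_cluster_mass(null_track, null_t, tc)
            runs = _clusters_1d(obs_track, obs_t, tc)
            clusters = []
            for a, b, mass in runs:
                ge = int((null_max >= abs(mass)).sum())
                p = ge / n_used if exact else (1 + ge) / (n_used + 1)
                clusters.append((a, b, mass, p))

        fs = self.sampling_rate
        times = (np.arange(t_len) - self.t0_sample) / fs
        cluster_objs = [Cluster(start_s=float(times[a]),
                                end_s=float(times[b - 1] + 1.0 / fs),
                                mass=mass, p_value=p)
                        for a, b, mass, p in clusters]
        return PermutationResult(
            channel=self.channel, times=times, observed=obs_track,
            clusters=cluster_objs, spec=spec, seed=seed,
            n_cond=n1, n_rest=n2, n_partitions_used=n_used, exact=exact,
            cluster_forming_threshold=tc,
        )


def permutation_test(cond, rest, channel: str = "Pz",
                     spec: PermutationSpec = PermutationSpec(),
                     seed: int | None = None, **kwargs) -> PermutationResult:
    """Functional wrapper around `ErpPermutationTest(...).fit(seed)`."""
    return ErpPermutationTest(cond, rest, channel=channel, spec=spec, **kwargs).fit(seed)


__all__ = [
    "Erp", "average", "count_peaks", "dominant_frequency", "peak_amplitude",
    "PermutationSpec", "Cluster", "PermutationResult", "ErpPermutationTest",
    "permutation_test",
]
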