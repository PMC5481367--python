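"""EDF reader/writer and the events sidecar TSV.

Continuous recordings are exchanged as 16-bit EDF (European Data Format,
1-second data records) plus a tab-separated events sidecar with columns
``onset_sample``, ``kind``, ``condition``, ``trial_index``.  EDF quantizes to
16 bits over the per-channel physical range; the round-trip error is bounded
by half a quantization step.  The writer is self-contained; any EDF reader
(e.g. MNE-Python) can open the files.

The header's recording field carries ``subject=... seed=... ref=...`` so a
round trip preserves provenance; the 44-byte reserved field carries the true
sample count so recordings padded to a whole number of records are trimmed on
read.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .exceptions import ConfigurationError, ParseError
from .paradigm import DEFAULT_ROLES, EVENT_KINDS, EventMarker, Recording

_DIG_MAX = 32767
_DIG_MIN = -32767


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: Recording) -> Path:
    """Write a plain 16-bit EDF file with 1 s data records."""
    path = Path(path)
    fs = recording.sampling_rate
    if not math.isclose(fs, round(fs)):
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    sig = recording.signal
    n_ch, n_samples = sig.shape
    n_rec = max(int(math.ceil(n_samples / fs)), 1)
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samples] = sig

    pmax = np.maximum(np.abs(padded).max(axis=1), 1.0) * (1 + 1e-9)
    scale = pmax / _DIG_MAX
    digital = np.clip(np.round(padded / scale[:, None]), _DIG_MIN, _DIG_MAX
                      ).astype("<i2")

    subject = recording.meta.get("subject", "X")
    seed = recording.meta.get("seed", "")
    rec_field = f"subject={subject} seed={seed} ref={recording.reference}"

    header = b"".join([
        _ascii("0", 8),
        _ascii(str(subject), 80),
        _ascii(rec_field, 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 * (1 + n_ch)), 8),
        _ascii(f"NS={n_samples}", 44),
        _ascii(str(n_rec), 8),
        _ascii("1", 8),
        _ascii(str(n_ch), 4),
    ])
    labels = [_ascii(c, 16) for c in recording.channel_labels]
    fields = [
        b"".join(labels),
        b"".join(_ascii("", 80) for _ in range(n_ch)),               # transducer
        b"".join(_ascii("uV", 8) for _ in range(n_ch)),
        b"".join(_ascii(f"{-p:.6g}"[:8], 8) for p in pmax),          # phys min
        b"".join(_ascii(f"{p:.6g}"[:8], 8) for p in pmax),           # phys max
        b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_ascii("", 80) for _ in range(n_ch)),               # prefilter
        b"".join(_ascii(str(fs), 8) for _ in range(n_ch)),
        b"".join(_ascii("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(block)
        # records: channel-major within each 1 s record
        view = digital.reshape(n_ch, n_rec, fs)
        for r in range(n_rec):
            fh.write(view[:, r, :].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (or any plain 16-bit EDF)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ParseError(f"{path}: truncated EDF header")
        try:
            rec_field = head[88:168].decode("ascii").strip()
            reserved = head[192:236].decode("ascii").strip()
            n_rec = int(head[236:244])
            rec_dur = float(head[244:252])
            n_ch = int(head[252:256])
        except (UnicodeDecodeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed EDF header ({exc})") from exc
        sig_head = fh.read(256 * n_ch)
        if len(sig_head) < 256 * n_ch:
            raise ParseError(f"{path}: truncated signal headers")

        def field(offset: int, width: int) -> List[str]:
            base = offset * n_ch
            return [sig_head[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_ch)]

        labels = field(0, 16)
        pmin = np.array([float(v) for v in field(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in field(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in field(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in field(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in field(16 + 80 + 8 + 32 + 80, 8)]

        raw = fh.read()
    per_rec = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", count=n_rec * per_rec)
    data = data.reshape(n_rec, per_rec)
    sig = np.empty((n_ch, n_rec * spr[0]))
    col = 0
    for i, s in enumerate(spr):
        chunk = data[:, col:col + s].reshape(-1).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        sig[i] = (chunk - dmin[i]) * gain + pmin[i]
        col += s

    if reserved.startswith("NS="):
        sig = sig[:, :int(reserved[3:])]
    meta = {}
    reference = "unknown"
    for tok in rec_field.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            if k == "ref":
                reference = v
            elif k == "seed":
                meta["seed"] = int(v) if v else None
            else:
                meta[k] = v
    fs = spr[0] / rec_dur
    roles = {c: DEFAULT_ROLES.get(c, "eeg") for c in labels}
    return Recording(signal=sig, sampling_rate=fs, channel_labels=labels,
                     channel_roles=roles, reference=reference, events=[],
                     meta=meta)


# ---------------------------------------------------------------------------
# events sidecar


def write_events_tsv(path: str | Path, events: List[EventMarker]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_sample", "kind", "condition", "trial_index"])
        for e in events:
            w.writerow([e.onset_sample, e.kind, e.condition, e.trial_index])
    return path


def read_events_tsv(path: str | Path) -> List[EventMarker]:
    path = Path(path)
    events: List[EventMarker] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        return []
    header = rows[0]
    if header != ["onset_sample", "kind", "condition", "trial_index"]:
        raise ParseError(f"{path}: unexpected header {header!r}")
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        try:
            onset, kind, cond, idx = row
            onset_i, idx_i = int(onset), int(idx)
        except ValueError as exc:
            raise ParseError(f"{path}: row {lineno}: malformed ({exc})") from exc
        if kind not in EVENT_KINDS:
            raise ParseError(f"{path}: row {lineno}: unknown kind {kind!r}")
        events.append(EventMarker(onset_i, kind, cond, idx_i))
    return events


# ---------------------------------------------------------------------------
# combined recording round-trip


def recording_paths(basename: str | Path) -> Tuple[Path, Path]:
    base = Path(basename)
    if base.suffix == ".edf":
        base = base.with_suffix("")
    return base.with_suffix(".edf"), base.parent / (base.name + "_events.tsv")


def write_recording(recording: Recording, basename: str | Path) -> Tuple[Path, Path]:
    """Write ``<basename>.edf`` and ``<basename>_events.tsv``."""
    edf_path, ev_path = recording_paths(basename)
    write_edf(edf_path, recording)
    write_events_tsv(ev_path, recording.events)
    return edf_path, ev_path


def read_recording(basename: str | Path) -> Recording:
    edf_path, ev_path = recording_paths(basename)
    rec = read_edf(edf_path)
    if ev_path.exists():
        rec.events = read_events_tsv(ev_path)
        rec.__post_init__()
    return rec


__all__ = [
    "write_edf", "read_edf", "write_events_tsv", "read_events_tsv",
    "write_recording", "read_recording", "recording_paths",
]
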