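"""End-to-end study orchestration: simulate -> preprocess -> reject -> ERP -> test.

`run_study` reproduces the full per-subject analysis for each configured
subject profile, under both locking schemes (stimulus for all conditions,
EMG for foot execution) and both artifact policies (strict, lenient), and
returns a `StudyReport` results object whose JSON payload is byte-identical
for identical (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

from . import edfplus
from .artifacts import (
    ArtifactReport,
    ArtifactThresholds,
    apply_policy,
    tabulate_inclusion,
)
from .erpstats import (
    ErpPermutationTest,
    PermutationSpec,
    average,
    count_peaks,
    dominant_frequency,
    peak_amplitude,
)
from .exceptions import ConfigurationError, EmptyInputError
from .paradigm import ParadigmSpec
from .preprocessing import (
    FilterSpec,
    SegmentSet,
    apply_filters,
    baseline_correct,
    detect_emg_onsets,
    rereference_segments,
    segment,
)
from .simulate import SubjectProfile, preset_profiles, synthesize_recording

logger = logging.getLogger(__name__)

TEST_CONDITIONS = ("foot_exec", "hand_exec", "foot_imag", "hand_imag")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one full analysis run."""

    paradigm: ParadigmSpec = ParadigmSpec()
    profiles: Tuple[str, ...] = ("healthy_responder",)
    filter_spec: FilterSpec = FilterSpec()
    thresholds: ArtifactThresholds = ArtifactThresholds()
    permutation: PermutationSpec = PermutationSpec()
    policies: Tuple[str, ...] = ("strict", "lenient")
    locks: Tuple[str, ...] = ("stimulus", "emg")
    target_channel: str = "Pz"
    seed: int = 0
    out_dir: str | None = None

    def resolve_profiles(self) -> Dict[str, SubjectProfile]:
        presets = preset_profiles()
        out: Dict[str, SubjectProfile] = {}
        for p in self.profiles:
            if p not in presets:
                raise ConfigurationError(f"unknown profile preset {p!r}")
            out[p] = presets[p]
        return out

    def canonical(self) -> Dict[str, object]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def hash(self) -> str:
        payload = json.dumps(self.canonical(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subject_seed(seed: int, index: int) -> int:
    """Stable per-subject sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyReport:
    """Per-subject inclusion tables, ERP features and permutation outcomes."""

    config_hash: str
    seed: int
    subjects: Dict[str, Dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "subjects": self.subjects},
            sort_keys=True, indent=1)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    def summary(self) -> str:
        lines = [f"Study report (config {self.config_hash}, seed {self.seed})"]
        for subj, payload in self.subjects.items():
            lines.append(f"\n== {subj} ==")
            for policy, block in payload["policies"].items():
                sig = {key: val["significant_intervals"]
                       for key, val in block["permutation"].items()
                       if val is not None}
                lines.append(f"  [{policy}] inclusion: {block['inclusion']}")
                for key, intervals in sig.items():
                    mark = "SIGNIFICANT" if intervals else "n.s."
                    lines.append(f"    {key} vs rest: {mark} {intervals}")
        return "\n".join(lines)


def _erp_features(segments: SegmentSet, condition: str, channel: str,
                  window: Tuple[float, float]) -> Dict | None:
    try:
        erp = average(segments, condition)
    except EmptyInputError:
        return None
    return {
        "n_trials": erp.n_trials,
        "peak_amplitude_uV": round(peak_amplitude(erp, channel, window), 4),
        "n_peaks": count_peaks(erp, channel, window),
        "dominant_frequency_hz": round(dominant_frequency(erp, channel, window), 4),
    }


def _perm_entry(cond_set: SegmentSet, rest_set: SegmentSet, condition: str,
                channel: str, spec: PermutationSpec, seed: int) -> Dict | None:
    if len(cond_set.by_condition(condition)) < 2 or len(rest_set.by_condition("rest")) < 2:
        return None
    result = ErpPermutationTest(cond_set, rest_set, channel=channel, spec=spec,
                                condition=condition).fit(seed)
    return {
        "n_cond": result.n_cond,
        "n_rest": result.n_rest,
        "min_p": round(result.min_p, 6),
        "exact": result.exact,
        "clusters": [[round(c.start_s, 4), round(c.end_s, 4),
                      round(c.mass, 4), round(c.p_value, 6)]
                     for c in result.clusters],
        "significant_intervals": [[round(a, 4), round(b, 4)]
                                  for a, b in result.significant_intervals],
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full pipeline for every configured subject profile."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    window = (0.0, config.paradigm.task_duration)
    report = StudyReport(config_hash=config.hash(), seed=config.seed)

    for i, (name, profile) in enumerate(config.resolve_profiles().items()):
        sub_seed = _subject_seed(config.seed, i)
        logger.info("subject %s: simulating (seed %d)", name, sub_seed)
        rec = synthesize_recording(config.paradigm, profile, sub_seed)
        if out_dir:
            edfplus.write_recording(rec, out_dir / name)
        filt = apply_filters(rec, config.filter_spec)
        onsets = detect_emg_onsets(filt)
        filt.events = sorted(filt.events + onsets)

        locked: Dict[str, SegmentSet] = {}
        for lock in config.locks:
            locked[lock] = baseline_correct(segment(filt, lock))

        subject_block: Dict[str, Dict] = {
            "seed": sub_seed,
            "n_emg_onsets": len(onsets),
            "dropped": {lock: list(map(list, locked[lock].dropped))
                        for lock in config.locks},
            "policies": {},
        }
        for policy in config.policies:
            included: Dict[str, SegmentSet] = {}
            reports: List[ArtifactReport] = []
            for lock in config.locks:
                kept, rep = apply_policy(locked[lock], policy,
                                         config.target_channel, config.thresholds)
                included[lock] = rereference_segments(kept, "common_average")
                reports.append(rep)
            table = tabulate_inclusion(name, reports)
            block: Dict[str, Dict] = {
                "inclusion": {c: int(table[c].iloc[0]) for c in table.columns},
                "inclusion_totals": dict(table.attrs["totals"]),
                "erp_features": {},
                "permutation": {},
            }
            stim = included.get("stimulus")
            emg = included.get("emg")
            if stim is not None:
                for cond in config.paradigm.conditions:
                    block["erp_features"][f"stimulus:{cond}"] = _erp_features(
                        stim, cond, config.target_channel, window)
                for j, cond in enumerate(TEST_CONDITIONS):
                    if cond not in config.paradigm.conditions:
                        continue
                    block["permutation"][f"stimulus:{cond}"] = _perm_entry(
                        stim, stim, cond, config.target_channel,
                        config.permutation, _subject_seed(sub_seed, 100 + j))
            if emg is not None and stim is not None:
                block["erp_features"]["emg:foot_exec"] = _erp_features(
                    emg, "foot_exec", config.target_channel, window)
                block["permutation"]["emg:foot_exec"] = _perm_entry(
                    emg, stim, "foot_exec", config.target_channel,
                    config.permutation, _subject_seed(sub_seed, 200))
            subject_block["policies"][policy] = block
        report.subjects[name] = subject_block

    if out_dir:
        report.save(out_dir / "report.json")
    return report


# ---------------------------------------------------------------------------
# segment serialization (per-segment matrices + JSON manifest)


def save_segments(segments: SegmentSet, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"seg{i:04d}": s.data for i, s in enumerate(segments.segments)}
    np.savez(directory / "segments.npz", **arrays)
    manifest = {
        "lock": segments.lock,
        "sampling_rate": segments.sampling_rate,
        "channel_labels": list(segments.channel_labels),
        "channel_roles": dict(segments.channel_roles),
        "reference": segments.reference,
        "provenance": segments.provenance,
        "dropped": list(map(list, segments.dropped)),
        "segments": [{"key": f"seg{i:04d}", "condition": s.condition,
                      "trial_index": s.trial_index, "t0_sample": s.t0_sample,
                      "annotations": {k: sorted(v) if isinstance(v, set) else v
                                      for k, v in s.annotations.items()}}
                     for i, s in enumerate(segments.segments)],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_segments(directory: str | Path) -> SegmentSet:
    from .preprocessing import Segment

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    arrays = np.load(directory / "segments.npz")
    segs = []
    for entry in manifest["segments"]:
        ann = dict(entry["annotations"])
        if "bad_channels" in ann:
            ann["bad_channels"] = set(ann["bad_channels"])
        segs.append(Segment(arrays[entry["key"]], manifest["lock"],
                            entry["t0_sample"], entry["condition"],
                            entry["trial_index"], ann))
    return SegmentSet(
        segments=segs, lock=manifest["lock"],
        sampling_rate=manifest["sampling_rate"],
        channel_labels=manifest["channel_labels"],
        channel_roles=manifest["channel_roles"],
        reference=manifest["reference"], provenance=manifest["provenance"],
        dropped=[tuple(d) for d in manifest["dropped"]],
    )


# ---------------------------------------------------------------------------
# declarative configuration (flat key-value overrides)


def _coerce_dataclass(cls, base, overrides: Dict[str, object]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    clean = {}
    for key, value in overrides.items():
        if key not in fields:
            raise ConfigurationError(f"unknown {cls.__name__} field {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        clean[key] = value
    return replace(base, **clean)


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a flat key-value YAML config.

    Top-level keys: ``seed``, ``profiles``, ``policies``, ``locks``,
    ``target_channel``, ``out_dir``; dotted keys ``paradigm.<field>``,
    ``filter.<field>``, ``thresholds.<field>``, ``permutation.<field>``
    override the corresponding spec objects.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    groups: Dict[str, Dict[str, object]] = {
        "paradigm": {}, "filter": {}, "thresholds": {}, "permutation": {}}
    top: Dict[str, object] = {}
    for key, value in raw.items():
        if "." in key:
            group, fieldname = key.split(".", 1)
            if group not in groups:
                raise ConfigurationError(f"unknown config group {group!r}")
            groups[group][fieldname] = value
        else:
            top[key] = value

    cfg = StudyConfig(
        paradigm=_coerce_dataclass(ParadigmSpec, ParadigmSpec(), groups["paradigm"]),
        filter_spec=_coerce_dataclass(FilterSpec, FilterSpec(), groups["filter"]),
        thresholds=_coerce_dataclass(ArtifactThresholds, ArtifactThresholds(),
                                     groups["thresholds"]),
        permutation=_coerce_dataclass(PermutationSpec, PermutationSpec(),
                                      groups["permutation"]),
    )
    allowed = {"seed", "profiles", "policies", "locks", "target_channel", "out_dir"}
    updates = {}
    for key, value in top.items():
        if key not in allowed:
            raise ConfigurationError(f"unknown config key {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        updates[key] = value
    return replace(cfg, **updates)


__all__ = [
    "StudyConfig", "StudyReport", "run_study", "save_segments", "load_segments",
    "load_study_config",
]
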