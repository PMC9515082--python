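"""Configuration files, pulse logs, manifests and summaries.

Everything here is deliberately lossless: floats are serialized with
repr-round-trip precision so a written pulse log reads back bit-identical,
and a session manifest pins the config hashes and seeds needed to reproduce
a run.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .control import (PulseRecord, SonicationConfig, TreatmentLog,
                      PULSE_LOG_COLUMNS, summarize_log)
from .plant import PlantParams

__all__ = ["load_config", "save_config", "write_pulse_log", "read_pulse_log",
           "summarize", "SessionManifest", "load_roi", "file_sha256"]

_KINDS = {"sonication": SonicationConfig, "plant": PlantParams}


def _read_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_config(path, kind: str):
    """Load and validate a YAML/JSON config of the given kind.

    ``kind`` is ``"sonication"`` or ``"plant"``.  Unknown keys are rejected
    and every type invariant is enforced, with the offending field named.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown config kind: {kind!r}")
    data = _read_structured(path)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return _KINDS[kind].from_dict(data)


def save_config(cfg, path) -> None:
    """Write a config dataclass back to YAML (or JSON by extension)."""
    d = cfg.to_dict()
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_pulse_log(log: TreatmentLog | Sequence[PulseRecord], path) -> None:
    """Write pulse records as CSV with full-precision floats."""
    records = log.records if isinstance(log, TreatmentLog) else log
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(PULSE_LOG_COLUMNS)
        for r in records:
            w.writerow([r.index, r.phase, repr(float(r.pressure)),
                        repr(float(r.sc_linear)), repr(float(r.ic_linear)),
                        repr(float(r.sc_db)), repr(float(r.ic_db)),
                        bool(r.in_band), bool(r.ic_event)])


def read_pulse_log(path) -> list[PulseRecord]:
    """Read a pulse-log CSV; write -> read is the identity on all fields."""
    records = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader)
        if tuple(header) != PULSE_LOG_COLUMNS:
            missing = set(PULSE_LOG_COLUMNS) - set(header)
            raise ValueError(f"bad pulse-log header; missing {sorted(missing)}")
        for row in reader:
            records.append(PulseRecord(
                index=int(row[0]), phase=row[1], pressure=float(row[2]),
                sc_linear=float(row[3]), ic_linear=float(row[4]),
                sc_db=float(row[5]), ic_db=float(row[6]),
                in_band=row[7] == "True", ic_event=row[8] == "True"))
    return records


_SUMMARY_METRICS = ("good_pulse_rate_pct", "ic_probability_pct",
                    "opening_volume_mm3")


def summarize(groups: Mapping) -> dict:
    """Per-group mean and sample sd of the characterization metrics.

    ``groups`` maps a group key (typically the TCL in dB) to a list of
    either ``TreatmentLog`` objects or per-session summary dicts.  Metrics
    present in every session of a group are aggregated; a single-session
    group reports sd 0.
    """
    out = {}
    for key, sessions in groups.items():
        if not sessions:
            raise ValueError(f"group {key!r} is empty")
        dicts = [summarize_log(s) if isinstance(s, TreatmentLog) else dict(s)
                 for s in sessions]
        stats = {"n": len(dicts)}
        for m in _SUMMARY_METRICS:
            vals = [d[m] for d in dicts if m in d]
            if len(vals) != len(dicts):
                continue
            arr = np.asarray(vals, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            stats[m] = {"mean": float(arr.mean()), "sd": sd}
        out[key] = stats
    return out


def summary_table(summary: dict) -> str:
    """Plain-text table rendering of a `summarize` result."""
    lines = [f"{'group':>8}  {'n':>3}  " +
             "  ".join(f"{m:>28}" for m in _SUMMARY_METRICS)]
    for key, stats in summary.items():
        cells = []
        for m in _SUMMARY_METRICS:
            if m in stats:
                cells.append(f"{stats[m]['mean']:14.4f} +/- {stats[m]['sd']:9.4f}")
            else:
                cells.append(f"{'-':>28}")
        lines.append(f"{key!s:>8}  {stats['n']:>3}  " + "  ".join(cells))
    return "\n".join(lines)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class SessionManifest:
    """Pins everything needed to reproduce a run bit-identically."""

    seeds: dict = field(default_factory=dict)
    configs: dict = field(default_factory=dict)  # name -> {path, sha256}
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, seeds: dict, config_paths: Mapping[str, str]):
        from . import __version__
        return cls(
            seeds=dict(seeds),
            configs={name: {"path": str(p), "sha256": file_sha256(p)}
                     for name, p in config_paths.items()},
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "SessionManifest":
        return cls(**json.loads(Path(path).read_text()))


def load_roi(data: dict):
    """Build an ROISpec from a plain mapping (YAML/JSON fragment)."""
    from .imaging import ROISpec
    known = {"center", "major_axis", "minor_axis", "orientation", "slices"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown ROI key(s): {sorted(unknown)}")
    d = dict(data)
    d["center"] = tuple(d["center"])
    if d.get("slices") is not None:
        d["slices"] = tuple(d["slices"])
    return ROISpec(**d)
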