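"""Configuration files, trial logs and run manifests.

Configs are YAML (or JSON — YAML is a superset) with a mandatory ``kind``
key selecting the schema: ``step``, ``baseline`` or ``population``.  Unknown
keys are rejected by name.  Trial logs are plain CSV with booleans encoded
as 0/1; the round trip is lossless.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .baselines import BaselineConfig
from .psychometric import PopulationSpec
from .step import IntensityScale, StepConfig, TrialRecord

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "write_trial_log",
    "read_trial_log",
    "RunManifest",
]


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


_KINDS = {"step": StepConfig, "baseline": BaselineConfig,
          "population": PopulationSpec}


def _fields(cls) -> dict[str, dataclasses.Field]:
    return {f.name: f for f in dataclasses.fields(cls)}


def _build_scale(raw) -> IntensityScale:
    if isinstance(raw, IntensityScale):
        return raw
    if not isinstance(raw, dict):
        raise ConfigError("scale must be a mapping")
    unknown = set(raw) - set(_fields(IntensityScale))
    if unknown:
        raise ConfigError(f"unknown scale key(s): {sorted(unknown)}")
    try:
        return IntensityScale(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scale: {exc}") from exc


def config_from_dict(data: dict):
    """Validate and instantiate a config from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    kind = data.get("kind")
    if kind not in _KINDS:
        raise ConfigError(
            f"config needs kind in {sorted(_KINDS)}, got {kind!r}")
    cls = _KINDS[kind]
    body = {k: v for k, v in data.items() if k != "kind"}
    allowed = _fields(cls)
    unknown = set(body) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) for kind={kind}: {sorted(unknown)}")
    if "scale" in body:
        body["scale"] = _build_scale(body["scale"])
    for name in ("theta1", "theta2", "subj_theta", "subj_sigma"):
        if name in body and isinstance(body[name], list):
            body[name] = tuple(body[name])
    try:
        return cls(**body)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {kind} config: {exc}") from exc


def config_to_dict(config) -> dict:
    kind = {StepConfig: "step", BaselineConfig: "baseline",
            PopulationSpec: "population"}[type(config)]
    data = dataclasses.asdict(config)
    for name in ("theta1", "theta2", "subj_theta", "subj_sigma"):
        if name in data and isinstance(data[name], tuple):
            data[name] = list(data[name])
    return {"kind": kind, **data}


def load_config(path: str | Path):
    """Read and validate a config file; returns the matching config object."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# --- trial logs ------------------------------------------------------------

_LOG_COLUMNS = ["run", "trial", "intensity", "correct", "seen",
                "step_size", "boundary", "cwir_current"]


def write_trial_log(path: str | Path,
                    logs: list[list[TrialRecord]]) -> None:
    """Write per-run trial records as CSV (booleans as 0/1)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LOG_COLUMNS)
        for run_idx, run in enumerate(logs):
            for t in run:
                writer.writerow([
                    run_idx, t.index, repr(t.intensity), int(t.correct),
                    int(t.seen), repr(t.step_size), repr(t.boundary),
                    t.cwir_current,
                ])


def read_trial_log(path: str | Path) -> list[list[TrialRecord]]:
    """Read a trial-log CSV back into per-run record lists."""
    runs: dict[int, list[TrialRecord]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _LOG_COLUMNS:
            raise ValueError(f"bad trial-log header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_LOG_COLUMNS):
                raise ValueError(f"malformed row at line {lineno}: {row}")
            try:
                run = int(row[0])
                record = TrialRecord(
                    index=int(row[1]), intensity=float(row[2]),
                    correct=bool(int(row[3])), seen=bool(int(row[4])),
                    step_size=float(row[5]), boundary=float(row[6]),
                    cwir_current=int(row[7]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed row at line {lineno}: {exc}") from exc
            runs.setdefault(run, []).append(record)
    return [runs[k] for k in sorted(runs)]


# --- run manifest ----------------------------------------------------------


@dataclass
class RunManifest:
    """Record of one CLI run: config snapshot, seed, outputs."""

    command: str
    master_seed: int | None
    config: dict
    outputs: list[str] = field(default_factory=list)
    version: str = "0.1.0"
    python: str = field(default_factory=platform.python_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest references missing {out}")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return RunManifest(**json.load(fh))
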