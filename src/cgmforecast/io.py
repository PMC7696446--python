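"""Trace CSV dialect, pipeline configuration, and run manifests.

Trace files are UTF-8 comma-separated with a required header
``patient_id,timestamp,glucose_mg_dl``; timestamps are ISO-8601 in naive
local clock time (single-site hospital setting, no timezone arithmetic);
missing readings are simply absent rows.  Configuration files are YAML (or
JSON, a YAML subset) with documented defaults; unknown keys are rejected so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ValidationError
from .framing import FramingSpec
from .models import ModelSpec, TrainConfig
from .preprocessing import regularize
from .trace import GlucoseTrace

__all__ = ["read_traces", "write_traces", "PipelineConfig", "load_config",
           "dump_config", "RunManifest"]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["patient_id", "timestamp", "glucose_mg_dl"]


def write_traces(traces: list[GlucoseTrace], path) -> None:
    """Write traces in the shared CSV dialect (one row per present reading)."""
    frames = [t.to_frame() for t in traces]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=TRACE_COLUMNS))
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_traces(path, *, interval: int = 5, strict: bool = True) -> list[GlucoseTrace]:
    """Read traces from CSV, snapping each patient onto the sampling grid.

    Malformed rows (unparseable timestamp or non-numeric glucose) are
    reported with their 1-based line numbers: with ``strict`` they raise a
    :class:`DataError`, otherwise they are dropped with a warning.
    """
    path = Path(path)
    try:
        # round_trip parser: written values must re-read bit-identically
        df = pd.read_csv(path, dtype={"patient_id": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("read_traces: %s is empty", path)
        return []
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("read_traces: %s has a header but no rows", path)
        return []

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    glucose = pd.to_numeric(df["glucose_mg_dl"], errors="coerce")
    bad = ts.isna() | glucose.isna() | df["patient_id"].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        msg = f"{path}: {int(bad.sum())} malformed row(s) at line(s) {lines}"
        if strict:
            raise DataError(msg)
        logger.warning("read_traces: %s — dropped", msg)
        df = df[~bad]
        ts, glucose = ts[~bad], glucose[~bad]

    traces = []
    clean = pd.DataFrame({"patient_id": df["patient_id"].to_numpy(),
                          "timestamp": ts.to_numpy(),
                          "glucose_mg_dl": glucose.to_numpy(dtype=np.float64)})
    for pid, group in clean.groupby("patient_id", sort=True):
        group = group.sort_values("timestamp")
        traces.append(regularize(group, interval, patient_id=str(pid)))
    return traces


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PreprocessingConfig:
    valid_range: tuple[float, float] = (40.0, 400.0)
    scaling: str = "zscore"

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if lo >= hi:
            raise ValidationError("preprocessing.valid_range must satisfy low < high")
        if self.scaling not in ("zscore", "minmax", "none"):
            raise ValidationError("preprocessing.scaling must be zscore|minmax|none")
        object.__setattr__(self, "valid_range", (float(lo), float(hi)))


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 20
    seed: int = 0
    distributions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("cohort.n_patients must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Frozen full-pipeline configuration with the study-protocol defaults:

    lookback 7, delay 6, step 1, 5-minute interval; GRU baseline; batch 20,
    RMSprop, 20 epochs; 7:3 chronological split; z-score scaling.
    """

    framing: FramingSpec = field(default_factory=FramingSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocessing"]["valid_range"] = list(d["preprocessing"]["valid_range"])
        return d


_SECTIONS = {"framing": FramingSpec, "model": ModelSpec, "training": TrainConfig,
             "preprocessing": PreprocessingConfig, "cohort": CohortConfig}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    if section == "preprocessing" and "valid_range" in data:
        data = {**data, "valid_range": tuple(data["valid_range"])}
    if section == "model" and "recurrent_layers" in data:
        data = {**data, "recurrent_layers": int(data["recurrent_layers"])}
    return cls(**data)


def config_from_dict(raw: dict | None) -> PipelineConfig:
    raw = dict(raw or {})
    top_known = set(_SECTIONS) | {"train_fraction"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValidationError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        data = raw.get(section, {})
        if not isinstance(data, dict):
            raise ValidationError(f"config section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, data, section)
    if "train_fraction" in raw:
        kwargs["train_fraction"] = float(raw["train_fraction"])
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline configuration file.

    An empty file yields all documented defaults; unknown keys raise a
    :class:`ValidationError` naming the offending key.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    return config_from_dict(raw)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run manifests

@dataclass
class RunManifest:
    """Everything needed to re-execute one pipeline stage deterministically."""

    command: str
    config: dict
    seed: int
    software_version: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))
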