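"""Domain types and on-disk formats.

The canonical on-disk schema is a long (tidy) event table — one row per timed
observation, offsets in integer minutes since ICU admission (the convention of
the large credentialed ICU databases whose extracts this package consumes) —
plus a patient table with demographics, label, onset anchor and discharge
offset.  Readers reject malformed rows (non-numeric values, negative or
sub-minute offsets) and *count* them rather than silently dropping, because
downstream cohort accounting depends on exact exclusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimedObservation", "PatientRecord", "AlignedWindow",
    "ModelConfig", "TrainConfig", "RunConfig",
    "EventTable", "SchemaError", "EmptyTableError",
    "read_long_events", "write_long_events",
    "read_patients", "write_patients", "records_from_tables",
    "load_config", "EVENT_COLUMNS", "PATIENT_COLUMNS",
]

EVENT_COLUMNS = ["patient_id", "offset_min", "variable", "value"]
PATIENT_COLUMNS = ["patient_id", "age_years", "label",
                   "anchor_offset_min", "discharge_offset_min"]

VALID_LABELS = {"sepsis", "control"}


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class EmptyTableError(ValueError):
    """The file contains no data rows."""


@dataclass(frozen=True)
class TimedObservation:
    """One timed measurement of one clinical variable."""
    patient_id: str
    offset_min: int
    variable: str
    value: float

    def __post_init__(self):
        if self.offset_min < 0:
            raise ValueError(f"offset_min must be >= 0, got {self.offset_min}")
        if not self.variable:
            raise ValueError("variable name must be non-empty")
        if not np.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")


@dataclass
class PatientRecord:
    """One patient: demographics, label, onset anchor, and their event stream.

    ``anchor_offset_min`` is the sepsis diagnosis offset for cases; controls
    carry a synthetic anchor (recorded in the patient table) so that windows
    can be cut the same way for both arms.
    """
    patient_id: str
    age_years: float
    label: str  # "sepsis" | "control"
    anchor_offset_min: int
    discharge_offset_min: int
    events: list[TimedObservation] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}")
        if self.anchor_offset_min > self.discharge_offset_min:
            raise ValueError("anchor_offset_min must be <= discharge_offset_min")
        for ev in self.events:
            if ev.offset_min > self.discharge_offset_min:
                raise ValueError(
                    f"event at {ev.offset_min} min after discharge "
                    f"({self.discharge_offset_min} min) for patient {self.patient_id}")
        self.events = sorted(self.events, key=lambda e: (e.variable, e.offset_min))

    @property
    def stay_hours(self) -> float:
        return self.discharge_offset_min / 60.0

    @property
    def is_sepsis(self) -> bool:
        return self.label == "sepsis"

    def first_event_offset(self) -> int:
        if not self.events:
            raise ValueError(f"patient {self.patient_id} has no events")
        return min(e.offset_min for e in self.events)

    def observed_variables(self) -> set[str]:
        return {e.variable for e in self.events}


@dataclass
class AlignedWindow:
    """A fixed-grid observation window ending `horizon` hours before onset.

    ``matrix`` is T x N (rows = hourly steps, columns = features) with no
    missing entries; ``imputed_mask`` marks cells that were filled rather than
    observed; ``valid_mask`` is False on left-padding rows.
    """
    matrix: np.ndarray
    feature_names: list[str]
    imputed_mask: np.ndarray
    valid_mask: np.ndarray
    window_end_offset_min: int

    def __post_init__(self):
        T, N = self.matrix.shape
        if len(self.feature_names) != N:
            raise ValueError("feature_names length must equal matrix width")
        if len(set(self.feature_names)) != N:
            raise ValueError("feature_names must be unique")
        if self.imputed_mask.shape != (T, N) or self.valid_mask.shape != (T,):
            raise ValueError("mask shapes inconsistent with matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("window matrix must have no missing entries")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the sequence classifiers."""
    architecture: str = "lstm_transformer"
    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    ff_dim: int = 128
    rnn_hidden: int = 64
    cnn_kernel: int = 3
    dropout: float = 0.1
    channel_dropout: float = 0.2  # train-time whole-channel masking
    positional_encoding: str = "auto"  # auto | sinusoidal | none
    pooling: str = "last_valid"  # last_valid | masked_mean
    n_classes: int = 2

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.cnn_kernel % 2 != 1:
            raise ValueError("cnn_kernel must be odd")
        if self.pooling not in ("last_valid", "masked_mean"):
            raise ValueError("pooling must be 'last_valid' or 'masked_mean'")
        if not (0.0 <= self.channel_dropout < 1.0):
            raise ValueError("channel_dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization protocol (cross-entropy + Adam, early stopping)."""
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    weight_decay: float = 1e-3
    ema_decay: float = 0.0  # >0 enables Polyak weight averaging
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs",
                     "early_stop_patience", "validation_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class RunConfig:
    """End-to-end run protocol: grid, windowing, split and CV settings."""
    horizon_hours: int = 12
    grid_step_min: int = 60
    max_timepoints: int = 300
    split_ratio: float = 0.7
    cv_folds: int = 5
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.horizon_hours <= 0:
            raise ValueError("horizon_hours must be positive")
        if self.grid_step_min <= 0 or self.max_timepoints <= 0:
            raise ValueError("grid_step_min and max_timepoints must be positive")
        if self.horizon_hours not in (4, 8, 12):
            warnings.warn(
                f"horizon_hours={self.horizon_hours} is outside the studied set "
                "{4, 8, 12}; proceeding anyway", UserWarning, stacklevel=2)


class EventTable:
    """Canonical long-format event table with reject accounting.

    Wraps a pandas DataFrame with columns ``patient_id`` (str),
    ``offset_min`` (int), ``variable`` (str), ``value`` (float), kept sorted
    by (patient_id, variable, offset_min) so parsing is order-independent.
    """

    def __init__(self, frame: pd.DataFrame, rejects: Mapping[str, int] | None = None):
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"event table missing column(s): {missing}")
        frame = frame.loc[:, EVENT_COLUMNS].copy()
        frame["patient_id"] = frame["patient_id"].astype(str)
        frame["variable"] = frame["variable"].astype(str)
        frame["offset_min"] = frame["offset_min"].astype(np.int64)
        frame["value"] = frame["value"].astype(np.float64)
        self.frame = frame.sort_values(
            ["patient_id", "variable", "offset_min"], kind="mergesort"
        ).reset_index(drop=True)
        self.rejects = dict(rejects or {})

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def n_rejected(self) -> int:
        return int(sum(self.rejects.values()))

    def observations(self) -> list[TimedObservation]:
        return [TimedObservation(r.patient_id, int(r.offset_min), r.variable, float(r.value))
                for r in self.frame.itertuples(index=False)]

    def for_patient(self, patient_id: str) -> pd.DataFrame:
        return self.frame[self.frame["patient_id"] == str(patient_id)]


def read_long_events(path, schema: Mapping[str, str] | None = None) -> EventTable:
    """Read a long-format event CSV.

    ``schema`` optionally maps canonical names (``patient_id``, ``offset_min``,
    ``variable``, ``value``) to the file's column names.  Rows with
    non-numeric values, or negative/non-integer offsets, are counted in
    ``EventTable.rejects`` by reason — never silently dropped.
    """
    raw = pd.read_csv(path)
    if raw.empty:
        raise EmptyTableError(f"no data rows in {path}")
    colmap = {k: k for k in EVENT_COLUMNS}
    if schema:
        colmap.update(schema)
    for canonical, actual in colmap.items():
        if actual not in raw.columns:
            raise SchemaError(
                f"column {actual!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(raw.columns)}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})[EVENT_COLUMNS]

    rejects: dict[str, int] = {}
    value = pd.to_numeric(df["value"], errors="coerce")
    bad_value = value.isna() | ~np.isfinite(value.fillna(np.inf))
    offset = pd.to_numeric(df["offset_min"], errors="coerce")
    bad_offset_nan = offset.isna()
    with np.errstate(invalid="ignore"):
        nonint = ~bad_offset_nan & (offset != np.floor(offset))
        negative = ~bad_offset_nan & ~nonint & (offset < 0)
    bad = bad_value | bad_offset_nan | nonint | negative
    rejects["non_numeric_value"] = int((bad_value & ~bad_offset_nan & ~nonint & ~negative).sum())
    rejects["unparseable_offset"] = int(bad_offset_nan.sum())
    rejects["sub_minute_offset"] = int(nonint.sum())
    rejects["negative_offset"] = int((negative & ~bad_value).sum())
    rejects = {k: v for k, v in rejects.items() if v}

    kept = df[~bad].copy()
    kept["value"] = value[~bad]
    kept["offset_min"] = offset[~bad].astype(np.int64)
    return EventTable(kept, rejects)


def write_long_events(table: EventTable, path) -> None:
    """Write an event table as CSV, rows ordered (patient_id, variable, offset)."""
    out = table.frame.sort_values(
        ["patient_id", "variable", "offset_min"], kind="mergesort")
    out.to_csv(path, index=False)


def read_patients(path) -> pd.DataFrame:
    """Read the patient table CSV; validates columns and label values."""
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyTableError(f"no data rows in {path}")
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient table missing column(s): {missing}")
    df = df[PATIENT_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    bad_labels = set(df["label"]) - VALID_LABELS
    if bad_labels:
        raise SchemaError(f"unknown labels in patient table: {sorted(bad_labels)}")
    return df.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def write_patients(patients: pd.DataFrame, path) -> None:
    patients.sort_values("patient_id", kind="mergesort").to_csv(path, index=False)


def records_from_tables(patients: pd.DataFrame, events: EventTable) -> list[PatientRecord]:
    """Join the patient table with the event table into PatientRecord objects."""
    records = []
    grouped = dict(iter(events.frame.groupby("patient_id", sort=False)))
    for row in patients.itertuples(index=False):
        pid = str(row.patient_id)
        obs = []
        if pid in grouped:
            g = grouped[pid]
            obs = [TimedObservation(pid, int(o), v, float(x))
                   for o, v, x in zip(g["offset_min"], g["variable"], g["value"])]
        records.append(PatientRecord(
            patient_id=pid,
            age_years=float(row.age_years),
            label=str(row.label),
            anchor_offset_min=int(row.anchor_offset_min),
            discharge_offset_min=int(row.discharge_offset_min),
            events=obs,
        ))
    return records


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys take protocol defaults
    (60-min grid, 300-point cap, 0.7 split, 5 CV folds, 12 h horizon)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    model_kwargs = data.pop("model", {}) or {}
    train_kwargs = data.pop("train", {}) or {}
    # tolerate a flat `architecture` key at the top level
    if "architecture" in data:
        model_kwargs.setdefault("architecture", data.pop("architecture"))
    known = {f for f in RunConfig.__dataclass_fields__ if f not in ("model", "train")}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(model=ModelConfig(**model_kwargs),
                    train=TrainConfig(**train_kwargs), **data)
    if "seed" in data:
        cfg.train = replace(cfg.train, seed=cfg.seed)
    return cfg
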