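"""Cohort filtering and the alignment/imputation/windowing chain.

The pipeline turns each patient's irregular event stream into a fixed hourly
matrix ending a chosen horizon before the onset anchor:

1. cohort filters (age >= 18, stay > 24 h, <= 30% of channels entirely
   absent), applied in order with per-rule exclusion counts;
2. a uniform time grid from the first recorded event to
   ``anchor - horizon``, one point per hour;
3. nearest-grid-point alignment (ties to the earlier point; several
   observations landing in one cell keep the latest);
4. forward-fill imputation, with leading gaps back-filled from the first
   observation and entirely missing channels set to a training-cohort mean;
5. truncation to the most recent 300 rows / left zero-padding, keeping the
   window end (onset-proximal rows) at a fixed position;
6. per-feature z-standardization with constants fitted on the training
   split only, padding rows exactly zero afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlignedWindow, PatientRecord, TimedObservation

__all__ = [
    "FilterCriteria", "ExclusionReport", "GridSpec", "TooShortHistoryError",
    "apply_cohort_filters", "build_grid", "align_to_grid", "impute",
    "extract_window", "Dataset", "assemble_dataset", "standardize_dataset",
]


class TooShortHistoryError(ValueError):
    """The record's history ends before the requested window begins."""


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion thresholds: adults, stays longer than a day, and at most
    30% of feature channels entirely absent."""
    min_age_years: float = 18.0
    min_stay_hours: float = 24.0
    max_missing_fraction: float = 0.30

    def __post_init__(self):
        if min(self.min_age_years, self.min_stay_hours, self.max_missing_fraction) < 0:
            raise ValueError("criteria must be non-negative")
        if self.max_missing_fraction >= 1:
            raise ValueError("max_missing_fraction must be < 1")


@dataclass
class ExclusionReport:
    n_input: int = 0
    excluded_age: int = 0
    excluded_stay: int = 0
    excluded_missingness: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.excluded_age - self.excluded_stay - self.excluded_missingness

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "excluded_age": self.excluded_age,
                "excluded_stay": self.excluded_stay,
                "excluded_missingness": self.excluded_missingness,
                "n_kept": self.n_kept}


def apply_cohort_filters(records: Sequence[PatientRecord],
                         criteria: FilterCriteria,
                         feature_names: Sequence[str],
                         ) -> tuple[list[PatientRecord], ExclusionReport]:
    """Apply the inclusion rules in order (age, stay, missingness).

    Age is inclusive at the threshold (18.0 qualifies); stay is strict
    ("exceeding" the minimum); a record is excluded when the fraction of
    feature channels with no observation at all exceeds the cap.
    """
    if not feature_names:
        raise ValueError("feature_names must be non-empty")
    feats = list(feature_names)
    report = ExclusionReport(n_input=len(records))
    kept: list[PatientRecord] = []
    for rec in records:
        if rec.age_years < criteria.min_age_years:
            report.excluded_age += 1
            continue
        if rec.stay_hours <= criteria.min_stay_hours:
            report.excluded_stay += 1
            continue
        observed = rec.observed_variables()
        missing_frac = sum(1 for f in feats if f not in observed) / len(feats)
        if missing_frac > criteria.max_missing_fraction:
            report.excluded_missingness += 1
            continue
        kept.append(rec)
    return kept, report


@dataclass(frozen=True)
class GridSpec:
    """Uniform time axis: points start, start+step, ..., <= end (minutes)."""
    start_offset_min: int
    end_offset_min: int
    step_min: int = 60

    def __post_init__(self):
        if self.step_min <= 0:
            raise ValueError("step_min must be positive")
        if self.start_offset_min > self.end_offset_min:
            raise ValueError("grid start must be <= end")

    @property
    def n_points(self) -> int:
        return (self.end_offset_min - self.start_offset_min) // self.step_min + 1

    def points(self) -> np.ndarray:
        return self.start_offset_min + self.step_min * np.arange(self.n_points)

    @property
    def last_point_offset_min(self) -> int:
        return int(self.start_offset_min + self.step_min * (self.n_points - 1))


def build_grid(record: PatientRecord, horizon_hours: int,
               step_min: int = 60) -> GridSpec:
    """Grid from the first recorded event to ``anchor - horizon``."""
    start = record.first_event_offset()
    end = record.anchor_offset_min - 60 * horizon_hours
    if end < start:
        raise TooShortHistoryError(
            f"patient {record.patient_id}: window end ({end} min) precedes "
            f"first event ({start} min) at horizon {horizon_hours} h")
    return GridSpec(start, end, step_min)


def align_to_grid(events, grid: GridSpec, feature_names: Sequence[str],
                  ) -> tuple[np.ndarray, dict]:
    """Assign each observation to its nearest grid point.

    Returns a T x N matrix with NaN where no observation landed, plus a
    report counting ignored rows (unknown variable, outside the half-step
    range around the grid).  Midpoint ties go to the earlier grid point;
    when several observations share a cell the one with the largest offset
    (most recent) wins.

    ``events`` may be a list of TimedObservation or a DataFrame with columns
    offset_min / variable / value.
    """
    if isinstance(events, pd.DataFrame):
        offs = events["offset_min"].to_numpy(dtype=np.int64)
        vars_ = events["variable"].to_numpy()
        vals = events["value"].to_numpy(dtype=np.float64)
    else:
        offs = np.array([e.offset_min for e in events], dtype=np.int64)
        vars_ = np.array([e.variable for e in events])
        vals = np.array([e.value for e in events], dtype=np.float64)

    feats = list(feature_names)
    col_of = {name: j for j, name in enumerate(feats)}
    T = grid.n_points
    matrix = np.full((T, N := len(feats)), np.nan)
    report = {"unknown_variable": 0, "out_of_range": 0}
    if offs.size == 0:
        return matrix, report

    known = np.array([v in col_of for v in vars_])
    report["unknown_variable"] = int((~known).sum())
    offs, vars_, vals = offs[known], vars_[known], vals[known]

    s, start, end = grid.step_min, grid.start_offset_min, grid.end_offset_min
    # keep offsets in [start - s/2, end + s/2)
    in_range = (2 * offs >= 2 * start - s) & (2 * offs < 2 * end + s)
    report["out_of_range"] = int((~in_range).sum())
    offs, vars_, vals = offs[in_range], vars_[in_range], vals[in_range]

    # nearest grid index with midpoint ties to the earlier point:
    # idx = ceil((d - s/2) / s) for d = offset - start, in exact integer form
    d = offs - start
    idx = -((s - 2 * d) // (2 * s))
    idx = np.clip(idx, 0, T - 1)

    order = np.argsort(offs, kind="stable")  # ascending: later offsets overwrite
    for p in order:
        matrix[idx[p], col_of[vars_[p]]] = vals[p]
    return matrix, report


def impute(raw: np.ndarray, feature_names: Sequence[str],
           feature_means: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Fill a T x N aligned matrix: forward fill within each column, leading
    gaps from the column's first observation, entirely missing columns from
    ``feature_means``.  Returns (filled, imputed_mask); the imputed mask is
    True exactly where a value was filled rather than observed."""
    feats = list(feature_names)
    missing_means = [f for f in feats if f not in feature_means]
    if missing_means:
        raise ValueError(f"feature_means missing variable(s): {missing_means}")
    raw = np.asarray(raw, dtype=np.float64)
    imputed_mask = np.isnan(raw)
    df = pd.DataFrame(raw, columns=feats)
    filled = df.ffill().bfill()
    for f in feats:
        if filled[f].isna().all():
            filled[f] = float(feature_means[f])
    out = filled.to_numpy()
    if np.isnan(out).any():  # pragma: no cover - guarded by the branches above
        raise AssertionError("imputation left missing values")
    return out, imputed_mask


def extract_window(filled: np.ndarray, imputed_mask: np.ndarray,
                   feature_names: Sequence[str], window_end_offset_min: int,
                   max_timepoints: int = 300) -> AlignedWindow:
    """Cap the window at ``max_timepoints`` rows, keeping the most recent
    (onset-proximal) history; shorter windows are left-padded with zero rows
    flagged invalid so the window end stays anchored at the last row."""
    T = filled.shape[0]
    if T == 0:
        raise ValueError("empty window: no grid points")
    if T > max_timepoints:
        filled = filled[T - max_timepoints:]
        imputed_mask = imputed_mask[T - max_timepoints:]
        T = max_timepoints
    valid = np.ones(T, dtype=bool)
    return AlignedWindow(matrix=filled.copy(), feature_names=list(feature_names),
                         imputed_mask=imputed_mask.copy(), valid_mask=valid,
                         window_end_offset_min=int(window_end_offset_min))


def _pad_left(matrix: np.ndarray, mask: np.ndarray, valid: np.ndarray,
              total: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    T, N = matrix.shape
    if T == total:
        return matrix, mask, valid
    pad = total - T
    m = np.zeros((total, N))
    m[pad:] = matrix
    im = np.zeros((total, N), dtype=bool)
    im[pad:] = mask
    v = np.zeros(total, dtype=bool)
    v[pad:] = valid
    return m, im, v


@dataclass
class Dataset:
    """Assembled windows for a record set.

    ``X`` is (n, T, N) with window ends aligned at the last row; ``valid``
    is False on left-padding rows; ``y`` is 1 for sepsis.  When standardized,
    ``standardization`` holds the (mean, sd) fitted on the training split.
    """
    X: np.ndarray
    imputed: np.ndarray
    valid: np.ndarray
    y: np.ndarray
    patient_ids: list[str]
    feature_names: list[str]
    feature_means: dict[str, float]
    window_end_offset_min: np.ndarray
    skip_report: dict[str, str] = field(default_factory=dict)
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return replace(
            self, X=self.X[idx], imputed=self.imputed[idx], valid=self.valid[idx],
            y=self.y[idx], patient_ids=[self.patient_ids[i] for i in idx],
            window_end_offset_min=self.window_end_offset_min[idx])


def assemble_dataset(records: Sequence[PatientRecord], horizon_hours: int, *,
                     feature_names: Sequence[str] | None = None,
                     step_min: int = 60, max_timepoints: int = 300,
                     feature_means: Mapping[str, float] | None = None) -> Dataset:
    """Run grid -> align -> impute -> extract for every record and stack.

    ``feature_means`` (for entirely missing channels) should come from
    training records when assembling a test set; by default they are the
    observed-cell means of the records given here.  Records whose history is
    too short for the horizon are skipped and listed in ``skip_report``.
    """
    if not records:
        raise ValueError("no records to assemble")
    if feature_names is None:
        feature_names = sorted(set().union(*(r.observed_variables() for r in records)))
    feats = list(feature_names)

    aligned, skip_report, kept = [], {}, []
    for rec in records:
        try:
            grid = build_grid(rec, horizon_hours, step_min)
        except TooShortHistoryError as err:
            skip_report[rec.patient_id] = str(err)
            continue
        raw, _ = align_to_grid(_events_frame(rec), grid, feats)
        aligned.append((rec, grid, raw))
        kept.append(rec)
    if not aligned:
        raise ValueError("all records skipped: no history long enough for the horizon")

    if feature_means is None:
        sums = np.zeros(len(feats))
        counts = np.zeros(len(feats))
        for _, _, raw in aligned:
            obs = ~np.isnan(raw)
            sums += np.where(obs, raw, 0.0).sum(axis=0)
            counts += obs.sum(axis=0)
        never = [f for f, c in zip(feats, counts) if c == 0]
        if never:
            raise ValueError(f"feature(s) never observed in these records: {never}")
        feature_means = dict(zip(feats, sums / counts))
    feature_means = {f: float(feature_means[f]) for f in feats}

    windows = []
    for rec, grid, raw in aligned:
        filled, mask = impute(raw, feats, feature_means)
        win = extract_window(filled, mask, feats, grid.last_point_offset_min,
                             max_timepoints)
        windows.append(win)

    total_T = max(w.n_timepoints for w in windows)
    X = np.zeros((len(windows), total_T, len(feats)))
    imput = np.zeros((len(windows), total_T, len(feats)), dtype=bool)
    valid = np.zeros((len(windows), total_T), dtype=bool)
    for i, w in enumerate(windows):
        X[i], imput[i], valid[i] = _pad_left(w.matrix, w.imputed_mask, w.valid_mask, total_T)

    return Dataset(
        X=X, imputed=imput, valid=valid,
        y=np.array([1 if r.is_sepsis else 0 for r in kept], dtype=np.int64),
        patient_ids=[r.patient_id for r in kept],
        feature_names=feats, feature_means=feature_means,
        window_end_offset_min=np.array([w.window_end_offset_min for w in windows],
                                       dtype=np.int64),
        skip_report=skip_report)


def _events_frame(record: PatientRecord) -> pd.DataFrame:
    return pd.DataFrame({
        "offset_min": [e.offset_min for e in record.events],
        "variable": [e.variable for e in record.events],
        "value": [e.value for e in record.events],
    })


def standardize_dataset(dataset: Dataset, train_idx=None,
                        constants: tuple[np.ndarray, np.ndarray] | None = None,
                        ) -> Dataset:
    """Z-score each feature using mean/SD over valid cells of the training
    subset (or supplied constants); padding cells are exactly 0 afterwards."""
    if constants is not None:
        mean, sd = constants
    else:
        idx = np.arange(dataset.n) if train_idx is None else np.asarray(train_idx)
        rows = dataset.X[idx][dataset.valid[idx]]  # (n_valid_cells, N)
        if rows.size == 0:
            raise ValueError("no valid cells to fit standardization")
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0)
        sd = np.where(sd <= 0, 1.0, sd)
    Xs = (dataset.X - mean) / sd
    Xs[~dataset.valid] = 0.0
    return replace(dataset, X=Xs, standardization=(np.asarray(mean), np.asarray(sd)))
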