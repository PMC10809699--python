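"""Classification metrics, ROC/AUROC, multi-horizon comparison, and
baseline-characteristics tables.

AUROC is computed by the tie-aware Mann-Whitney rank formula (the probability
that a random positive outscores a random negative, ties counted 1/2), which
equals trapezoidal integration of the ROC curve.  The cohort summary follows
the usual ICU-table conventions: Welch two-sided t-test for continuous
variables, chi-square without continuity correction for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ModelConfig, RunConfig, TrainConfig
from .preprocess import Dataset, assemble_dataset, standardize_dataset
from . import models as _models

__all__ = [
    "ConfusionMatrix", "EvalReport", "confusion", "classification_metrics",
    "roc_auc", "evaluate_predictions", "cross_validate", "run_experiment",
    "horizon_comparison", "cohort_summary",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float | None
    confusion: ConfusionMatrix
    undefined_metrics: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1, "auroc": self.auroc,
             "confusion": self.confusion.to_dict()}
        if self.undefined_metrics:
            d["undefined_metrics"] = list(self.undefined_metrics)
        return d


def confusion(labels, predicted) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation of binary labels vs predicted labels."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predicted).astype(int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()), fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()), fn=int(((y == 1) & (p == 0)).sum()))


def classification_metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, precision, recall and F1 from a confusion matrix; ratios
    with a zero denominator are reported as 0 and flagged."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return EvalReport(accuracy=(cm.tp + cm.tn) / cm.n, precision=precision,
                      recall=recall, f1=f1, auroc=None, confusion=cm,
                      undefined_metrics=tuple(undefined))


def roc_auc(labels, scores) -> float:
    """Tie-aware Mann-Whitney AUROC: P(score+ > score-) + P(tie)/2."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(s)  # mid-ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_predictions(labels, proba_pos) -> EvalReport:
    """Full report from positive-class probabilities (threshold 0.5,
    ties to the positive class).  A full (n, 2) probability matrix is also
    accepted; its last column is taken as the positive class."""
    proba_pos = np.asarray(proba_pos, dtype=np.float64)
    if proba_pos.ndim == 2:
        proba_pos = proba_pos[:, -1]
    pred = (proba_pos >= 0.5).astype(int)
    report = classification_metrics(confusion(labels, pred))
    return replace(report, auroc=roc_auc(labels, proba_pos))


def cross_validate(dataset: Dataset, model_config: ModelConfig,
                   train_config: TrainConfig, k: int = 5, seed: int = 0,
                   ) -> pd.DataFrame:
    """Stratified k-fold on an assembled dataset: one metrics row per fold,
    plus mean and SD rows (SD with the n-1 denominator)."""
    rows = []
    for fold, (fit_idx, val_idx) in enumerate(
            _models.kfold_indices(dataset.y, k=k, seed=seed)):
        fit_ds = standardize_dataset(dataset.subset(fit_idx))
        val_ds = standardize_dataset(dataset.subset(val_idx),
                                     constants=fit_ds.standardization)
        tc = replace(train_config, seed=train_config.seed + fold)
        clf = _models.train(fit_ds, model_config, tc)
        report = evaluate_predictions(val_ds.y, _models.predict_proba(clf, val_ds))
        rows.append({"fold": fold, **{k_: v for k_, v in report.to_dict().items()
                                      if k_ not in ("confusion", "undefined_metrics")}})
    df = pd.DataFrame(rows)
    metric_cols = ["accuracy", "precision", "recall", "f1", "auroc"]
    summary = pd.DataFrame([
        {"fold": "mean", **df[metric_cols].mean().to_dict()},
        {"fold": "sd", **df[metric_cols].std(ddof=1).to_dict()},
    ])
    return pd.concat([df, summary], ignore_index=True)


def run_experiment(records, horizon_hours: int, config: RunConfig,
                   feature_names=None, permute_labels: bool = False,
                   ) -> tuple[EvalReport, _models.SequenceClassifier]:
    """The end-to-end protocol for one (horizon, architecture, seed) cell.

    Records are split 70:30 stratified by label *before* assembly so the
    imputation means and standardization constants come from training
    patients only; the fitted model is evaluated on the held-out patients.
    With ``permute_labels`` the patient labels are shuffled (seeded) across
    the whole record set before splitting — the standard permutation null:
    the identical pipeline runs on label-scrambled data and is scored against
    the scrambled held-out labels, so any apparent skill is spurious.
    """
    records = list(records)
    y = np.array([1 if r.is_sepsis else 0 for r in records])
    if len(np.unique(y)) < 2:
        raise ValueError("records must contain both classes")
    if permute_labels:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 77]))
        y = rng.permutation(y)
    from sklearn.model_selection import train_test_split as _tts
    tr_idx, te_idx = _tts(np.arange(len(records)), train_size=config.split_ratio,
                          stratify=y, random_state=int(config.seed) % (2 ** 32))
    train_recs = [records[i] for i in sorted(tr_idx)]
    test_recs = [records[i] for i in sorted(te_idx)]

    train_ds = assemble_dataset(train_recs, horizon_hours,
                                feature_names=feature_names,
                                step_min=config.grid_step_min,
                                max_timepoints=config.max_timepoints)
    test_ds = assemble_dataset(test_recs, horizon_hours,
                               feature_names=train_ds.feature_names,
                               step_min=config.grid_step_min,
                               max_timepoints=config.max_timepoints,
                               feature_means=train_ds.feature_means)
    train_ds = standardize_dataset(train_ds)
    test_ds = standardize_dataset(test_ds, constants=train_ds.standardization)

    if permute_labels:
        label_of = {r.patient_id: int(lab) for r, lab in zip(records, y)}
        train_ds = replace(train_ds, y=np.array([label_of[p] for p in train_ds.patient_ids]))
        test_ds = replace(test_ds, y=np.array([label_of[p] for p in test_ds.patient_ids]))

    clf = _models.train(train_ds, config.model, replace(config.train, seed=config.seed))
    report = evaluate_predictions(test_ds.y, _models.predict_proba(clf, test_ds))
    return report, clf


def horizon_comparison(records, horizons=(4, 8, 12),
                       architectures=("lstm_transformer",),
                       config: RunConfig | None = None,
                       seeds=(0,)) -> pd.DataFrame:
    """Metric table per (horizon, architecture, seed) with shared splits.

    Columns: horizon_hours, architecture, seed, accuracy, precision, recall,
    f1, auroc.  Errors in one cell are raised with the failing cell named.
    """
    base = config or RunConfig()
    rows = []
    for horizon in horizons:
        for arch in architectures:
            for seed in seeds:
                cfg = replace(
                    base, horizon_hours=horizon, seed=seed,
                    model=replace(base.model, architecture=arch),
                    train=replace(base.train, seed=seed))
                try:
                    report, _ = run_experiment(records, horizon, cfg)
                except Exception as err:
                    raise RuntimeError(
                        f"horizon_comparison failed at horizon={horizon}, "
                        f"architecture={arch}, seed={seed}: {err}") from err
                rows.append({"horizon_hours": horizon, "architecture": arch,
                             "seed": seed,
                             **{k: v for k, v in report.to_dict().items()
                                if k not in ("confusion", "undefined_metrics")}})
    return pd.DataFrame(rows)


def cohort_summary(patients: pd.DataFrame, group_col: str = "label",
                   continuous=None, categorical=None) -> pd.DataFrame:
    """Baseline-characteristics comparison between the two groups.

    Continuous variables: per-group mean and SD, Welch two-sided t-test.
    Categorical variables: counts and percentages, chi-square test without
    continuity correction.  One row per variable (or per category level).
    """
    groups = sorted(patients[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"cohort_summary requires exactly 2 groups, got {groups}")
    g0 = patients[patients[group_col] == groups[0]]
    g1 = patients[patients[group_col] == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 patients")

    if continuous is None or categorical is None:
        num_cols = [c for c in patients.columns
                    if c != group_col and pd.api.types.is_numeric_dtype(patients[c])]
        cat_cols = [c for c in patients.columns
                    if c != group_col and not pd.api.types.is_numeric_dtype(patients[c])]
        continuous = num_cols if continuous is None else continuous
        categorical = cat_cols if categorical is None else categorical

    rows = []
    for col in continuous:
        a, b = g0[col].to_numpy(float), g1[col].to_numpy(float)
        if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": col, "level": "",
                     f"{groups[0]}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                     f"{groups[1]}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                     "test": "welch_t", "statistic": float(t), "p_value": float(p)})
    for col in categorical:
        table = pd.crosstab(patients[col], patients[group_col])
        if table.shape[0] < 2:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        for level in table.index:
            c0 = int(table.loc[level, groups[0]]) if groups[0] in table else 0
            c1 = int(table.loc[level, groups[1]]) if groups[1] in table else 0
            rows.append({"variable": col, "level": str(level),
                         f"{groups[0]}": f"{c0} ({100 * c0 / len(g0):.2f}%)",
                         f"{groups[1]}": f"{c1} ({100 * c1 / len(g1):.2f}%)",
                         "test": "chi_square", "statistic": float(chi2),
                         "p_value": float(p)})
    return pd.DataFrame(rows)
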