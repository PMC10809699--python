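"""Sequence classifiers for onset-anchored clinical windows.

Five architectures share one estimator, :class:`SequenceClassifier`
(scikit-learn API: ``fit`` / ``predict_proba`` / ``get_params``):

* ``baseline_static`` — a two-layer perceptron on the features at the first
  valid time step (admission snapshot; no temporal information);
* ``rnn`` / ``lstm`` — a recurrent stack whose last-valid-step state feeds a
  fully connected head;
* ``cnn_transformer`` — 1-D convolution along time lifts the N channels to
  d_model (replacing a token embedding), a sinusoidal positional code
  (anchored at the window end) adds order, then a Transformer encoder,
  masked mean pooling and the head;
* ``lstm_transformer`` — an LSTM provides the per-step d_model embedding
  (recurrence already encodes order, so no positional code by default),
  followed by the same encoder, pooling, and head.

All attention, pooling, and recurrences respect the valid mask, so
predictions are exactly invariant to the amount of left padding.  Training
is full-batch-order deterministic given ``random_state``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from ._autodiff import Tensor
from .io import ModelConfig, TrainConfig
from .preprocess import Dataset

__all__ = [
    "ARCHITECTURES", "SequenceClassifier", "build_model",
    "split_train_test", "kfold_indices", "train", "predict_proba",
    "save_model", "load_model",
]

ARCHITECTURES = ("baseline_static", "rnn", "lstm", "cnn_transformer", "lstm_transformer")


class _SequenceNet(nn.Module):
    """The shared network body; built from a ModelConfig."""

    def __init__(self, config: ModelConfig, n_features: int, rng: np.random.Generator):
        arch = config.architecture
        if arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {arch!r}; choose from {ARCHITECTURES}")
        self.config = config
        self.n_features = n_features
        arch_pe = config.positional_encoding
        if arch_pe == "auto":
            arch_pe = "sinusoidal" if arch == "cnn_transformer" else "none"
        self.pe = arch_pe

        d = config.d_model
        if arch == "baseline_static":
            self.fc1 = nn.Linear(n_features, config.rnn_hidden, rng)
            self.fc2 = nn.Linear(config.rnn_hidden, config.n_classes, rng)
        elif arch in ("rnn", "lstm"):
            cls = nn.RNN if arch == "rnn" else nn.LSTM
            self.encoder_in = cls(n_features, config.rnn_hidden, rng)
            self.fc1 = nn.Linear(config.rnn_hidden, config.rnn_hidden, rng)
            self.fc2 = nn.Linear(config.rnn_hidden, config.n_classes, rng)
        else:
            if arch == "cnn_transformer":
                self.encoder_in = nn.Conv1dTime(n_features, d, config.cnn_kernel, rng)
            else:
                self.encoder_in = nn.LSTM(n_features, d, rng)
            self.blocks = [
                nn.TransformerEncoderLayer(d, config.n_heads, config.ff_dim,
                                           config.dropout, rng)
                for _ in range(config.n_encoder_layers)]
            self.fc1 = nn.Linear(d, d, rng)
            self.fc2 = nn.Linear(d, config.n_classes, rng)

    def forward(self, X: np.ndarray, valid: np.ndarray,
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        arch = self.config.architecture
        if training and rng is not None and self.config.channel_dropout > 0:
            # whole-channel masking augmentation: a dropped channel becomes 0,
            # exactly what a mean-imputed missing channel looks like after
            # standardization; forces reliance on every informative channel
            keep = rng.random((X.shape[0], 1, X.shape[2])) >= self.config.channel_dropout
            X = X * keep
        if arch == "baseline_static":
            first = np.argmax(valid, axis=1)
            x0 = Tensor(X[np.arange(X.shape[0]), first, :])
            return self.fc2(self.fc1(x0).relu())

        x = Tensor(X)
        if arch in ("rnn", "lstm"):
            h = self.encoder_in(x, valid)
            pooled = nn.last_valid_state(h, valid)
        else:
            if arch == "cnn_transformer":
                h = self.encoder_in(x).relu()
            else:
                h = self.encoder_in(x, valid)
            if self.pe == "sinusoidal":
                h = h + nn.positional_encoding_from_end(X.shape[1], self.config.d_model)
            for block in self.blocks:
                h = block(h, valid, rng=rng, training=training)
            if self.config.pooling == "masked_mean":
                pooled = nn.masked_mean_pool(h, valid)
            else:
                pooled = nn.last_valid_state(h, valid)
        hid = nn.dropout(self.fc1(pooled).relu(), self.config.dropout, rng, training)
        return self.fc2(hid)


def build_model(config: ModelConfig, n_features: int, seed: int = 0) -> _SequenceNet:
    """Instantiate an untrained network with seeded initialization."""
    return _SequenceNet(config, n_features, np.random.default_rng(seed))


class SequenceClassifier(BaseEstimator, ClassifierMixin):
    """Binary sequence classifier over (n, T, N) windows with a valid mask.

    Parameters mirror ModelConfig/TrainConfig; inputs are expected already
    standardized (padding rows exactly zero).  ``fit`` minimizes softmax
    cross-entropy with Adam and early-stops on a stratified validation
    split of the training data; given the same data, parameters and
    ``random_state`` the fitted weights are bit-identical.
    """

    def __init__(self, architecture: str = "lstm_transformer", d_model: int = 64,
                 n_heads: int = 4, n_encoder_layers: int = 2, ff_dim: int = 128,
                 rnn_hidden: int = 64, cnn_kernel: int = 3, dropout: float = 0.1,
                 channel_dropout: float = 0.2,
                 positional_encoding: str = "auto", pooling: str = "last_valid",
                 learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 50,
                 early_stop_patience: int = 5, validation_fraction: float = 0.1,
                 weight_decay: float = 1e-3, ema_decay: float = 0.0,
                 random_state: int = 0):
        self.architecture = architecture
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_encoder_layers = n_encoder_layers
        self.ff_dim = ff_dim
        self.rnn_hidden = rnn_hidden
        self.cnn_kernel = cnn_kernel
        self.dropout = dropout
        self.channel_dropout = channel_dropout
        self.positional_encoding = positional_encoding
        self.pooling = pooling
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.weight_decay = weight_decay
        self.ema_decay = ema_decay
        self.random_state = random_state

    # ------------------------------------------------------------------ api
    def model_config(self) -> ModelConfig:
        return ModelConfig(
            architecture=self.architecture, d_model=self.d_model,
            n_heads=self.n_heads, n_encoder_layers=self.n_encoder_layers,
            ff_dim=self.ff_dim, rnn_hidden=self.rnn_hidden,
            cnn_kernel=self.cnn_kernel, dropout=self.dropout,
            channel_dropout=self.channel_dropout,
            positional_encoding=self.positional_encoding, pooling=self.pooling)

    def fit(self, X, y, valid_mask=None):
        X, y, valid = _check_Xyv(X, y, valid_mask)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(self.classes_)}")
        self.n_features_in_ = X.shape[2]

        net = build_model(self.model_config(), self.n_features_in_,
                          seed=self.random_state)
        train_rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 1]))

        n = X.shape[0]
        n_val = int(round(self.validation_fraction * n))
        use_val = n_val >= 2 and min(np.bincount(y_idx)) >= 2
        if use_val:
            tr_idx, val_idx = train_test_split(
                np.arange(n), test_size=n_val, stratify=y_idx,
                random_state=int(self.random_state) % (2 ** 32))
        else:
            tr_idx, val_idx = np.arange(n), None

        params = net.parameters()
        opt = nn.Adam(params, lr=self.learning_rate,
                      weight_decay=self.weight_decay)
        best_loss, best_state, best_epoch, since_best = np.inf, net.get_state(), 0, 0
        history = []
        ema = [p.data.copy() for p in params] if self.ema_decay > 0 else None

        for epoch in range(1, self.max_epochs + 1):
            order = train_rng.permutation(tr_idx)
            epoch_loss, n_seen = 0.0, 0
            for a in range(0, len(order), self.batch_size):
                b = order[a:a + self.batch_size]
                logits = net.forward(X[b], valid[b], rng=train_rng, training=True)
                loss = nn.softmax_cross_entropy(logits, y_idx[b])
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                if ema is not None:  # Polyak averaging smooths the learned function
                    d = self.ema_decay
                    for e, p in zip(ema, params):
                        e *= d
                        e += (1.0 - d) * p.data
                epoch_loss += float(loss.data) * len(b)
                n_seen += len(b)
            train_loss = epoch_loss / n_seen

            if ema is not None:  # validate (and keep) the averaged weights
                raw_state = net.get_state()
                net.set_state(ema)
            if val_idx is not None:
                monitor = self._eval_loss(net, X[val_idx], valid[val_idx], y_idx[val_idx])
            else:
                monitor = train_loss
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "monitor_loss": monitor})
            if monitor < best_loss - 1e-6:
                best_loss, best_state, best_epoch, since_best = monitor, net.get_state(), epoch, 0
                stop = False
            else:
                since_best += 1
                stop = since_best >= self.early_stop_patience
            if ema is not None:
                net.set_state(raw_state)  # resume optimization from raw weights
            if stop:
                break

        net.set_state(best_state)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(history)
        return self

    def _eval_loss(self, net, X, valid, y_idx) -> float:
        logits = net.forward(X, valid, training=False)
        return float(nn.softmax_cross_entropy(logits, y_idx).data)

    def predict_proba(self, X, valid_mask=None, batch_size: int = 256) -> np.ndarray:
        check_is_fitted(self, "net_")
        X, _, valid = _check_Xyv(X, None, valid_mask)
        if X.shape[2] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[2]} features; model was fitted with {self.n_features_in_}")
        params = self.net_.parameters()
        for p in params:  # no-grad fast path: skip tape construction
            p.requires_grad = False
        try:
            out = []
            for a in range(0, X.shape[0], batch_size):
                logits = self.net_.forward(X[a:a + batch_size],
                                           valid[a:a + batch_size], training=False)
                out.append(logits.softmax(axis=-1).data)
        finally:
            for p in params:
                p.requires_grad = True
        return np.concatenate(out, axis=0)

    def predict(self, X, valid_mask=None) -> np.ndarray:
        proba = self.predict_proba(X, valid_mask)
        # ties go to the positive (second) class
        return self.classes_[(proba[:, 1] >= proba[:, 0]).astype(int)]

    def decision_function(self, X, valid_mask=None) -> np.ndarray:
        return self.predict_proba(X, valid_mask)[:, 1]


def _check_Xyv(X, y, valid_mask):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"X must be 3-D (n, T, N), got shape {X.shape}")
    if valid_mask is None:
        valid = np.ones(X.shape[:2], dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool)
        if valid.shape != X.shape[:2]:
            raise ValueError("valid_mask shape must be (n, T)")
        if not valid.any(axis=1).all():
            raise ValueError("every window needs at least one valid time step")
    if y is not None:
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
    return X, y, valid


# --------------------------------------------------------------- protocol ops

def split_train_test(dataset: Dataset, ratio: float = 0.7, seed: int = 0,
                     ) -> tuple[Dataset, Dataset]:
    """Stratified 70:30-style split of an assembled dataset."""
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    idx = np.arange(dataset.n)
    tr, te = train_test_split(idx, train_size=ratio, stratify=y,
                              random_state=int(seed) % (2 ** 32))
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(te))


def kfold_indices(y, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (fit, validate) index pairs over a label vector."""
    y = np.asarray(y)
    if k > len(y):
        raise ValueError(f"k={k} exceeds n={len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2 ** 32))
    return [(fit, val) for fit, val in skf.split(np.zeros(len(y)), y)]


def train(dataset: Dataset, model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None) -> SequenceClassifier:
    """Fit a SequenceClassifier on an assembled (standardized) dataset."""
    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    clf = SequenceClassifier(
        architecture=mc.architecture, d_model=mc.d_model, n_heads=mc.n_heads,
        n_encoder_layers=mc.n_encoder_layers, ff_dim=mc.ff_dim,
        rnn_hidden=mc.rnn_hidden, cnn_kernel=mc.cnn_kernel, dropout=mc.dropout,
        channel_dropout=mc.channel_dropout,
        positional_encoding=mc.positional_encoding, pooling=mc.pooling,
        learning_rate=tc.learning_rate, batch_size=tc.batch_size,
        max_epochs=tc.max_epochs, early_stop_patience=tc.early_stop_patience,
        validation_fraction=tc.validation_fraction,
        weight_decay=tc.weight_decay, ema_decay=tc.ema_decay,
        random_state=tc.seed)
    clf.fit(dataset.X, dataset.y, dataset.valid)
    clf.feature_names_ = list(dataset.feature_names)
    if dataset.standardization is not None:
        clf.standardization_ = (np.asarray(dataset.standardization[0]),
                                np.asarray(dataset.standardization[1]))
    return clf


def predict_proba(fitted: SequenceClassifier, dataset: Dataset) -> np.ndarray:
    """Class probabilities for an assembled dataset, order preserved."""
    if hasattr(fitted, "feature_names_") and \
            list(dataset.feature_names) != list(fitted.feature_names_):
        raise ValueError("dataset feature names do not match the fitted model")
    return fitted.predict_proba(dataset.X, dataset.valid)


# ------------------------------------------------------------- serialization

def save_model(clf: SequenceClassifier, path) -> None:
    """Serialize a fitted classifier: weights as .npz + JSON sidecar."""
    check_is_fitted(clf, "net_")
    path = Path(path)
    arrays = {f"param_{i}": p.data for i, p in enumerate(clf.net_.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"params": clf.get_params(),
            "classes": np.asarray(clf.classes_).tolist(),
            "n_features_in": int(clf.n_features_in_),
            "best_epoch": int(clf.best_epoch_),
            "feature_names": getattr(clf, "feature_names_", None)}
    if hasattr(clf, "standardization_"):
        meta["standardization"] = {"mean": clf.standardization_[0].tolist(),
                                   "sd": clf.standardization_[1].tolist()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> SequenceClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    clf = SequenceClassifier(**meta["params"])
    clf.classes_ = np.asarray(meta["classes"])
    clf.n_features_in_ = meta["n_features_in"]
    clf.best_epoch_ = meta["best_epoch"]
    clf.history_ = []
    net = build_model(clf.model_config(), clf.n_features_in_, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        net.set_state([data[f"param_{i}"] for i in range(len(data.files))])
    clf.net_ = net
    if meta.get("feature_names"):
        clf.feature_names_ = meta["feature_names"]
    if meta.get("standardization"):
        clf.standardization_ = (np.asarray(meta["standardization"]["mean"]),
                                np.asarray(meta["standardization"]["sd"]))
    return clf
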