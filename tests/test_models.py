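"""Architecture contracts, the split/CV protocol, and training behaviour."""

import numpy as np
import pytest

from sepsishorizon import (
    SequenceClassifier, build_model, kfold_indices, load_model, save_model,
    split_train_test,
)
from sepsishorizon.io import ModelConfig
from sepsishorizon.models import ARCHITECTURES


def separable_windows(n=40, T=6, N=3, seed=0):
    """Tiny windows where class 1 carries +2 on channel 0 in the last rows."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, T, N))
    y = np.arange(n) % 2
    X[y == 1, T // 2:, 0] += 2.0
    valid = np.ones((n, T), dtype=bool)
    valid[: n // 4, : T // 3] = False  # some left padding
    X[~valid] = 0.0
    return X, y, valid


SMALL = dict(d_model=8, n_heads=2, n_encoder_layers=1, ff_dim=16,
             rnn_hidden=8, dropout=0.0, learning_rate=1e-2, batch_size=16,
             max_epochs=4, random_state=0)


class TestArchitectures:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_probabilities_sum_to_one(self, arch):
        X, y, valid = separable_windows()
        clf = SequenceClassifier(architecture=arch, **SMALL).fit(X, y, valid)
        proba = clf.predict_proba(X, valid)
        assert proba.shape == (len(y), 2)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_transformer_adds_parameters_over_lstm(self):
        lstm = build_model(ModelConfig(architecture="lstm", rnn_hidden=64), 10)
        hybrid = build_model(ModelConfig(architecture="lstm_transformer",
                                         d_model=64, rnn_hidden=64), 10)
        assert hybrid.n_parameters() > lstm.n_parameters()

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_padding_invariance(self, arch):
        """Re-padding windows to a different total length leaves the output
        probabilities unchanged — the key contract of the left-pad design."""
        X, y, valid = separable_windows()
        clf = SequenceClassifier(architecture=arch, **SMALL).fit(X, y, valid)
        p1 = clf.predict_proba(X, valid)
        pad = 5
        Xp = np.concatenate([np.zeros((X.shape[0], pad, X.shape[2])), X], axis=1)
        vp = np.concatenate([np.zeros((X.shape[0], pad), bool), valid], axis=1)
        p2 = clf.predict_proba(Xp, vp)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_batching_invariance(self):
        X, y, valid = separable_windows()
        clf = SequenceClassifier(architecture="lstm_transformer", **SMALL)
        clf.fit(X, y, valid)
        one = clf.predict_proba(X[:1], valid[:1])
        many = clf.predict_proba(X, valid)
        np.testing.assert_allclose(one[0], many[0], atol=1e-6)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_model(ModelConfig(architecture="gru"), 4)


class TestTraining:
    def test_loss_descends_on_separable_data(self):
        X, y, valid = separable_windows()
        clf = SequenceClassifier(architecture="lstm", **SMALL).fit(X, y, valid)
        assert clf.history_[-1]["train_loss"] <= clf.history_[0]["train_loss"]

    def test_seeded_training_is_bit_reproducible(self):
        X, y, valid = separable_windows()
        runs = []
        for _ in range(2):
            clf = SequenceClassifier(architecture="lstm_transformer", **SMALL)
            clf.fit(X, y, valid)
            runs.append([p.data.copy() for p in clf.net_.parameters()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_different_seed_changes_parameters(self):
        X, y, valid = separable_windows()
        a = SequenceClassifier(architecture="lstm", **SMALL).fit(X, y, valid)
        kw = dict(SMALL, random_state=1)
        b = SequenceClassifier(architecture="lstm", **kw).fit(X, y, valid)
        assert any(not np.array_equal(pa.data, pb.data)
                   for pa, pb in zip(a.net_.parameters(), b.net_.parameters()))

    def test_single_class_rejected(self):
        X, y, valid = separable_windows()
        with pytest.raises(ValueError, match="2 classes"):
            SequenceClassifier(**SMALL).fit(X, np.zeros_like(y), valid)

    def test_ema_weight_averaging_trains_and_differs(self):
        X, y, valid = separable_windows()
        plain = SequenceClassifier(architecture="lstm", **SMALL).fit(X, y, valid)
        kw = dict(SMALL)
        ema = SequenceClassifier(architecture="lstm", ema_decay=0.9, **kw)
        ema.fit(X, y, valid)
        proba = ema.predict_proba(X, valid)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert any(not np.array_equal(pa.data, pb.data)
                   for pa, pb in zip(plain.net_.parameters(), ema.net_.parameters()))

    def test_feature_count_mismatch_rejected(self):
        X, y, valid = separable_windows()
        clf = SequenceClassifier(architecture="lstm", **SMALL).fit(X, y, valid)
        with pytest.raises(ValueError, match="features"):
            clf.predict_proba(X[:, :, :2], valid)

    def test_sklearn_param_interface(self):
        clf = SequenceClassifier(architecture="rnn")
        assert clf.get_params()["architecture"] == "rnn"
        clf.set_params(d_model=16)
        assert clf.d_model == 16


class TestSplit:
    def _dataset(self, n=10):
        from sepsishorizon.preprocess import Dataset
        rng = np.random.default_rng(0)
        return Dataset(
            X=rng.normal(size=(n, 4, 2)), imputed=np.zeros((n, 4, 2), bool),
            valid=np.ones((n, 4), bool), y=np.arange(n) % 2,
            patient_ids=[f"p{i}" for i in range(n)], feature_names=["a", "b"],
            feature_means={"a": 0.0, "b": 0.0},
            window_end_offset_min=np.zeros(n, dtype=np.int64))

    def test_seventy_thirty(self):
        tr, te = split_train_test(self._dataset(10), 0.7, seed=0)
        assert tr.n == 7 and te.n == 3

    def test_disjoint_and_covering(self):
        ds = self._dataset(20)
        tr, te = split_train_test(ds, 0.7, seed=1)
        assert set(tr.patient_ids) | set(te.patient_ids) == set(ds.patient_ids)
        assert not set(tr.patient_ids) & set(te.patient_ids)

    def test_stratified(self):
        tr, te = split_train_test(self._dataset(20), 0.7, seed=2)
        assert abs(tr.y.mean() - 0.5) <= 0.1 and abs(te.y.mean() - 0.5) <= 0.2

    def test_seed_determinism(self):
        ds = self._dataset(20)
        a1, _ = split_train_test(ds, 0.7, seed=3)
        a2, _ = split_train_test(ds, 0.7, seed=3)
        b, _ = split_train_test(ds, 0.7, seed=4)
        assert a1.patient_ids == a2.patient_ids
        assert a1.patient_ids != b.patient_ids

    def test_single_class_rejected(self):
        ds = self._dataset(10)
        ds.y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            split_train_test(ds, 0.7, seed=0)


class TestKFold:
    def test_five_folds_of_twenty(self):
        y = np.arange(100) % 2
        folds = kfold_indices(y, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(val) == 20 for _, val in folds)

    def test_validation_folds_partition_the_set(self):
        y = np.arange(53) % 2
        folds = kfold_indices(y, k=5, seed=1)
        all_val = np.concatenate([val for _, val in folds])
        assert sorted(all_val) == list(range(53))

    def test_stratification_within_one_sample(self):
        y = np.arange(100) % 2
        for fit, val in kfold_indices(y, k=5, seed=2):
            assert abs(y[val].sum() - 10) <= 1

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_indices(np.array([0, 1]), k=5)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        X, y, valid = separable_windows()
        clf = SequenceClassifier(architecture="cnn_transformer", **SMALL)
        clf.fit(X, y, valid)
        save_model(clf, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(clf.predict_proba(X, valid),
                                   back.predict_proba(X, valid), atol=1e-12)
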