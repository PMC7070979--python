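"""Classifier families: selection, training, prediction, quantization."""

import numpy as np
import pytest

from emggate.models import (ModelConfig, ModelSpec, contiguous_folds,
                            cv_train, lasso_select, predict,
                            predict_quantized, quantize_model, satlins,
                            sbs_select, train_logreg, train_nn, train_rnn,
                            train_tree)


def _logistic_data(n=400, noise_cols=4, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n)
    y = (x0 > 0).astype(int)
    X = np.column_stack([x0] + [rng.standard_normal(n) for _ in range(noise_cols)])
    return X, y


class TestLassoSelect:
    def test_informative_feature_survives(self):
        X, y = _logistic_data()
        assert 0 in lasso_select(X, y, n_keep=1)

    def test_keep_all(self):
        X, y = _logistic_data()
        assert lasso_select(X, y, n_keep=5) == list(range(5))

    def test_duplicated_informative_column_not_both_kept(self):
        rng = np.random.default_rng(1)
        x0 = rng.standard_normal(500)
        y = (x0 > 0).astype(int)
        X = np.column_stack([x0, x0 + 1e-6 * rng.standard_normal(500),
                             rng.standard_normal(500)])
        sel = lasso_select(X, y, n_keep=1)
        assert len(set(sel) & {0, 1}) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lasso_select(np.zeros((10, 2)), np.zeros(10), 1)


class TestSbs:
    def test_noise_feature_removed_first(self):
        X, y = _logistic_data(noise_cols=2, seed=2)

        def scorer(Xs, ys, idx):
            from sklearn.linear_model import LogisticRegression
            clf = LogisticRegression(max_iter=500).fit(Xs[:, idx], ys)
            return clf.score(Xs[:, idx], ys)

        kept = sbs_select(X, y, scorer, n_keep=1)
        assert kept == [0]

    def test_keep_all_identity(self):
        X, y = _logistic_data()
        kept = sbs_select(X, y, lambda *a: 0.0, n_keep=X.shape[1])
        assert kept == list(range(X.shape[1]))


class TestLogreg:
    def test_separable_data_perfect(self):
        X, y = _logistic_data(noise_cols=1)
        X[:, 0] = np.where(y == 1, X[:, 0] + 5, X[:, 0] - 5)
        spec = train_logreg(X, y, ["a", "b"])
        assert np.mean(predict(spec, X) == y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_logreg(np.zeros((10, 2)), np.ones(10), ["a", "b"])

    def test_permutation_symmetry(self):
        X, y = _logistic_data(noise_cols=1, seed=3)
        s1 = train_logreg(X, y, ["a", "b"])
        s2 = train_logreg(X[:, ::-1], y, ["b", "a"])
        assert np.allclose(s1.params["w"], s2.params["w"][::-1], atol=1e-4)


class TestTree:
    def test_1d_separable_single_split(self):
        X = np.concatenate([np.arange(0, 5, 0.1), np.arange(5.1, 10, 0.1)])[:, None]
        y = (X[:, 0] > 5).astype(int)
        spec = train_tree(X, y, ["x"], max_splits_grid=(4,))
        assert np.mean(predict(spec, X) == y) == 1.0
        internal = [n for n in spec.params["nodes"] if n[0] != -1]
        assert len(internal) == 1
        assert internal[0][1] == pytest.approx(5.05, abs=0.1)

    def test_split_cap_respected(self, fd40, split):
        tr = fd40.select_windows(split.train)
        spec = train_tree(tr.X[:, :6].astype(float), tr.y,
                         [f"f{i}" for i in range(6)], max_splits_grid=(4,))
        internal = [n for n in spec.params["nodes"] if n[0] != -1]
        assert 1 <= len(internal) <= 4
        assert spec.meta["n_splits"] <= 4


class TestNn:
    def test_satlins_definition(self):
        assert satlins(np.array([2.0, -3.0, 0.4])).tolist() == [1.0, -1.0, 0.4]

    def test_xor_learnable(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (600, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        spec = train_nn(X, y, ["a", "b"], hidden_units=6, max_epochs=400, seed=1)
        assert np.mean(predict(spec, X) == y) >= 0.95

    def test_zero_weight_network_outputs_bias(self):
        spec = ModelSpec("nn", ["a"], {
            "W1": np.zeros((1, 3)), "b1": np.zeros(3),
            "W2": np.zeros(3), "b2": 0.9})
        assert np.all(predict(spec, np.random.randn(5, 1)) == 1)  # 0.9 > 0.5

    def test_early_stopping_records_epoch(self):
        X, y = _logistic_data(noise_cols=1)
        spec = train_nn(X, y, ["a", "b"], hidden_units=3, max_epochs=50, seed=0)
        assert 1 <= spec.meta["epochs"] <= 50


class TestRnn:
    def _seqs(self, seed=0, n=8, T=60):
        rng = np.random.default_rng(seed)
        Xs, ys = [], []
        for _ in range(n):
            y = np.repeat(rng.integers(0, 2, T // 20), 20)[:T].astype(float)
            x = y[:, None] * 2 - 1 + 0.3 * rng.standard_normal((T, 2))
            Xs.append(x)
            ys.append(y)
        return Xs, ys

    def test_zero_recurrence_equals_feedforward(self):
        """With Wr = 0 the quantized recurrent forward pass is bit-identical
        to the quantized feedforward network with the same weights."""
        rng = np.random.default_rng(4)
        W1, b1, W2, b2 = rng.normal(size=(3, 5)), rng.normal(size=5), rng.normal(size=5), 0.4
        nn = ModelSpec("nn", list("abc"), {"W1": W1, "b1": b1, "W2": W2, "b2": b2})
        rnn = ModelSpec("rnn", list("abc"), {"W1": W1, "Wr": np.zeros((5, 5)),
                                             "b1": b1, "W2": W2, "b2": b2})
        Xq = rng.integers(-1024, 1024, (50, 3))
        assert np.array_equal(predict_quantized(quantize_model(nn), Xq),
                              predict_quantized(quantize_model(rnn), Xq))

    def test_learns_sequence_classes(self):
        Xs, ys = self._seqs()
        spec = train_rnn(Xs, ys, ["a", "b"], hidden_units=4, max_epochs=40, seed=0)
        pred = predict(spec, Xs[0])
        assert np.mean(pred == ys[0]) >= 0.9

    def test_initial_hidden_state_is_zero(self):
        """Prediction on a sequence does not depend on any earlier call."""
        Xs, ys = self._seqs(seed=5)
        spec = train_rnn(Xs, ys, ["a", "b"], hidden_units=3, max_epochs=5, seed=0)
        a = predict(spec, Xs[0])
        predict(spec, Xs[1])
        b = predict(spec, Xs[0])
        assert np.array_equal(a, b)


class TestQuantization:
    def test_weight_scale(self):
        spec = ModelSpec("logreg", ["a"], {"w": np.array([0.5]), "b": -0.25})
        q = quantize_model(spec)
        assert q.params["w"].tolist() == [512] and q.params["b"] == -256

    def test_dequantized_within_half_lsb(self):
        rng = np.random.default_rng(6)
        W = rng.uniform(-2, 2, (4, 3))
        spec = ModelSpec("nn", list("abcd"),
                         {"W1": W, "b1": rng.uniform(-1, 1, 3),
                          "W2": rng.uniform(-1, 1, 3), "b2": 0.1})
        q = quantize_model(spec)
        assert np.max(np.abs(q.params["W1"] / 1024 - W)) <= 1 / 2048

    def test_tree_quantization_exact_on_integer_features(self, fd40, split):
        tr = fd40.select_windows(split.train)
        X = tr.X[:, :5].astype(float)
        spec = train_tree(X, tr.y, [f"f{i}" for i in range(5)], max_splits_grid=(8,))
        q = quantize_model(spec)
        assert np.array_equal(predict(spec, X), predict_quantized(q, tr.X[:, :5]))

    def test_logreg_decision_agreement(self):
        X, y = _logistic_data(noise_cols=1, seed=7)
        X[:, 0] = np.where(y == 1, X[:, 0] + 3, X[:, 0] - 3)
        spec = train_logreg(X, y, ["a", "b"])
        Xq = np.rint(X * 1024).astype(np.int64)
        agree = np.mean(predict(spec, X) == predict_quantized(quantize_model(spec), Xq))
        assert agree >= 0.99


class TestCv:
    def test_folds_partition_pool(self):
        pool = list(range(40))
        folds = contiguous_folds(pool, k=5, seed=0)
        assert sorted(sum(folds, [])) == pool
        assert all(len(f) > 0 for f in folds)

    def test_cv_train_selects_and_reports(self, fd40, split):
        def trainer(fd_tr, fd_va, g):
            return train_tree(fd_tr.X.astype(float), fd_tr.y,
                              fd40.names, max_splits_grid=(g,))
        cfg = ModelConfig(family="tree", seed=0)
        spec, report = cv_train("tree", fd40, split.train, trainer, [2, 8], cfg)
        assert report["winner"] in {"2", "8"}
        assert spec.family == "tree"
        assert 0 <= report["cv_accuracy"] <= 100

    def test_cv_deterministic(self, fd40, split):
        def trainer(fd_tr, fd_va, g):
            return train_tree(fd_tr.X.astype(float), fd_tr.y,
                              fd40.names, max_splits_grid=(g,))
        cfg = ModelConfig(family="tree", seed=1)
        _, r1 = cv_train("tree", fd40, split.train, trainer, [4], cfg)
        _, r2 = cv_train("tree", fd40, split.train, trainer, [4], cfg)
        assert r1 == r2


def test_model_spec_json_roundtrip():
    spec = ModelSpec("logreg", ["a", "b"], {"w": np.array([0.25, -1.5]), "b": 0.125})
    back = ModelSpec.from_dict(spec.to_dict())
    assert back.family == "logreg"
    assert np.array_equal(back.params["w"], spec.params["w"])
    assert back.params["b"] == spec.params["b"]
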