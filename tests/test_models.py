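"""Classifiers: SMOTE, logistic regression, MLP, tuning, probability tables."""

import numpy as np
import pytest

from spikeloc.models import (
    BalancedLogisticRegression,
    ProbabilityTable,
    SpikeTrainMLP,
    hyperparameter_space,
    predict_probabilities,
    resample,
    smote_resample,
    tune_hyperparameters,
)
from spikeloc.metrics import balanced_accuracy, chance_level


def _blobs(rng, n_per=60, d=4, sep=4.0, k=3):
    X = np.vstack([rng.normal(i * sep, 1.0, size=(n_per, d)) for i in range(k)])
    y = np.repeat(np.arange(k), n_per)
    return X, y


class TestSmote:
    def test_balanced_input_returned_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        Xr, yr = smote_resample(X, y, seed=1)
        np.testing.assert_array_equal(Xr, X)
        np.testing.assert_array_equal(yr, y)

    def test_synthetic_points_are_convex_combinations(self):
        # 1-D minority at {0, 2} with k=1: every synthetic value lies in [0, 2]
        X = np.array([[0.0], [2.0]] + [[10.0]] * 10)
        y = np.array([0, 0] + [1] * 10)
        Xr, yr = smote_resample(X, y, k_neighbors=1, seed=2)
        synth = Xr[len(X):]
        assert (yr[len(X):] == 0).all()
        assert ((synth >= 0.0) & (synth <= 2.0)).all()

    def test_all_class_counts_equal_majority(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(35, 2))
        y = np.array([0] * 5 + [1] * 10 + [2] * 20)
        _, yr = smote_resample(X, y, seed=4)
        _, counts = np.unique(yr, return_counts=True)
        assert (counts == 20).all()

    def test_singleton_class_falls_back_to_duplication(self):
        X = np.array([[0.0, 0.0]] + [[1.0, 1.0]] * 6)
        y = np.array([0] + [1] * 6)
        with pytest.warns(UserWarning, match="duplicating"):
            Xr, yr = smote_resample(X, y, seed=5)
        np.testing.assert_array_equal(Xr[yr == 0], np.zeros((6, 2)))

    def test_originals_preserved(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 3))
        y = np.array([0] * 5 + [1] * 10)
        Xr, yr = smote_resample(X, y, seed=7)
        np.testing.assert_array_equal(Xr[:15], X)

    @pytest.mark.parametrize("method", ["undersample", "oversample"])
    def test_other_resamplers_balance_counts(self, method):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = np.array([0] * 10 + [1] * 20)
        _, yr = resample(X, y, method, seed=9)
        _, counts = np.unique(yr, return_counts=True)
        assert counts[0] == counts[1]


class TestLogistic:
    def test_linearly_separable_learned(self):
        rng = np.random.default_rng(10)
        X, y = _blobs(rng, sep=6.0, k=2)
        model = BalancedLogisticRegression(seed=0).fit(X, y)
        assert balanced_accuracy(y, model.predict(X)) >= 0.99

    def test_label_shuffled_near_chance(self):
        rng = np.random.default_rng(11)
        X, y = _blobs(rng, n_per=150, k=3)
        y_shuf = rng.permutation(y)
        idx = rng.permutation(len(y))
        tr, va = idx[:300], idx[300:]
        model = BalancedLogisticRegression(seed=0).fit(X[tr], y_shuf[tr])
        ba = balanced_accuracy(y_shuf[va], model.predict(X[va]))
        n_per_class = len(va) / 3
        se = np.sqrt((1 / 3) * (2 / 3) / n_per_class)
        assert abs(ba - 1 / 3) < 3 * se

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        X, y = _blobs(rng)
        p1 = BalancedLogisticRegression(seed=3).fit(X, y).predict_proba(X)
        p2 = BalancedLogisticRegression(seed=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(13)
        X, y = _blobs(rng)
        X = np.hstack([X, np.ones((len(X), 1))])
        with pytest.warns(UserWarning, match="constant feature"):
            model = BalancedLogisticRegression(seed=0).fit(X, y)
        assert model.predict(X).shape == y.shape


class TestMlp:
    def test_xor_needs_nonlinearity(self):
        rng = np.random.default_rng(14)
        n = 200
        X = rng.uniform(-1, 1, size=(n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        mlp = SpikeTrainMLP(hidden_nodes=30, learning_rate=1e-2, batch_size=32,
                            resampling="none", max_epochs=200, seed=0)
        mlp.fit(X, y)
        assert balanced_accuracy(y, mlp.predict(X)) > 0.9
        lin = BalancedLogisticRegression(seed=0).fit(X, y)
        assert balanced_accuracy(y, lin.predict(X)) < 0.7

    def test_separable_blobs_with_validation_early_stopping(self):
        rng = np.random.default_rng(15)
        X, y = _blobs(rng, n_per=100, sep=5.0)
        idx = rng.permutation(len(y))
        tr, va, te = idx[:180], idx[180:240], idx[240:]
        mlp = SpikeTrainMLP(hidden_nodes=50, learning_rate=1e-2, batch_size=50,
                            max_epochs=100, seed=1)
        mlp.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        assert balanced_accuracy(y[te], mlp.predict(X[te])) >= 0.95
        assert mlp.val_balanced_accuracy_ >= 0.95

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(16)
        X, y = _blobs(rng, n_per=40)
        p1 = SpikeTrainMLP(max_epochs=5, seed=2).fit(X, y).predict_proba(X)
        p2 = SpikeTrainMLP(max_epochs=5, seed=2).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_smote_improves_balanced_accuracy_on_imbalanced_task(self):
        # heavily imbalanced two-blob task; average over seeds
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X0 = rng.normal(0.0, 1.0, size=(400, 4))
            X1 = rng.normal(1.4, 1.0, size=(16, 4))
            X = np.vstack([X0, X1])
            y = np.array([0] * 400 + [1] * 16)
            idx = rng.permutation(len(y))
            tr, te = idx[: len(y) // 2], idx[len(y) // 2:]
            scores = {}
            for rs in ("none", "smote"):
                mlp = SpikeTrainMLP(hidden_nodes=20, learning_rate=1e-2,
                                    batch_size=64, resampling=rs,
                                    max_epochs=30, seed=seed)
                mlp.fit(X[tr], y[tr])
                scores[rs] = balanced_accuracy(y[te], mlp.predict(X[te]))
            deltas.append(scores["smote"] - scores["none"])
        assert np.mean(deltas) >= 0.0


class TestHyperparameterSearch:
    def test_grids_match_per_representation(self):
        isi = hyperparameter_space("isi_dist")
        assert isi.hidden_nodes == tuple(range(50, 601, 50))
        assert isi.learning_rate == (1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
        assert isi.batch_size == tuple(range(25, 501, 50))
        assert isi.alpha_l2 == (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 5.0, 10.0)
        avg = hyperparameter_space("avg_psth")
        assert avg.hidden_nodes == tuple(range(30, 301, 50))
        assert avg.learning_rate == (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
        assert avg.batch_size == tuple(range(50, 601, 50))
        assert avg.alpha_l2 == (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
        cat = hyperparameter_space("cat_psth")
        assert cat.hidden_nodes == tuple(range(50, 601, 50))
        for space in (isi, avg, cat):
            assert space.beta1 == (0.5, 0.6, 0.7, 0.8, 0.9)

    def test_budget_one_returns_single_point(self):
        rng = np.random.default_rng(17)
        X, y = _blobs(rng, n_per=30)
        space = hyperparameter_space("avg_psth")
        best, log = tune_hyperparameters(space, X[:60], y[:60], X[60:], y[60:],
                                         budget=1, seed=0, max_epochs=3)
        assert len(log) == 1
        assert best in space

    def test_best_dominates_all_logged_trials(self):
        rng = np.random.default_rng(18)
        X, y = _blobs(rng, n_per=30)
        space = hyperparameter_space("avg_psth")
        best, log = tune_hyperparameters(space, X[:60], y[:60], X[60:], y[60:],
                                         budget=4, seed=1, max_epochs=3)
        best_row = max(log["objective"])
        assert all(log["objective"] <= best_row)

    def test_planted_optimum_recovered_by_exhaustion(self):
        # a mock model whose objective depends only on hidden_nodes, peaked at 80
        from spikeloc.models import HyperparameterSpace

        space = HyperparameterSpace(
            hidden_nodes=(30, 80, 130), learning_rate=(1e-3,),
            batch_size=(50,), alpha_l2=(1e-4,), beta1=(0.9,), resampling=("none",),
        )

        class Mock:
            def __init__(self, hp, seed):
                self.hp = hp

            def fit(self, X, y, X_val=None, y_val=None):
                return self

            def predict(self, X):
                # encode objective: perfect iff hidden_nodes == 80
                if self.hp["hidden_nodes"] == 80:
                    return np.asarray(_Y_VAL)
                return np.zeros(len(X), dtype=int)

        global _Y_VAL
        rng = np.random.default_rng(19)
        Xv = rng.normal(size=(30, 2))
        _Y_VAL = rng.integers(3, size=30)
        best, log = tune_hyperparameters(
            space, Xv, _Y_VAL, Xv, _Y_VAL, strategy="exhaustive",
            model_factory=lambda hp, s: Mock(hp, s),
        )
        assert best["hidden_nodes"] == 80
        assert len(log) == 3


class TestProbabilityTable:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(20)
        X, y = _blobs(rng, n_per=30)
        model = BalancedLogisticRegression(seed=0).fit(X, y)
        pt = predict_probabilities(model, X)
        np.testing.assert_allclose(pt.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_tie_breaks_to_lowest_class_index(self):
        pt = ProbabilityTable(("u0",), ("a", "b"), np.array([[0.5, 0.5]]))
        assert pt.predicted_labels[0] == "a"

    def test_training_accuracy_bookkeeping(self):
        rng = np.random.default_rng(21)
        X, y = _blobs(rng, sep=6.0)
        model = BalancedLogisticRegression(seed=0).fit(X, y)
        pt = predict_probabilities(model, X)
        ba = balanced_accuracy(y, pt.predicted_labels.astype(int))
        assert ba == pytest.approx(model.train_balanced_accuracy_, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(22)
        X, y = _blobs(rng, n_per=20)
        model = BalancedLogisticRegression(seed=0).fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            predict_probabilities(model, X[:, :2])

    def test_permuted_label_mlp_pipeline_canary(self):
        # leakage canary: training on permuted labels scores at chance
        rng = np.random.default_rng(23)
        X, y = _blobs(rng, n_per=200, k=4, sep=3.0)
        y_shuf = rng.permutation(y)
        idx = rng.permutation(len(y))
        tr, va = idx[:500], idx[500:]
        mlp = SpikeTrainMLP(hidden_nodes=30, learning_rate=1e-2, batch_size=100,
                            max_epochs=20, seed=3)
        mlp.fit(X[tr], y_shuf[tr])
        ba = balanced_accuracy(y_shuf[va], mlp.predict(X[va]))
        n_per_class = len(va) / 4
        se = np.sqrt(0.25 * 0.75 / n_per_class)
        assert abs(ba - chance_level(4)) < 3 * se
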