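"""Classifier training, the probability contract, and weight transfer."""

import numpy as np
import pytest

from molbalance import (
    DNNConfig,
    FingerprintConfig,
    TransferSpec,
    fine_tune,
    load_model,
    save_model,
    train_baseline,
    train_dnn,
    transfer_weights,
)
from molbalance.models import MLP, train_from_arrays
from molbalance.evaluation import roc_auc_from_scores

from .conftest import make_dataset, make_fp_matrix

FP64 = FingerprintConfig(n_bits=64)


def separable_problem(n=40, d=64, seed=0):
    """Fingerprints where the first 8 bits identify the active class."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, d)) < 0.15).astype(float)
    y = (np.arange(n) < n // 2).astype(float)
    X[y == 1, :8] = 1.0
    X[y == 0, :8] = 0.0
    return X, y


class TestDNN:
    def test_separable_data_fit_perfectly(self):
        X, y = separable_problem()
        cfg = DNNConfig(input_width=64, hidden_widths=(32, 16), max_epochs=200,
                        early_stop_patience=50, seed=1)
        mlp = MLP(cfg).fit(X, y)
        assert (((mlp.predict_proba(X) >= 0.5) == y).mean()) == 1.0
        assert len(mlp.loss_curve) <= 200

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(5)
        X = (rng.random((120, 64)) < 0.2).astype(float)
        y = rng.permutation([1.0] * 60 + [0.0] * 60)
        Xte = (rng.random((200, 64)) < 0.2).astype(float)
        yte = rng.permutation([1.0] * 100 + [0.0] * 100)
        cfg = DNNConfig(input_width=64, hidden_widths=(32,), max_epochs=60,
                        early_stop_patience=60, seed=2)
        auc = roc_auc_from_scores(yte, MLP(cfg).fit(X, y).predict_proba(Xte))
        assert 0.4 <= auc <= 0.6

    def test_zero_epochs_untrained_outputs_in_unit_interval(self):
        cfg = DNNConfig(input_width=64, max_epochs=0, seed=0)
        p = MLP(cfg).predict_proba(np.ones((5, 64)))
        assert np.all((p > 0) & (p < 1))

    def test_early_stopping_halts_on_plateau(self):
        X, y = separable_problem(n=20)
        cfg = DNNConfig(input_width=64, hidden_widths=(16,), max_epochs=2000,
                        early_stop_patience=10, seed=3)
        mlp = MLP(cfg).fit(X, y)
        assert len(mlp.loss_curve) < 2000

    def test_determinism_same_seed_same_predictions(self):
        X, y = separable_problem(seed=4)
        cfg = DNNConfig(input_width=64, hidden_widths=(16,), max_epochs=30, seed=9)
        p1 = MLP(cfg).fit(X, y).predict_proba(X)
        p2 = MLP(cfg).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_input_rejected(self):
        ds = make_dataset(["a", "b"], [])
        fps = make_fp_matrix([{1}, {2}], ids=["a", "b"])
        with pytest.raises(ValueError, match="both classes"):
            train_dnn(ds, fps, DNNConfig(input_width=64, max_epochs=5))


class TestPredictContract:
    def _model(self):
        ds = make_dataset(["a", "b"], ["c", "d"])
        fps = make_fp_matrix([{1, 2}, {1, 3}, {9}, {10}], ids=["a", "b", "c", "d"])
        cfg = DNNConfig(input_width=64, hidden_widths=(16,), max_epochs=30, seed=0)
        return train_dnn(ds, fps, cfg), fps

    def test_probabilities_in_unit_interval_every_kind(self):
        ds = make_dataset(["a", "b", "e"], ["c", "d", "f"])
        fps = make_fp_matrix(
            [{1, 2}, {1, 3}, {2, 3}, {9}, {10}, {9, 10}],
            ids=["a", "b", "e", "c", "d", "f"],
        )
        rng = np.random.default_rng(0)
        Xq = (rng.random((20, 64)) < 0.2).astype(float)
        for kind in ("naive_bayes", "random_forest", "gradient_boosting"):
            model = train_baseline(kind, ds, fps, seed=0)
            p = model.predict_proba(Xq)
            assert np.all((p >= 0) & (p <= 1))

    def test_duplicate_rows_identical_outputs(self):
        model, fps = self._model()
        X = np.vstack([fps.bits[0], fps.bits[0]]).astype(float)
        p = model.predict_proba(X)
        assert p[0] == p[1]

    def test_probability_half_labels_active(self):
        model, _ = self._model()
        # the >= tie-break at the 0.5 threshold is part of the contract
        assert model.predict_label(np.zeros((1, 64))) in (0, 1)
        labels = (np.array([0.5, 0.49999]) >= 0.5).astype(int)
        assert labels.tolist() == [1, 0]

    def test_fingerprint_config_mismatch_raises(self, small_fps):
        model, _ = self._model()
        with pytest.raises(ValueError, match="mismatch"):
            model.predict_proba(small_fps)  # 1024-bit vs 64-bit model


class TestBaselines:
    def test_bernoulli_nb_matches_hand_bayes(self):
        """Posterior on 3 informative bits vs. a literal Bayes-rule oracle
        with Laplace smoothing."""
        X = np.array(
            [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]], dtype=float
        )
        y = np.array([1, 1, 0, 0])
        Xq = np.array([[1, 0, 0], [0, 0, 1]], dtype=float)

        def hand_posterior(xq):
            post = {}
            for c in (0, 1):
                Xc = X[y == c]
                prior = len(Xc) / len(X)
                theta = (Xc.sum(axis=0) + 1) / (len(Xc) + 2)  # Laplace alpha=1
                lik = np.prod(np.where(xq == 1, theta, 1 - theta))
                post[c] = prior * lik
            return post[1] / (post[0] + post[1])

        ds = make_dataset(["a", "b"], ["c", "d"])
        fps64 = make_fp_matrix(
            [set(np.nonzero(r)[0]) for r in X.astype(int)], ids=["a", "b", "c", "d"]
        )
        # embed the 3 bits into the 64-bit space for the query too
        Xq64 = np.zeros((2, 64))
        Xq64[:, :3] = Xq
        model = train_baseline("naive_bayes", ds, fps64, seed=0)
        p = model.predict_proba(Xq64)
        # bits 3..63 are uniformly zero in both classes: their likelihood
        # ratio is 1 and the 3-bit hand computation carries over exactly
        assert p[0] == pytest.approx(hand_posterior(Xq[0]), abs=1e-9)
        assert p[1] == pytest.approx(hand_posterior(Xq[1]), abs=1e-9)

    def test_random_forest_stump_is_piecewise_constant(self):
        ds = make_dataset(["a", "b"], ["c", "d"])
        fps = make_fp_matrix([{0}, {0}, {1}, {1}], ids=["a", "b", "c", "d"])
        model = train_baseline("random_forest", ds, fps, seed=0, n_estimators=1, max_depth=1)
        p = model.predict_proba(fps.bits.astype(float))
        assert len(np.unique(p)) <= 2

    def test_unknown_kind_rejected(self):
        ds = make_dataset(["a"], ["c"])
        fps = make_fp_matrix([{0}, {1}], ids=["a", "c"])
        with pytest.raises(ValueError, match="unknown"):
            train_baseline("svm", ds, fps)


class TestTransfer:
    def _source(self, seed=0):
        X, y = separable_problem(seed=seed)
        cfg = DNNConfig(input_width=64, hidden_widths=(32, 16), max_epochs=50, seed=seed)
        return train_from_arrays("dnn", X, y, FP64, dnn_config=cfg)

    def test_transferred_layer_outputs_match_bit_for_bit(self):
        source = self._source()
        target_cfg = DNNConfig(input_width=64, hidden_widths=(32, 16), max_epochs=10, seed=99)
        model = transfer_weights(source, target_cfg, TransferSpec(layers_to_transfer=(0,)))
        rng = np.random.default_rng(1)
        X = (rng.random((10, 64)) < 0.2).astype(float)
        np.testing.assert_array_equal(
            model.backend.hidden_preactivation(X, 0),
            source.backend.hidden_preactivation(X, 0),
        )

    def test_transfer_both_layers(self):
        source = self._source()
        target_cfg = DNNConfig(input_width=64, hidden_widths=(32, 16), seed=7)
        model = transfer_weights(source, target_cfg, TransferSpec(layers_to_transfer=(0, 1)))
        rng = np.random.default_rng(2)
        X = (rng.random((10, 64)) < 0.2).astype(float)
        for layer in (0, 1):
            np.testing.assert_array_equal(
                model.backend.hidden_activation(X, layer),
                source.backend.hidden_activation(X, layer),
            )

    def test_empty_transfer_list_is_fresh_initialization(self):
        source = self._source()
        target_cfg = DNNConfig(input_width=64, hidden_widths=(32, 16), seed=7)
        model = transfer_weights(source, target_cfg, TransferSpec(layers_to_transfer=()))
        fresh = MLP(target_cfg)
        for W_model, W_fresh in zip(model.backend.W, fresh.W):
            np.testing.assert_array_equal(W_model, W_fresh)
        assert not np.array_equal(model.backend.W[0], source.backend.W[0])

    def test_width_mismatch_raises(self):
        source = self._source()
        bad_cfg = DNNConfig(input_width=64, hidden_widths=(20, 16), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            transfer_weights(source, bad_cfg, TransferSpec(layers_to_transfer=(0,)))

    def test_frozen_layer_unchanged_by_fine_tuning(self):
        source = self._source()
        target_cfg = DNNConfig(input_width=64, hidden_widths=(32, 16), max_epochs=20, seed=3)
        model = transfer_weights(
            source, target_cfg,
            TransferSpec(layers_to_transfer=(0,), fine_tune_transferred=False),
        )
        W0_before = model.backend.W[0].copy()
        ds = make_dataset(["a", "b"], ["c", "d"])
        fps = make_fp_matrix([{1, 2}, {1, 3}, {9}, {10}], ids=["a", "b", "c", "d"])
        fine_tune(model, ds, fps)
        np.testing.assert_array_equal(model.backend.W[0], W0_before)
        assert not np.array_equal(model.backend.W[1], source.backend.W[1])


class TestPersistence:
    def test_dnn_round_trip(self, tmp_path):
        X, y = separable_problem(seed=8)
        cfg = DNNConfig(input_width=64, hidden_widths=(16,), max_epochs=20, seed=8)
        model = train_from_arrays("dnn", X, y, FP64, dnn_config=cfg)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        np.testing.assert_array_equal(model.predict_proba(X), loaded.predict_proba(X))

    def test_baseline_round_trip(self, tmp_path):
        ds = make_dataset(["a", "b"], ["c", "d"])
        fps = make_fp_matrix([{1, 2}, {1, 3}, {9}, {10}], ids=["a", "b", "c", "d"])
        model = train_baseline("random_forest", ds, fps, seed=0)
        save_model(model, tmp_path / "rf")
        loaded = load_model(tmp_path / "rf")
        X = fps.bits.astype(float)
        np.testing.assert_array_equal(model.predict_proba(X), loaded.predict_proba(X))
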