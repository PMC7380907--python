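import numpy as np
import pytest

from egonet.models import (
    EGONetConfig,
    TrainedModel,
    apply_scaler,
    fit_scaler,
    predict,
    train_baseline,
    train_egonet,
)
from egonet.relationship_features import STRUCTURAL_ZERO_POSITIONS

FAST = EGONetConfig(conv_channels=(4, 8, 8), fc_width=16, epochs=10,
                    batch_size=64, dropout_rate=0.0, seed=0)


def separable_grids(n, rng, noise=0.05):
    """Grids whose cell (0, 0) carries the label, everything else noise."""
    labels = (rng.random(n) < 0.5).astype(int)
    grids = rng.random((n, 18, 20))
    grids[:, 0, 0] = labels + noise * rng.standard_normal(n)
    return grids, labels


class TestScaler:
    def test_range(self, rng):
        grids = rng.normal(size=(40, 18, 20))
        scaler = fit_scaler(grids)
        out = apply_scaler(grids, scaler)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_structural_zeros_pass_through(self, rng):
        grids = rng.random((20, 18, 20))
        flat = grids.reshape(20, -1)
        flat[:, list(STRUCTURAL_ZERO_POSITIONS)] = 0.0
        scaler = fit_scaler(grids)
        out = apply_scaler(grids, scaler).reshape(20, -1)
        assert np.all(out[:, list(STRUCTURAL_ZERO_POSITIONS)] == 0.0)

    def test_clipping_above_train_max(self, rng):
        train = rng.random((30, 18, 20))
        scaler = fit_scaler(train)
        test = train[:1].copy()
        test[0, 3, 4] = 99.0
        out = apply_scaler(test, scaler)
        assert out[0, 3, 4] == 1.0

    def test_constant_cell_maps_to_zero(self, rng):
        grids = rng.random((10, 18, 20))
        grids[:, 5, 5] = 7.0
        out = apply_scaler(grids, fit_scaler(grids))
        assert np.all(out[:, 5, 5] == 0.0)

    def test_leakage_guard(self, rng):
        # scaler fitted on the train fold is unaffected by test-fold values
        grids = rng.random((50, 18, 20))
        train_idx = np.arange(40)
        s1 = fit_scaler(grids[train_idx])
        grids[40:] += 100.0
        s2 = fit_scaler(grids[train_idx])
        assert np.array_equal(s1.lo, s2.lo) and np.array_equal(s1.hi, s2.hi)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.empty((0, 18, 20)))


class TestEGONet:
    def test_capacity_on_separable_data(self, rng):
        grids, labels = separable_grids(400, rng)
        cfg = EGONetConfig(conv_channels=(4, 8, 8), fc_width=16, epochs=40,
                           batch_size=64, dropout_rate=0.0, seed=1)
        model = train_egonet(grids, labels, cfg)
        _, pred = predict(model, grids)
        assert (pred == labels).mean() >= 0.99

    def test_determinism(self, rng):
        grids, labels = separable_grids(120, rng)
        m1 = train_egonet(grids, labels, FAST)
        m2 = train_egonet(grids, labels, FAST)
        p1, _ = predict(m1, grids)
        p2, _ = predict(m2, grids)
        assert np.array_equal(p1, p2)

    def test_probabilities_sum_to_one(self, rng):
        grids, labels = separable_grids(80, rng)
        model = train_egonet(grids, labels, FAST)
        proba = model.estimator.predict_proba(
            apply_scaler(grids, model.scaler))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_permuted_labels_give_null_auprg(self, rng):
        from egonet.evaluation import auprg, prg_curve

        grids, labels = separable_grids(200, rng)
        aucs = []
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(labels)
            cfg = EGONetConfig(conv_channels=(4, 8, 8), fc_width=16,
                               epochs=8, batch_size=64, dropout_rate=0.0,
                               seed=seed)
            model = train_egonet(grids[:150], perm[:150], cfg)
            prob, _ = predict(model, grids[150:])
            if 0 < perm[150:].sum() < 50:
                aucs.append(auprg(prg_curve(perm[150:], prob)))
        assert abs(float(np.mean(aucs))) < 0.35  # within noise of no skill

    def test_full_batch_loss_decreases(self, rng):
        grids, labels = separable_grids(32, rng)
        cfg = EGONetConfig(conv_channels=(4, 8, 8), fc_width=16, epochs=25,
                           batch_size=32, dropout_rate=0.0,
                           optimizer="sgd", learning_rate=0.01, seed=0)
        model = train_egonet(grids, labels, cfg)
        trace = np.array(model.estimator.loss_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_loss_trace_recorded(self, rng):
        grids, labels = separable_grids(60, rng)
        model = train_egonet(grids, labels, FAST)
        assert len(model.estimator.loss_trace) == FAST.epochs


class TestBaselines:
    def test_perfect_feature_recovery(self, rng):
        grids, labels = separable_grids(1000, rng, noise=0.01)
        from egonet.evaluation import confusion_metrics

        for kind in ("linreg", "rf"):
            model = train_baseline(grids[:800], labels[:800], kind, seed=0,
                                   n_trees=100)
            _, pred = predict(model, grids[800:])
            f1 = confusion_metrics(labels[800:], pred)["weighted_f1"]
            assert f1 >= 0.95, kind

    def test_rf_determinism(self, rng):
        grids, labels = separable_grids(150, rng)
        m1 = train_baseline(grids, labels, "rf", seed=3, n_trees=50)
        m2 = train_baseline(grids, labels, "rf", seed=3, n_trees=50)
        p1, _ = predict(m1, grids)
        p2, _ = predict(m2, grids)
        assert np.array_equal(p1, p2)

    def test_constant_labels(self, rng):
        grids = rng.random((50, 18, 20))
        labels = np.zeros(50, dtype=int)
        model = train_baseline(grids, labels, "rf", seed=0, n_trees=20)
        _, pred = predict(model, grids)
        assert np.all(pred == 0)

    def test_unknown_kind(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            train_baseline(rng.random((10, 18, 20)), np.zeros(10), "svm")

    def test_logistic_option(self, rng):
        grids, labels = separable_grids(200, rng)
        model = train_baseline(grids, labels, "logistic", seed=0)
        prob, pred = predict(model, grids)
        assert ((prob >= 0) & (prob <= 1)).all()
        assert (pred == labels).mean() > 0.9


class TestPredict:
    def test_empty_input(self, rng):
        grids, labels = separable_grids(30, rng)
        model = train_baseline(grids, labels, "linreg")
        prob, pred = predict(model, np.empty((0, 18, 20)))
        assert prob.shape == (0,) and pred.shape == (0,)

    def test_memorised_toy_model(self, rng):
        grids, labels = separable_grids(60, rng, noise=0.0)
        cfg = EGONetConfig(conv_channels=(4, 8, 8), fc_width=16, epochs=60,
                           batch_size=60, dropout_rate=0.0,
                           learning_rate=3e-3, seed=2)
        model = train_egonet(grids, labels, cfg)
        _, pred = predict(model, grids)
        assert np.array_equal(pred, labels)

    def test_shape_mismatch(self, rng):
        grids, labels = separable_grids(30, rng)
        model = train_baseline(grids, labels, "linreg")
        with pytest.raises(ValueError):
            predict(model, rng.random((5, 10, 10)))

    def test_linreg_probabilities_clipped(self, rng):
        grids, labels = separable_grids(100, rng)
        model = train_baseline(grids, labels, "linreg")
        prob, _ = predict(model, grids)
        assert ((prob >= 0) & (prob <= 1)).all()
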