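import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egonet.evaluation import (
    auprg,
    confusion_metrics,
    prg_curve,
    proportion_pct,
    run_cv,
    stratified_folds,
)
from egonet.models import EGONetConfig


def brute_force_auprg(y, scores):
    """Independent PRG oracle: plain loops over every threshold."""
    y = list(y)
    scores = list(scores)
    pi = sum(y) / len(y)
    points = []
    thresholds = sorted(set(scores), reverse=True)
    for t in thresholds:
        pred = [1 if s >= t else 0 for s in scores]
        tp = sum(1 for yi, pi_ in zip(y, pred) if yi == 1 and pi_ == 1)
        npred = sum(pred)
        prec = tp / npred
        rec = tp / sum(y)
        if rec == 0 or rec < pi:
            continue
        pg = (prec - pi) / ((1 - pi) * prec)
        rg = (rec - pi) / ((1 - pi) * rec)
        points.append((rg, pg))
    # sweep order: recall gain is already non-decreasing as t drops
    if not points or points[0][0] > 0:
        first_pg = points[0][1] if points else 0.0
        points.insert(0, (0.0, first_pg))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


class TestStratifiedFolds:
    def test_exact_stratification(self):
        labels = np.array([1] * 10 + [0] * 10)
        folds = stratified_folds(labels, 5, seed=0)
        for f in range(5):
            assert labels[folds == f].sum() == 2

    def test_partition(self, rng):
        labels = (rng.random(97) < 0.3).astype(int)
        folds = stratified_folds(labels, 7, seed=1)
        assert folds.shape == (97,)
        assert set(folds) == set(range(7))
        counts = np.bincount(folds)
        assert counts.sum() == 97

    def test_within_one_of_global_ratio(self, rng):
        labels = (rng.random(200) < 0.17).astype(int)
        folds = stratified_folds(labels, 10, seed=2)
        per_fold = [labels[folds == f].sum() for f in range(10)]
        assert max(per_fold) - min(per_fold) <= 1

    def test_determinism(self, rng):
        labels = (rng.random(50) < 0.4).astype(int)
        assert np.array_equal(stratified_folds(labels, 5, seed=9),
                              stratified_folds(labels, 5, seed=9))

    def test_small_class_error(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="smaller k"):
            stratified_folds(labels, 5, seed=0)


class TestConfusionMetrics:
    def test_perfect(self):
        y = np.array([0, 1, 1, 0, 1])
        m = confusion_metrics(y, y)
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy",
                     "weighted_f1"):
            assert m[name] == 1.0

    def test_all_negative_predictions(self):
        y = np.array([1] * 2 + [0] * 8)  # prevalence 0.2
        pred = np.zeros(10, dtype=int)
        m = confusion_metrics(y, pred)
        assert m["ppv"] == 0.0 and "ppv" in m["degenerate"]
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["accuracy"] == 0.8

    def test_hand_computed_table(self):
        # TP=3 FP=1 FN=2 TN=4
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        m = confusion_metrics(y, p)
        assert m["ppv"] == 0.75
        assert m["sensitivity"] == 0.6
        f1_pos = 2 * 0.75 * 0.6 / 1.35
        f1_neg = 2 * (4 / 6) * (4 / 5) / (4 / 6 + 4 / 5)
        assert m["weighted_f1"] == pytest.approx((5 * f1_pos + 5 * f1_neg) / 10)

    def test_accuracy_identity(self, rng):
        y = (rng.random(60) < 0.3).astype(int)
        p = (rng.random(60) < 0.5).astype(int)
        m = confusion_metrics(y, p)
        assert m["accuracy"] == (m["tp"] + m["tn"]) / 60

    def test_permutation_invariance(self, rng):
        y = (rng.random(40) < 0.4).astype(int)
        p = (rng.random(40) < 0.4).astype(int)
        perm = rng.permutation(40)
        assert confusion_metrics(y, p) == confusion_metrics(y[perm], p[perm])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0])


class TestPRG:
    def test_perfect_ranking(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.1])
        assert auprg(prg_curve(y, s)) == pytest.approx(1.0)

    def test_always_positive_point(self):
        y = np.array([1, 0, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        curve = prg_curve(y, s)
        assert curve.recall_gain[-1] == pytest.approx(1.0)
        assert curve.precision_gain[-1] == pytest.approx(0.0)

    def test_six_point_hand_example(self):
        y = np.array([1, 0, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        assert auprg(prg_curve(y, s)) == pytest.approx(
            brute_force_auprg(y, s), abs=1e-12
        )

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            prg_curve(np.ones(5), np.arange(5))

    def test_recall_gain_monotone(self, rng):
        y = (rng.random(30) < 0.4).astype(int)
        s = rng.random(30)
        curve = prg_curve(y, s)
        assert np.all(np.diff(curve.recall_gain) >= 0)

    def test_fuzz_against_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = 8
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # rounded -> frequent ties
            assert auprg(prg_curve(y, s)) == pytest.approx(
                brute_force_auprg(y, s), abs=1e-12
            )

    @given(st.integers(0, 2 ** 8 - 2).filter(lambda b: 0 < bin(b).count("1") < 8),
           st.integers(0, 10 ** 6))
    @settings(max_examples=200, deadline=None)
    def test_property_matches_oracle(self, label_bits, seed):
        y = np.array([(label_bits >> i) & 1 for i in range(8)])
        s = np.round(np.random.default_rng(seed).random(8), 1)
        assert auprg(prg_curve(y, s)) == pytest.approx(
            brute_force_auprg(y, s), abs=1e-12
        )


def test_proportion_pct():
    assert proportion_pct(107, 190) == 56.3
    assert proportion_pct(190, 1112) == 17.1
    with pytest.raises(ZeroDivisionError):
        proportion_pct(1, 0)


FAST_CFG = EGONetConfig(conv_channels=(4, 8, 8), fc_width=16, epochs=5,
                        batch_size=64, dropout_rate=0.0, seed=0)


class TestRunCV:
    @pytest.fixture(scope="class")
    def noise_data(self):
        rng = np.random.default_rng(0)
        grids = rng.random((150, 18, 20))
        labels = (rng.random(150) < 0.17).astype(int)
        return grids, labels

    def test_constant_scores_give_majority_accuracy(self, noise_data):
        # featureless input -> constant linreg score below 0.5 ->
        # all-majority predictions
        _, labels = noise_data
        grids = np.zeros((labels.size, 18, 20))
        rep = run_cv(grids, labels, kinds=("linreg",), k=5, seed=0)["linreg"]
        majority = 1 - labels.mean()
        assert rep.mean["accuracy"] == pytest.approx(majority, abs=0.02)
        assert rep.mean["sensitivity"] == 0.0

    def test_determinism(self, noise_data):
        grids, labels = noise_data
        r1 = run_cv(grids, labels, kinds=("linreg",), k=5, n_trials=2, seed=4)
        r2 = run_cv(grids, labels, kinds=("linreg",), k=5, n_trials=2, seed=4)
        assert r1["linreg"].mean == r2["linreg"].mean
        assert r1["linreg"].per_fold == r2["linreg"].per_fold

    def test_signal_beats_permuted_labels(self):
        from conftest import make_cohort_df  # noqa: F401  (path check)
        from egonet.relationship_features import cohort_to_grids
        from egonet.synthetic_data import generate_cohort, pairwise_signal_config

        cfg = pairwise_signal_config(n_subjects=400, prevalence=0.5, seed=0)
        cfg.missing_rate = 0.0
        table, _ = generate_cohort(cfg)
        grids, labels = cohort_to_grids(table)
        f1_signal, f1_null = [], []
        for seed in range(2):
            ecfg = EGONetConfig(conv_channels=(8, 16, 32), fc_width=32,
                                epochs=12, batch_size=128, seed=seed)
            rep = run_cv(grids, labels, kinds=("egonet",), k=5, seed=seed,
                         egonet_config=ecfg)["egonet"]
            perm = np.random.default_rng(seed).permutation(labels)
            rep0 = run_cv(grids, perm, kinds=("egonet",), k=5, seed=seed,
                          egonet_config=ecfg)["egonet"]
            f1_signal.append(rep.mean["weighted_f1"])
            f1_null.append(rep0.mean["weighted_f1"])
        assert np.mean(f1_signal) > np.mean(f1_null)

    def test_report_structure(self, noise_data):
        grids, labels = noise_data
        rep = run_cv(grids, labels, kinds=("egonet",), k=5, seed=1,
                     egonet_config=FAST_CFG)["egonet"]
        assert rep.n_folds == 5 and rep.n_trials == 1
        assert len(rep.per_fold) == 5
        assert set(rep.mean) == {"weighted_f1", "ppv", "npv", "sensitivity",
                                 "specificity", "accuracy", "auprg"}
        d = rep.to_dict()
        assert d["seeds"]["master"] == 1
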