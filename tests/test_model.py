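import numpy as np
import pytest

from pdgait.model import (
    ConfusionMatrix,
    NetConfig,
    apply_scaler,
    architecture_search,
    confusion,
    cross_validate,
    fit_scaler,
    load_net,
    metrics,
    predict,
    save_net,
    train_mlp,
)


class TestScaler:
    def test_endpoints(self):
        s = fit_scaler(np.array([[0.0], [5.0], [10.0]]))
        out = apply_scaler(s, np.array([[0.0], [5.0], [10.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_training_data_spans_exactly_unit_interval(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5)) * rng.uniform(1, 100, size=5)
        s = fit_scaler(X)
        out = apply_scaler(s, X)
        assert np.allclose(out.min(axis=0), -1.0)
        assert np.allclose(out.max(axis=0), 1.0)

    def test_unseen_data_not_clipped(self):
        s = fit_scaler(np.array([[0.0], [10.0]]))
        assert apply_scaler(s, np.array([[20.0]]))[0, 0] == pytest.approx(3.0)

    def test_constant_column_zero_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant"):
            s = fit_scaler(X)
        assert np.allclose(apply_scaler(s, X)[:, 0], 0.0)


class TestTraining:
    @pytest.mark.parametrize("algorithm", ["RPROP", "LM", "GDM", "SCG"])
    def test_separable_clusters_learned_by_every_algorithm(
        self, separable_clusters, algorithm
    ):
        X, y = separable_clusters
        cfg = NetConfig(n_hidden=8, algorithm=algorithm, max_epochs=400, seed=0)
        net = train_mlp(X, y, cfg)
        pred, _ = predict(net, X)
        assert np.mean(pred == y) >= 0.99

    def test_same_seed_identical_weights(self, separable_clusters):
        X, y = separable_clusters
        cfg = NetConfig(n_hidden=5, algorithm="RPROP", max_epochs=50, seed=3)
        a = train_mlp(X, y, cfg)
        b = train_mlp(X, y, cfg)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
        assert np.array_equal(a.b1, b.b1) and np.array_equal(a.b2, b.b2)

    def test_xor_problem_rprop(self):
        rng = np.random.default_rng(1)
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        X = np.vstack([base + rng.normal(0, 0.05, size=(4, 2)) for _ in range(50)])
        y = np.array([0, 1, 1, 0] * 50)
        cfg = NetConfig(n_hidden=25, algorithm="RPROP", max_epochs=600,
                        patience=50, seed=0)
        net = train_mlp(X, y, cfg)
        pred, _ = predict(net, X)
        assert np.mean(pred == y) >= 0.95

    def test_early_stop_contract(self, separable_clusters):
        X, y = separable_clusters
        cfg = NetConfig(n_hidden=4, algorithm="RPROP", max_epochs=1,
                        patience=0, seed=0)
        net = train_mlp(X, y, cfg)
        assert net.stopped_epoch <= 1
        assert len(net.train_curve) <= 1

    def test_lm_reaches_comparable_loss_to_rprop(self, separable_clusters):
        X, y = separable_clusters
        lm = train_mlp(X, y, NetConfig(n_hidden=8, algorithm="LM",
                                       max_epochs=200, seed=0))
        rp = train_mlp(X, y, NetConfig(n_hidden=8, algorithm="RPROP",
                                       max_epochs=200, seed=0))
        assert min(v for _, v in lm.train_curve) <= \
            1.5 * min(v for _, v in rp.train_curve) + 1e-6

    def test_singleton_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError, match="at least 2"):
            train_mlp(X, y, NetConfig(n_hidden=2))


class TestPredict:
    def test_probabilities_sum_to_one(self, separable_clusters):
        X, y = separable_clusters
        net = train_mlp(X, y, NetConfig(n_hidden=4, max_epochs=30, seed=0))
        rng = np.random.default_rng(0)
        _, P = predict(net, rng.normal(size=(200, 2)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P >= 0)

    def test_label_is_argmax(self, separable_clusters):
        X, y = separable_clusters
        net = train_mlp(X, y, NetConfig(n_hidden=4, max_epochs=30, seed=0))
        rng = np.random.default_rng(1)
        Xr = rng.normal(size=(1000, 2)) * 5
        labels, P = predict(net, Xr)
        assert np.array_equal(labels, net.classes[np.argmax(P, axis=1)])

    def test_column_mismatch_rejected(self, separable_clusters):
        X, y = separable_clusters
        net = train_mlp(X, y, NetConfig(n_hidden=4, max_epochs=10, seed=0))
        with pytest.raises(ValueError, match="columns"):
            predict(net, np.zeros((3, 5)))


class TestConfusionAndMetrics:
    def test_perfect_predictions_diagonal(self):
        y = ["a", "b", "c", "a", "b"]
        cm = confusion(y, y, ["a", "b", "c"])
        assert np.trace(cm.counts) == 5
        assert cm.counts.sum() == 5

    def test_hand_counted_binary(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 0], [0, 1])
        rep = metrics(cm, positive_class=1)
        # TP=1 FN=1 TN=2 FP=0
        assert cm.counts[1, 1] == 1 and cm.counts[0, 1] == 1
        assert rep.sn == pytest.approx(0.5)
        assert rep.sp == pytest.approx(1.0)
        assert rep.fpr == pytest.approx(0.0)

    def test_column_sums_are_target_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, size=100)
        y_pred = rng.integers(0, 3, size=100)
        cm = confusion(y_true, y_pred, [0, 1, 2])
        for c in range(3):
            assert cm.counts[:, c].sum() == np.sum(y_true == c)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([0, 3], [0, 0], [0, 1])

    def test_symmetric_half_panel(self):
        cm = ConfusionMatrix(np.array([[25, 25], [25, 25]]), [0, 1])
        rep = metrics(cm, positive_class=1)
        assert rep.acc == pytest.approx(0.5)
        assert rep.sn == pytest.approx(0.5)
        assert rep.sp == pytest.approx(0.5)

    def test_identities_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            counts = rng.integers(0, 50, size=(2, 2))
            if counts.sum() == 0:
                continue
            rep = metrics(ConfusionMatrix(counts, [0, 1]), positive_class=0)
            assert rep.err == pytest.approx(1.0 - rep.acc, abs=1e-12)
            if rep.fpr is not None and rep.sp is not None:
                assert rep.fpr == pytest.approx(1.0 - rep.sp, abs=1e-12)

    def test_undefined_ratio_is_absent_not_zero(self):
        cm = ConfusionMatrix(np.array([[0, 0], [0, 5]]), [0, 1])
        rep = metrics(cm, positive_class=0)
        assert rep.sn is None and rep.prec is None


class TestCrossValidation:
    def test_loo_fold_structure(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(8, 1, (6, 2))])
        y = np.array([0] * 6 + [1] * 6)
        cfg = NetConfig(n_hidden=3, max_epochs=40, seed=0)
        res = cross_validate(X, y, cfg, scheme="LOO")
        assert len(res.fold_accuracy) == 12
        assert res.confusion.n == 12

    def test_kfold_partitions_all_samples(self, separable_clusters):
        X, y = separable_clusters
        cfg = NetConfig(n_hidden=4, max_epochs=60, seed=0)
        res = cross_validate(X, y, cfg, scheme="KFOLD", k=5)
        assert res.confusion.n == len(y)
        assert res.pooled_accuracy >= 0.95

    def test_holdout(self, separable_clusters):
        X, y = separable_clusters
        cfg = NetConfig(n_hidden=4, max_epochs=60, seed=0)
        res = cross_validate(X, y, cfg, scheme="HOLDOUT")
        assert res.confusion.n == 30  # 15% of 200
        assert res.pooled_accuracy >= 0.9

    def test_fold_internal_smote_changes_nothing_for_balanced_easy_data(
        self, separable_clusters
    ):
        X, y = separable_clusters
        cfg = NetConfig(n_hidden=4, max_epochs=60, seed=0)
        res = cross_validate(X, y, cfg, scheme="KFOLD", k=3,
                             smote_amounts={"A": 10}, smote_k_neighbors=3)
        assert res.confusion.n == len(y)


class TestArchitectureSearch:
    def test_single_cell_grid(self, separable_clusters):
        X, y = separable_clusters
        best, table = architecture_search(X, y, [4], ["RPROP"], seed=0,
                                          base_config=NetConfig(max_epochs=40))
        assert best.n_hidden == 4 and best.algorithm == "RPROP"
        assert len(table) == 1

    def test_table_covers_grid_and_best_is_minimum(self, separable_clusters):
        X, y = separable_clusters
        base = NetConfig(max_epochs=30)
        best, table = architecture_search(X, y, [2, 4], ["RPROP", "GDM"],
                                          seed=0, base_config=base)
        assert len(table) == 4
        best_row = min(table, key=lambda r: (r["val_mse"], r["n_hidden"]))
        assert best.algorithm == best_row["algorithm"]
        assert best.n_hidden == best_row["n_hidden"]


def test_save_load_roundtrip(tmp_path, separable_clusters):
    X, y = separable_clusters
    net = train_mlp(X, y, NetConfig(n_hidden=4, max_epochs=30, seed=0))
    save_net(net, tmp_path / "net.json")
    loaded = load_net(tmp_path / "net.json")
    p0, P0 = predict(net, X)
    p1, P1 = predict(loaded, X)
    assert np.array_equal(p0, p1)
    assert np.allclose(P0, P1)
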