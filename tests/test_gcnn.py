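import numpy as np
import pytest

from conftest import make_cluster_dataset
from methyltoo.gcnn import (
    GraphDataset,
    TrainConfig,
    _focal_loss_and_grad,
    backward,
    build_knn_graph,
    focal_loss,
    forward,
    gtn_layer_forward,
    init_parameters,
    predict_nodes,
    stratified_folds,
    train_transductive,
)


class TestKnnGraph:
    def test_collinear_points_union_symmetrized(self):
        x = np.array([[0.0], [1.0], [10.0]])
        adj = build_knn_graph(x, k=1)
        # 0 and 1 pick each other; 2 picks 1; union adds the 1-2 edge
        expected = np.array(
            [[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=bool
        )
        np.testing.assert_array_equal(adj, expected)

    def test_k_equals_n_minus_one_complete(self, rng):
        x = rng.normal(size=(6, 3))
        adj = build_knn_graph(x, k=5)
        assert adj.all()

    def test_duplicate_points_tie_break_by_index(self):
        x = np.zeros((4, 2))  # all pairwise distances tie at 0
        adj = build_knn_graph(x, k=1)
        # every node picks node 0 (lowest index); node 0 picks node 1
        assert adj[2, 0] and adj[3, 0] and adj[0, 1]
        assert not adj[2, 3]

    def test_too_few_nodes_rejected(self, rng):
        with pytest.raises(ValueError, match="k=5"):
            build_knn_graph(rng.normal(size=(4, 2)), k=5)


class TestLayer:
    def _params(self, h, rng):
        return (rng.normal(size=(h, h)), rng.normal(size=(h, h)), rng.normal(size=(h, h)))

    def test_isolated_node_attends_to_itself(self, rng):
        wq, wk, wv = self._params(3, rng)
        z = rng.normal(size=(1, 3))
        adj = np.ones((1, 1), dtype=bool)
        out, cache = gtn_layer_forward(z, adj, wq, wk, wv, return_cache=True)
        assert cache["attn"][0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(out, z @ wv + z)

    def test_zero_query_key_gives_uniform_attention(self, rng):
        h = 4
        z = rng.normal(size=(6, h))
        adj = build_knn_graph(z, k=2)
        zero = np.zeros((h, h))
        _, cache = gtn_layer_forward(z, adj, zero, zero, rng.normal(size=(h, h)),
                                     return_cache=True)
        for u in range(6):
            nbhd = adj[u]
            np.testing.assert_allclose(
                cache["attn"][u, nbhd], 1.0 / nbhd.sum(), atol=1e-12
            )
            np.testing.assert_allclose(cache["attn"][u, ~nbhd], 0.0)

    def test_attention_rows_sum_to_one(self, rng):
        z = rng.normal(size=(20, 5))
        adj = build_knn_graph(z, k=4)
        wq, wk, wv = self._params(5, rng)
        for dense in (False, True):
            _, cache = gtn_layer_forward(z, adj, wq, wk, wv, dense_softmax=dense,
                                         return_cache=True)
            np.testing.assert_allclose(cache["attn"].sum(axis=1), 1.0, atol=1e-9)

    def test_zero_value_transform_is_identity(self, rng):
        z = rng.normal(size=(10, 4))
        adj = build_knn_graph(z, k=3)
        wq, wk, _ = self._params(4, rng)
        out = gtn_layer_forward(z, adj, wq, wk, np.zeros((4, 4)))
        np.testing.assert_array_equal(out, z)

    def test_non_finite_latents_rejected(self, rng):
        z = np.full((3, 2), np.nan)
        adj = np.eye(3, dtype=bool)
        with pytest.raises(ValueError, match="finite"):
            gtn_layer_forward(z, adj, *self._params(2, rng))


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self, rng):
        logits = rng.normal(size=(30, 5))
        labels = rng.integers(0, 5, size=30)
        shifted = logits - logits.max(axis=1, keepdims=True)
        log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        ce = -log_probs[np.arange(30), labels].mean()
        assert abs(focal_loss(logits, labels, gamma=0.0) - ce) < 1e-10

    def test_confident_correct_prediction_contributes_zero(self):
        logits = np.array([[50.0, 0.0, 0.0]])
        assert focal_loss(logits, np.array([0]), gamma=2.0) == pytest.approx(0.0, abs=1e-12)

    def test_binary_half_probability_closed_form(self):
        # p_y = 0.5, gamma = 2, w = 1: loss = 0.25 * ln 2
        logits = np.array([[0.0, 0.0]])
        loss = focal_loss(logits, np.array([0]), gamma=2.0)
        assert loss == pytest.approx(0.25 * np.log(2.0), rel=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            focal_loss(np.zeros((2, 3)), np.array([0, -1]), gamma=2.0)

    @pytest.mark.parametrize("gamma", [0.0, 2.0])
    def test_gradient_matches_finite_differences(self, rng, gamma):
        logits = rng.normal(size=(6, 4))
        labels = rng.integers(0, 4, size=6)
        weights = rng.uniform(0.5, 2.0, size=4)
        _, grad = _focal_loss_and_grad(logits, labels, gamma, weights)
        eps = 1e-6
        for i in (0, 3):
            for k in range(4):
                bump = logits.copy()
                bump[i, k] += eps
                up = focal_loss(bump, labels, gamma, weights)
                bump[i, k] -= 2 * eps
                down = focal_loss(bump, labels, gamma, weights)
                assert grad[i, k] == pytest.approx((up - down) / (2 * eps), abs=1e-6)


class TestNetworkGradients:
    def test_backward_matches_finite_differences(self, rng):
        n, d, h, c = 7, 3, 4, 3
        x = rng.normal(size=(n, d))
        adj = build_knn_graph(x, k=2)
        labels = rng.integers(0, c, size=n)
        params = init_parameters(d, h, c, 2, rng)

        def loss_of(p):
            return focal_loss(forward(p, x, adj, 2), labels, gamma=2.0)

        logits, cache = forward(params, x, adj, 2, return_cache=True)
        _, d_logits = _focal_loss_and_grad(logits, labels, 2.0, None)
        grads = backward(params, cache, x, d_logits, 2)
        eps = 1e-6
        for name, value in params.items():
            flat = value.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_of(params)
                flat[idx] = orig - eps
                down = loss_of(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].reshape(-1)[idx] == pytest.approx(
                    numeric, abs=5e-6
                ), name


class TestStratifiedFolds:
    def test_balanced_classes_one_per_fold(self):
        labels = np.repeat(np.arange(5), 10)
        folds = stratified_folds(labels, 10, seed=3)
        for f in range(10):
            values, counts = np.unique(labels[folds == f], return_counts=True)
            assert list(values) == list(range(5))
            assert (counts == 1).all()

    def test_uneven_class_spills_into_one_fold(self):
        labels = np.concatenate([np.repeat(np.arange(5), 10), [0]])
        folds = stratified_folds(labels, 10, seed=3)
        class0_per_fold = [
            ((folds == f) & (labels == 0)).sum() for f in range(10)
        ]
        assert sorted(class0_per_fold) == [1] * 9 + [2]

    def test_same_seed_identical(self):
        labels = np.repeat(np.arange(3), 12)
        np.testing.assert_array_equal(
            stratified_folds(labels, 4, seed=9), stratified_folds(labels, 4, seed=9)
        )

    def test_small_class_rejected_by_name(self):
        labels = np.array(["A"] * 12 + ["B"] * 3)
        with pytest.raises(ValueError, match="'B'"):
            stratified_folds(labels, 4, seed=0)


def quick_dataset(seed=0, n_per_class=12, n_classes=3, d=4):
    x, y, test_mask = make_cluster_dataset(
        seed=seed, n_per_class=n_per_class, n_classes=n_classes, d=d
    )
    adj = build_knn_graph(x, 5)
    # test nodes keep their labels for evaluation; training may only read
    # labels of train-mask nodes
    return GraphDataset(x, y.copy(), adj, ~test_mask, test_mask), y


QUICK_CONFIG = dict(n_folds=3, epochs=40, patience=10, seed=5)


class TestTraining:
    def test_same_seed_reproduces_fold_metrics(self):
        dataset, _ = quick_dataset()
        config = TrainConfig(**QUICK_CONFIG)
        _, metrics_a = train_transductive(dataset, config)
        _, metrics_b = train_transductive(dataset, config)
        assert metrics_a == metrics_b

    def test_test_labels_never_influence_training(self):
        dataset, y = quick_dataset()
        config = TrainConfig(**QUICK_CONFIG)
        params_a, metrics_a = train_transductive(dataset, config)
        # scramble the hidden test labels; training must be bit-identical
        scrambled = dataset.labels.copy()
        rng = np.random.default_rng(1)
        scrambled[dataset.test_mask] = rng.permutation(scrambled[dataset.test_mask])
        dataset_b = GraphDataset(
            dataset.features, scrambled, dataset.adjacency,
            dataset.train_mask, dataset.test_mask,
        )
        params_b, metrics_b = train_transductive(dataset_b, config)
        assert metrics_a == metrics_b
        for key in params_a:
            np.testing.assert_array_equal(params_a[key], params_b[key])

    def test_predictions_deterministic_and_normalized(self):
        dataset, y = quick_dataset()
        config = TrainConfig(**QUICK_CONFIG)
        params, _ = train_transductive(dataset, config)
        pred1, probs1 = predict_nodes(params, dataset, dataset.test_mask)
        pred2, probs2 = predict_nodes(params, dataset, dataset.test_mask)
        np.testing.assert_array_equal(pred1, pred2)
        np.testing.assert_allclose(probs1.sum(axis=1), 1.0, atol=1e-6)

    def test_mask_referencing_absent_nodes_rejected(self):
        dataset, _ = quick_dataset()
        params = init_parameters(4, 64, 3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="absent"):
            predict_nodes(params, dataset, np.array([0, 999]))

    def test_overlapping_masks_rejected(self):
        dataset, y = quick_dataset()
        with pytest.raises(ValueError, match="overlap"):
            GraphDataset(
                dataset.features, dataset.labels, dataset.adjacency,
                np.ones_like(dataset.train_mask), np.ones_like(dataset.test_mask),
            )
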