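"""Kernel fusion, simplex-grid weight tuning, and the SVM dual."""

import numpy as np
import pytest
from scipy import optimize

from ppikex.fusion import (
    FusionWeights,
    TrainedModel,
    decision_values,
    fuse,
    predict,
    simplex_grid,
    train,
    tune_weights,
)
from ppikex.gram import GramSet


def _labels(*vals):
    return np.array(vals, dtype=float)


def _gram_set(n=8, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    def psd():
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        d = np.sqrt(np.diag(K))
        return K / np.outer(d, d)
    return GramSet([f"p{i}" for i in range(n)], {"a": psd(), "b": psd(), "graph": psd()}, labels)


# ---------------------------------------------------------------------------
# fuse


def test_fuse_vertex_weight_selects_single_kernel():
    gs = _gram_set()
    w = FusionWeights({"a": 1.0, "b": 0.0})
    assert np.array_equal(fuse(gs.grams, w), gs.grams["a"])


def test_fuse_equal_matrices_identity():
    gs = _gram_set()
    grams = {"a": gs.grams["a"], "b": gs.grams["a"].copy()}
    fused = fuse(grams, FusionWeights({"a": 0.5, "b": 0.5}))
    assert np.allclose(fused, gs.grams["a"])


def test_fuse_is_linear_in_weights():
    gs = _gram_set()
    w1 = FusionWeights({"a": 1.0, "b": 0.0, "graph": 0.0})
    w2 = FusionWeights({"a": 0.0, "b": 0.5, "graph": 0.5})
    mix = FusionWeights({"a": 0.3, "b": 0.35, "graph": 0.35})
    lhs = fuse(gs.grams, mix)
    rhs = 0.3 * fuse(gs.grams, w1) + 0.7 * fuse(gs.grams, w2)
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_fused_psd_under_simplex_weights():
    gs = _gram_set(n=30, seed=3)
    rng = np.random.default_rng(0)
    for _ in range(5):
        raw = rng.dirichlet(np.ones(3))
        w = FusionWeights(dict(zip(sorted(gs.grams), raw / raw.sum())))
        fused = fuse(gs.grams, w)
        assert np.linalg.eigvalsh(fused).min() >= -1e-8


def test_fuse_rejects_unknown_kernel_and_shape_mismatch():
    gs = _gram_set()
    with pytest.raises(ValueError, match="unknown"):
        fuse(gs.grams, FusionWeights({"nope": 1.0}))
    bad = {"a": gs.grams["a"], "b": np.eye(3)}
    with pytest.raises(ValueError, match="shape"):
        fuse(bad, FusionWeights({"a": 0.5, "b": 0.5}))


def test_weights_validation():
    with pytest.raises(ValueError):
        FusionWeights({"a": -0.5, "b": 1.5})
    with pytest.raises(ValueError):
        FusionWeights({"a": 0.4, "b": 0.4})  # does not sum to 1
    with pytest.raises(ValueError):
        FusionWeights({"a": 0.0, "b": 0.0})


# ---------------------------------------------------------------------------
# simplex grid


def test_simplex_grid_step_one_visits_only_vertices():
    ws = simplex_grid(["a", "b"], 1.0)
    etas = sorted(tuple(sorted(w.eta.items())) for w in ws)
    assert etas == [
        (("a", 0.0), ("b", 1.0)),
        (("a", 1.0), ("b", 0.0)),
    ]


def test_simplex_grid_counts_and_sums():
    ws = simplex_grid(["a", "b", "c"], 0.25)
    assert len(ws) == 15  # compositions of 4 into 3 parts
    for w in ws:
        assert sum(w.eta.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# weight tuning


def _label_gram(y):
    return np.outer(y, y).astype(float)


def test_tuning_prefers_informative_kernel_over_noise():
    rng = np.random.default_rng(5)
    y = np.array([1.0] * 10 + [-1.0] * 10)
    noise = rng.normal(size=(20, 20))
    noise = noise @ noise.T / 20
    d = np.sqrt(np.diag(noise))
    gs = GramSet(
        [f"p{i}" for i in range(20)],
        {"informative": _label_gram(y), "noise": noise / np.outer(d, d)},
        y,
    )
    w = tune_weights(gs, grid_step=0.5, folds=2, seed=0)
    assert w.eta["informative"] >= w.eta["noise"]


def test_tuning_is_deterministic():
    y = np.array([1.0] * 8 + [-1.0] * 8)
    gs = _gram_set(n=16, seed=2, labels=y)
    w1 = tune_weights(gs, grid_step=0.5, folds=2, seed=9)
    w2 = tune_weights(gs, grid_step=0.5, folds=2, seed=9)
    assert w1.eta == w2.eta


def test_tuning_rejects_single_class():
    gs = _gram_set(labels=_labels(*([1.0] * 8)))
    with pytest.raises(ValueError, match="both classes"):
        tune_weights(gs)


# ---------------------------------------------------------------------------
# training and prediction


def test_identity_gram_closed_form():
    y = _labels(1, 1, -1, -1)
    gs = GramSet(["p0", "p1", "p2", "p3"], {"k": np.eye(4)}, y)
    model = train(gs, FusionWeights({"k": 1.0}), c=100.0, class_weight=None)
    assert len(model.support_ids) == 4  # identity kernel: everyone on the margin
    g = decision_values(model, {"k": np.eye(4)}, gs.pair_ids)
    # g(x_t) = alpha_t r_t + b must match the training labels in sign
    assert np.array_equal(np.sign(g), y)


def test_dual_feasibility_and_objective_vs_independent_solver():
    rng = np.random.default_rng(1)
    n, c = 10, 1.0
    y = np.array([1.0] * 5 + [-1.0] * 5)
    A = rng.normal(size=(n, n))
    K = A @ A.T / n + np.eye(n)
    gs = GramSet([f"p{i}" for i in range(n)], {"k": K}, y)
    model = train(gs, FusionWeights({"k": 1.0}), c=c, class_weight=None)

    alpha_full = np.zeros(n)
    for pid, a in zip(model.support_ids, model.alpha):
        alpha_full[gs.pair_ids.index(pid)] = a
    assert np.all(alpha_full >= -1e-9) and np.all(alpha_full <= c + 1e-9)
    assert abs(np.dot(alpha_full, y)) < 1e-6

    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    res = optimize.minimize(
        neg_dual,
        x0=np.full(n, 0.5 * c),
        jac=lambda a: -(np.ones(n) - Q @ a),
        bounds=[(0.0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    assert res.success
    assert -neg_dual(alpha_full) == pytest.approx(-res.fun, abs=1e-6)


def test_separable_gram_reaches_perfect_training_fit():
    y = np.array([1.0] * 6 + [-1.0] * 6)
    gs = GramSet([f"p{i}" for i in range(12)], {"k": _label_gram(y)}, y)
    model = train(gs, FusionWeights({"k": 1.0}), c=10.0, class_weight=None)
    pred, _ = predict(model, {"k": _label_gram(y)}, gs.pair_ids)
    assert np.array_equal(pred, y)


def test_duplicated_dataset_preserves_decision_values():
    rng = np.random.default_rng(4)
    n = 8
    y = np.array([1.0] * 4 + [-1.0] * 4)
    A = rng.normal(size=(n, n))
    K = A @ A.T / n + np.eye(n)
    gs1 = GramSet([f"p{i}" for i in range(n)], {"k": K}, y)
    K2 = np.tile(K, (2, 2))
    gs2 = GramSet([f"p{i}" for i in range(2 * n)], {"k": K2}, np.tile(y, 2))
    m1 = train(gs1, FusionWeights({"k": 1.0}), class_weight=None)
    m2 = train(gs2, FusionWeights({"k": 1.0}), class_weight=None)
    g1 = decision_values(m1, {"k": K}, gs1.pair_ids)
    g2 = decision_values(m2, {"k": np.tile(K, (1, 2))}, gs2.pair_ids)
    assert np.array_equal(np.sign(g1), np.sign(g2))


def test_predictions_on_training_pairs_match_train_time(small_gram_set):
    gs, _ = small_gram_set
    w = FusionWeights.uniform(gs.kernel_names)
    model = train(gs, w)
    pred1, g1 = predict(model, gs.grams, gs.pair_ids)
    pred2, g2 = predict(model, {k: K.copy() for k, K in gs.grams.items()}, gs.pair_ids)
    assert np.array_equal(pred1, pred2)
    assert np.allclose(g1, g2)


def test_all_zero_cross_row_predicts_bias_sign():
    y = _labels(1, 1, -1, -1)
    gs = GramSet(["p0", "p1", "p2", "p3"], {"k": np.eye(4)}, y)
    model = train(gs, FusionWeights({"k": 1.0}), c=1.0, class_weight=None)
    _, g = predict(model, {"k": np.zeros((1, 4))}, gs.pair_ids)
    assert g[0] == pytest.approx(model.bias)


def test_predict_missing_support_column_raises():
    y = _labels(1, 1, -1, -1)
    gs = GramSet(["p0", "p1", "p2", "p3"], {"k": np.eye(4)}, y)
    model = train(gs, FusionWeights({"k": 1.0}), class_weight=None)
    with pytest.raises(ValueError, match="support"):
        predict(model, {"k": np.zeros((1, 2))}, ["p0", "p1"])


def test_model_json_round_trip(tmp_path, small_gram_set):
    gs, _ = small_gram_set
    model = train(gs, FusionWeights.uniform(gs.kernel_names))
    path = tmp_path / "model.json"
    model.to_json(path)
    back = TrainedModel.from_json(path)
    assert back.support_ids == model.support_ids
    assert np.allclose(back.alpha, model.alpha)
    assert back.weights.eta == model.weights.eta
    assert back.bias == pytest.approx(model.bias)
    p1, g1 = predict(model, gs.grams, gs.pair_ids)
    p2, g2 = predict(back, gs.grams, gs.pair_ids)
    assert np.array_equal(p1, p2) and np.allclose(g1, g2)


def test_train_requires_both_classes():
    gs = GramSet(["p0", "p1"], {"k": np.eye(2)}, _labels(1, 1))
    with pytest.raises(ValueError, match="both classes"):
        train(gs, FusionWeights({"k": 1.0}))
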