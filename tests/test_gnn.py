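"""GCN/GAT layers: propagation oracles, attention, gradients, training."""

import numpy as np
import pytest

from wpnet import gnn
from wpnet.errors import ConfigurationError, DataError
from tests.conftest import random_symmetric_adjacency


# ---------------------------------------------------------------------------
# adjacency normalisation


def test_normalize_adjacency_hand_examples():
    assert np.allclose(gnn.normalize_adjacency(np.array([[0.0]])), [[1.0]])
    assert np.allclose(
        gnn.normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]])),
        [[0.5, 0.5], [0.5, 0.5]],
    )
    # edge weight 3: A~=[[1,3],[3,1]], D~=diag(4,4)
    assert np.allclose(
        gnn.normalize_adjacency(np.array([[0.0, 3.0], [3.0, 0.0]])),
        [[0.25, 0.75], [0.75, 0.25]],
    )


@pytest.mark.parametrize(
    "bad",
    [
        np.array([[0.0, 1.0], [0.0, 0.0]]),  # asymmetric
        np.array([[0.0, -1.0], [-1.0, 0.0]]),  # negative
        np.array([[1.0, 1.0], [1.0, 0.0]]),  # nonzero diagonal
    ],
)
def test_normalize_adjacency_rejects_invalid(bad):
    with pytest.raises(DataError):
        gnn.normalize_adjacency(bad)


# ---------------------------------------------------------------------------
# forward-pass oracles


def naive_gcn_forward(adj, x, weights):
    """Independent loop-based evaluation of the propagation rule."""
    n = adj.shape[0]
    a_tilde = adj + np.eye(n)
    d = a_tilde.sum(axis=1)
    s = np.zeros_like(a_tilde)
    for i in range(n):
        for j in range(n):
            s[i, j] = a_tilde[i, j] / np.sqrt(d[i] * d[j])
    h = x
    for li, w in enumerate(["W0", "W1", "W2"]):
        nxt = s @ (h @ weights[w])
        h = np.maximum(nxt, 0.0) if li < 2 else nxt
    return 1.0 / (1.0 + np.exp(-h[:, 0]))


def test_gcn_zero_weights_predict_half():
    adj = random_symmetric_adjacency(np.random.default_rng(0), 6)
    x = np.random.default_rng(1).normal(size=(6, 3))
    weights = {k: np.zeros_like(v) for k, v in gnn.init_gcn_weights(3, gnn.GCNConfig()).items()}
    preds, _ = gnn.gcn_forward(adj, x, weights)
    assert np.allclose(preds, 0.5)


def test_gcn_one_node_identity_chain():
    """1-node graph with 1-dim identity weights passes x through to sigmoid."""
    config = gnn.GCNConfig(hidden_size=1)
    weights = {"W0": np.eye(1), "W1": np.eye(1), "W2": np.eye(1)}
    x = np.array([[0.7]])  # positive, so ReLU is transparent
    preds, emb = gnn.gcn_forward(np.zeros((1, 1)), x, weights, config)
    assert preds[0] == pytest.approx(1.0 / (1.0 + np.exp(-0.7)))
    assert emb.shape == (1, 1)


def test_gcn_forward_matches_naive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(2, 15))
        adj = random_symmetric_adjacency(rng, n, weighted=True)
        x = rng.normal(size=(n, 3))
        config = gnn.GCNConfig(seed=int(rng.integers(0, 1000)))
        weights = gnn.init_gcn_weights(3, config)
        preds, _ = gnn.gcn_forward(adj, x, weights, config)
        assert np.allclose(preds, naive_gcn_forward(adj, x, weights), atol=1e-6)


def naive_gat_layer(x, w_heads, a_src, a_dst, adj, slope):
    """Per-node loop oracle for one multi-head attention layer."""
    n = x.shape[0]
    k = w_heads.shape[0]
    outs = []
    for head in range(k):
        z = x @ w_heads[head]
        out = np.zeros_like(z)
        for u in range(n):
            nbrs = [v for v in range(n) if adj[u, v] > 0 or v == u]
            logits = []
            for v in nbrs:
                e = a_src[head] @ z[u] + a_dst[head] @ z[v]
                logits.append(e if e > 0 else slope * e)
            logits = np.array(logits)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            for a_uv, v in zip(alpha, nbrs):
                out[u] += a_uv * z[v]
        outs.append(out)
    return outs


def test_gat_forward_matches_naive_loop_oracle():
    rng = np.random.default_rng(3)
    n = 12
    adj = random_symmetric_adjacency(rng, n)
    x = rng.normal(size=(n, 3))
    config = gnn.GATConfig(n_heads=2, head_features=4, seed=5)
    weights = gnn.init_gat_weights(3, config)
    preds, emb = gnn.gat_forward(adj, x, weights, config)

    outs1 = naive_gat_layer(
        x, weights["W1"], weights["a_src1"], weights["a_dst1"], adj,
        config.leaky_relu_slope,
    )
    h1 = np.hstack([np.where(o > 0, o, np.expm1(np.minimum(o, 0))) for o in outs1])
    assert np.allclose(emb, h1, atol=1e-6)
    out2 = naive_gat_layer(
        h1, weights["W2"], weights["a_src2"], weights["a_dst2"], adj,
        config.leaky_relu_slope,
    )[0]
    assert np.allclose(preds, 1.0 / (1.0 + np.exp(-out2[:, 0])), atol=1e-6)


# ---------------------------------------------------------------------------
# attention coefficients


def test_attention_uniform_for_identical_features():
    n = 5
    adj = np.ones((n, n)) - np.eye(n)
    x = np.tile([[1.0, 2.0]], (n, 1))
    config = gnn.GATConfig(n_heads=3, head_features=4, seed=0)
    weights = gnn.init_gat_weights(2, config)
    alpha = gnn.attention_coefficients(adj, x, weights, config)
    assert np.allclose(alpha, 1.0 / n)


def test_attention_rows_sum_to_one_with_nonnegative_entries():
    rng = np.random.default_rng(12)
    adj = random_symmetric_adjacency(rng, 9, weighted=True)
    x = rng.normal(size=(9, 4))
    for weighted_attention in (False, True):
        config = gnn.GATConfig(n_heads=4, head_features=3, seed=1,
                               weighted_attention=weighted_attention)
        weights = gnn.init_gat_weights(4, config)
        for layer in (1, 2):
            alpha = gnn.attention_coefficients(adj, x, weights, config, layer=layer)
            assert np.allclose(alpha.sum(axis=2), 1.0, atol=1e-6)
            assert np.all(alpha >= 0)


def test_attention_three_node_path_formula_oracle():
    """Direct evaluation of the attention softmax on a 3-node path."""
    adj = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    rng = np.random.default_rng(9)
    x = rng.normal(size=(3, 2))
    config = gnn.GATConfig(n_heads=1, head_features=2, seed=4)
    weights = gnn.init_gat_weights(2, config)
    alpha = gnn.attention_coefficients(adj, x, weights, config)[0]
    z = x @ weights["W1"][0]
    slope = config.leaky_relu_slope

    def leaky(v):
        return v if v > 0 else slope * v

    for u in range(3):
        nbrs = [v for v in range(3) if adj[u, v] > 0 or v == u]
        logits = np.array(
            [leaky(weights["a_src1"][0] @ z[u] + weights["a_dst1"][0] @ z[v]) for v in nbrs]
        )
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose([alpha[u, v] for v in nbrs], expected, atol=1e-6)
        for v in range(3):
            if v not in nbrs:
                assert alpha[u, v] == 0.0


# ---------------------------------------------------------------------------
# gradients (finite differences)


def _num_grad(loss_fn, weights, key, eps=1e-6):
    g = np.zeros_like(weights[key])
    it = np.nditer(weights[key], flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = weights[key][i]
        weights[key][i] = orig + eps
        lp = loss_fn()
        weights[key][i] = orig - eps
        lm = loss_fn()
        weights[key][i] = orig
        g[i] = (lp - lm) / (2 * eps)
    return g


def test_gcn_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    n = 6
    adj = random_symmetric_adjacency(rng, n, weighted=True)
    x = rng.normal(size=(n, 3))
    y = rng.integers(0, 2, size=n).astype(float)
    mask = np.ones(n, dtype=bool)
    config = gnn.GCNConfig(hidden_size=4, dropout=0.0, seed=1)
    weights = gnn.init_gcn_weights(3, config)
    s = gnn.normalize_adjacency(adj)
    logits, _, cache = gnn._gcn_forward(s, x, weights, config)
    grads = gnn._gcn_backward(
        s, x, weights, config, cache, (gnn._sigmoid(logits) - y) / n
    )

    def loss():
        lg, _, _ = gnn._gcn_forward(s, x, weights, config)
        return gnn._bce_from_logits(lg, y, mask)

    for key in weights:
        assert np.allclose(grads[key], _num_grad(loss, weights, key), atol=1e-6)


@pytest.mark.parametrize("weighted_attention", [False, True])
def test_gat_gradients_match_finite_differences(weighted_attention):
    rng = np.random.default_rng(5)
    n = 5
    adj = random_symmetric_adjacency(rng, n, weighted=True)
    x = rng.normal(size=(n, 2))
    y = rng.integers(0, 2, size=n).astype(float)
    mask = np.ones(n, dtype=bool)
    config = gnn.GATConfig(
        n_heads=2, head_features=3, dropout=0.0, seed=2,
        weighted_attention=weighted_attention,
    )
    weights = gnn.init_gat_weights(2, config)
    adj_mask, wmod = gnn._gat_masks(adj)
    logits, _, cache = gnn._gat_forward(adj_mask, wmod, x, weights, config)
    grads = gnn._gat_backward(x, weights, config, cache, (gnn._sigmoid(logits) - y) / n)

    def loss():
        lg, _, _ = gnn._gat_forward(adj_mask, wmod, x, weights, config)
        return gnn._bce_from_logits(lg, y, mask)

    for key in weights:
        assert np.allclose(grads[key], _num_grad(loss, weights, key), atol=1e-6)


# ---------------------------------------------------------------------------
# equivariance and weight handling


def test_forward_passes_are_permutation_equivariant():
    rng = np.random.default_rng(21)
    n = 10
    adj = random_symmetric_adjacency(rng, n, weighted=True)
    x = rng.normal(size=(n, 3))
    perm = rng.permutation(n)
    p_adj = adj[np.ix_(perm, perm)]
    p_x = x[perm]

    gcn_w = gnn.init_gcn_weights(3, gnn.GCNConfig(seed=0))
    a, _ = gnn.gcn_forward(adj, x, gcn_w)
    b, _ = gnn.gcn_forward(p_adj, p_x, gcn_w)
    assert np.allclose(a[perm], b, atol=1e-5)

    config = gnn.GATConfig(n_heads=2, head_features=4, seed=0)
    gat_w = gnn.init_gat_weights(3, config)
    a, _ = gnn.gat_forward(adj, x, gat_w, config)
    b, _ = gnn.gat_forward(p_adj, p_x, gat_w, config)
    assert np.allclose(a[perm], b, atol=1e-5)


def test_unit_weight_gcn_equals_binary_gcn_exactly():
    rng = np.random.default_rng(30)
    n = 12
    binary = random_symmetric_adjacency(rng, n)  # entries 0/1
    x = rng.normal(size=(n, 3))
    y = (rng.random(n) < 0.5).astype(int)
    masks = gnn.make_splits(y, seed=0)
    config = gnn.GCNConfig(seed=3, max_epochs=40)
    m1 = gnn.train("gcn", binary, x, y, masks, gnn.GCNConfig(seed=3, max_epochs=40))
    m2 = gnn.train("gcn", binary * 1.0, x, y, masks, config)
    assert np.array_equal(m1.predictions, m2.predictions)


# ---------------------------------------------------------------------------
# training loop


def test_training_loss_decreases_on_trivial_target():
    rng = np.random.default_rng(2)
    n = 20
    adj = random_symmetric_adjacency(rng, n)
    x = rng.normal(size=(n, 3))
    y = np.zeros(n)
    y[:2] = 1  # keep both classes for the stratified split
    masks = gnn.make_splits(y, seed=1)
    config = gnn.GCNConfig(seed=0, dropout=0.0, max_epochs=5)
    model = gnn.train("gcn", adj, x, y, masks, config)
    losses = model.history["train_loss"]
    assert all(b < a for a, b in zip(losses, losses[1:]))


def test_early_stopping_patience_arithmetic():
    """One improvement then 31 stale epochs stops training at epoch 32."""
    stopper = gnn.EarlyStopping(patience=30)
    assert stopper.update(1.0, 1) is False
    stopped_at = None
    for epoch in range(2, 100):
        if stopper.update(1.0, epoch):
            stopped_at = epoch
            break
    assert stopped_at == 32
    assert stopper.best_epoch == 1


def test_trained_model_restores_best_weights_and_records_history():
    rng = np.random.default_rng(7)
    n = 30
    adj = random_symmetric_adjacency(rng, n)
    x = rng.normal(size=(n, 3))
    y = (x[:, 0] > 0).astype(int)
    masks = gnn.make_splits(y, seed=2)
    config = gnn.GCNConfig(seed=1, max_epochs=200)
    model = gnn.train("gcn", adj, x, y, masks, config)
    assert len(model.history["val_loss"]) <= 200
    best = model.history["best_epoch"]
    assert model.history["val_loss"][best - 1] == min(model.history["val_loss"])
    assert model.predictions.shape == (n,)
    assert model.embeddings.shape == (n, config.hidden_size)


def test_training_reproducible_under_seed():
    rng = np.random.default_rng(8)
    n = 25
    adj = random_symmetric_adjacency(rng, n)
    x = rng.normal(size=(n, 3))
    y = (rng.random(n) < 0.5).astype(int)
    masks = gnn.make_splits(y, seed=0)
    config = gnn.GATConfig(n_heads=2, head_features=4, seed=9, max_epochs=30)
    m1 = gnn.train("gat", adj, x, y, masks, config)
    m2 = gnn.train("gat", adj, x, y, masks, config)
    assert np.array_equal(m1.predictions, m2.predictions)


# ---------------------------------------------------------------------------
# splits


def test_make_splits_exact_small_ratio():
    y = np.array([0, 1] * 5)
    masks = gnn.make_splits(y, seed=0)
    assert masks.train.sum() == 6 and masks.val.sum() == 2 and masks.test.sum() == 2


def test_make_splits_deterministic_and_partitioning():
    y = (np.random.default_rng(3).random(97) < 0.4).astype(int)
    a = gnn.make_splits(y, seed=5)
    b = gnn.make_splits(y, seed=5)
    assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
    total = a.train.astype(int) + a.val.astype(int) + a.test.astype(int)
    assert np.all(total == 1)


def test_make_splits_stratified_within_two_percent():
    y = (np.random.default_rng(0).random(1000) < 0.5).astype(int)
    masks = gnn.make_splits(y, seed=1)
    overall = y.mean()
    for m in (masks.train, masks.val, masks.test):
        assert abs(y[m].mean() - overall) < 0.02


def test_make_splits_requires_both_classes():
    with pytest.raises(ConfigurationError):
        gnn.make_splits(np.zeros(10), seed=0)
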