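"""Graph neural networks for patient-node classification, in pure numpy.

Two architectures operate full-batch on the weighted patient network:

* **GCN** — three graph-convolution layers applying the symmetrically
  normalised propagation rule ``H' = sigma(D^-1/2 (A+I) D^-1/2 H W)`` with
  ReLU on the two hidden layers (16 units each) and a sigmoid output head
  producing a per-patient risk in (0, 1).
* **GAT** — two attention layers.  The first runs K=8 independent attention
  heads of F=8 features each (64-dimensional concatenated embeddings, ELU);
  the output layer is a single attention head followed by a sigmoid.
  Attention logits are ``LeakyReLU(a_src . W h_u + a_dst . W h_v)``,
  softmax-normalised over each node's neighbourhood (self-loop included).

Training minimises binary cross-entropy on the train mask with a
hand-written Adam optimiser, dropout p=0.3 on every layer input, and early
stopping on validation loss with best-weight restoration.  Gradients are
derived by hand and verified against finite differences in the test suite.

The adjacency can be binary or edge-weighted.  In the weighted GCN the raw
weights enter the propagation rule directly (self-loop weight 1); with all
weights equal to 1 this reduces exactly to the binary model.  The GAT uses
binary connectivity by default (attention learns tie strength); an optional
mode multiplies post-softmax coefficients by edge weights and renormalises.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, TrainingError

__all__ = [
    "GCNConfig",
    "GATConfig",
    "SplitMasks",
    "TrainedModel",
    "normalize_adjacency",
    "init_gcn_weights",
    "init_gat_weights",
    "gcn_forward",
    "gat_forward",
    "attention_coefficients",
    "train",
    "make_splits",
    "EarlyStopping",
]


# ---------------------------------------------------------------------------
# configs


@dataclass
class GCNConfig:
    """Hyperparameters of the 3-layer GCN (defaults as used throughout)."""

    hidden_size: int = 16
    dropout: float = 0.3
    learning_rate: float = 0.01
    max_epochs: int = 1000
    patience: int = 30
    seed: int = 0
    # Alternative head: two graph convolutions followed by a dense layer
    # instead of a third convolution.
    dense_head: bool = False

    def validate(self) -> None:
        if self.hidden_size <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("hidden_size and learning_rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.max_epochs <= 0 or self.patience <= 0:
            raise ConfigurationError("max_epochs and patience must be positive")


@dataclass
class GATConfig:
    """Hyperparameters of the 2-layer GAT (K=8 heads of F=8 features)."""

    n_heads: int = 8
    head_features: int = 8
    dropout: float = 0.3
    leaky_relu_slope: float = 0.2
    learning_rate: float = 0.01
    max_epochs: int = 1000
    patience: int = 30
    seed: int = 0
    # If True, post-softmax attention coefficients are multiplied by the
    # edge weights (self-loop weight 1) and renormalised per node.
    weighted_attention: bool = False

    def validate(self) -> None:
        if self.n_heads <= 0 or self.head_features <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("n_heads, head_features, learning_rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.max_epochs <= 0 or self.patience <= 0:
            raise ConfigurationError("max_epochs and patience must be positive")


@dataclass
class SplitMasks:
    """Disjoint boolean train/validation/test masks over nodes."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def validate(self) -> None:
        n = self.train.shape[0]
        if self.val.shape[0] != n or self.test.shape[0] != n:
            raise ConfigurationError("masks must have equal length")
        total = self.train.astype(int) + self.val.astype(int) + self.test.astype(int)
        if not np.all(total == 1):
            raise ConfigurationError("masks must partition the node set")


@dataclass
class TrainedModel:
    """A fitted GNN: config, learned weights, history, embeddings, risks."""

    kind: str
    config: GCNConfig | GATConfig
    weights: dict[str, np.ndarray]
    history: dict = field(default_factory=dict)
    predictions: np.ndarray | None = None
    embeddings: np.ndarray | None = None

    def save(self, path) -> None:
        arrays = {f"w__{k}": v for k, v in self.weights.items()}
        np.savez(
            path,
            kind=np.array(self.kind),
            predictions=self.predictions,
            embeddings=self.embeddings,
            train_loss=np.array(self.history.get("train_loss", [])),
            val_loss=np.array(self.history.get("val_loss", [])),
            **arrays,
        )


# ---------------------------------------------------------------------------
# primitives


def _relu(x):
    return np.maximum(x, 0.0)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _leaky(x, slope):
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x, slope):
    return np.where(x > 0, 1.0, slope)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(logits, y, mask):
    """Mean binary cross-entropy over masked nodes, from raw logits."""
    z = logits[mask]
    t = y[mask]
    return float(np.mean(np.logaddexp(0.0, z) - t * z))


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _dropout_mask(rng, shape, p):
    if p <= 0:
        return None
    return (rng.random(shape) >= p).astype(float) / (1.0 - p)


def _apply_dropout(x, mask):
    return x if mask is None else x * mask


def normalize_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric normalisation ``D^-1/2 (A + I) D^-1/2`` with self-loops.

    ``adj`` must be square, symmetric, nonnegative, with a zero diagonal
    (binary or edge-weighted).
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DataError(f"adjacency must be square, got shape {a.shape}")
    if not np.allclose(a, a.T):
        raise DataError("adjacency must be symmetric")
    if np.any(a < 0):
        raise DataError("adjacency must be nonnegative")
    if np.any(np.diag(a) != 0):
        raise DataError("adjacency must have a zero diagonal (self-loops are added here)")
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# GCN


def init_gcn_weights(n_features: int, config: GCNConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    h = config.hidden_size
    return {
        "W0": _glorot(rng, (n_features, h)),
        "W1": _glorot(rng, (h, h)),
        "W2": _glorot(rng, (h, 1)),
    }


def _gcn_forward(s_norm, x, weights, config, drop_masks=None):
    dm = drop_masks or [None, None, None]
    x0 = _apply_dropout(x, dm[0])
    pre1 = s_norm @ (x0 @ weights["W0"])
    h1 = _relu(pre1)
    h1d = _apply_dropout(h1, dm[1])
    pre2 = s_norm @ (h1d @ weights["W1"])
    h2 = _relu(pre2)
    h2d = _apply_dropout(h2, dm[2])
    if config.dense_head:
        logits = (h2d @ weights["W2"])[:, 0]
    else:
        logits = (s_norm @ (h2d @ weights["W2"]))[:, 0]
    cache = {
        "x0": x0, "pre1": pre1, "h1": h1, "h1d": h1d,
        "pre2": pre2, "h2": h2, "h2d": h2d, "dm": dm,
    }
    return logits, h2, cache


def _gcn_backward(s_norm, x, weights, config, cache, dlogits):
    """Gradients of the masked BCE w.r.t. the three weight matrices."""
    dl = dlogits[:, None]
    if config.dense_head:
        dW2 = cache["h2d"].T @ dl
        dh2d = dl @ weights["W2"].T
    else:
        sdl = s_norm @ dl  # s_norm is symmetric
        dW2 = cache["h2d"].T @ sdl
        dh2d = sdl @ weights["W2"].T
    dh2 = _apply_dropout(dh2d, cache["dm"][2])
    dpre2 = dh2 * (cache["pre2"] > 0)
    sdp2 = s_norm @ dpre2
    dW1 = cache["h1d"].T @ sdp2
    dh1d = sdp2 @ weights["W1"].T
    dh1 = _apply_dropout(dh1d, cache["dm"][1])
    dpre1 = dh1 * (cache["pre1"] > 0)
    sdp1 = s_norm @ dpre1
    dW0 = cache["x0"].T @ sdp1
    return {"W0": dW0, "W1": dW1, "W2": dW2}


def gcn_forward(
    adj: np.ndarray,
    x: np.ndarray,
    weights: dict[str, np.ndarray],
    config: GCNConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode forward pass.

    Returns (per-node risk in (0,1), last-hidden-layer embeddings).
    ``adj`` is the raw (binary or weighted) adjacency; normalisation with
    self-loops happens internally.
    """
    config = config or GCNConfig()
    s_norm = normalize_adjacency(adj)
    logits, h2, _ = _gcn_forward(s_norm, np.asarray(x, dtype=float), weights, config)
    if not np.all(np.isfinite(logits)):
        raise TrainingError("non-finite activations in GCN output layer")
    return _sigmoid(logits), h2


# ---------------------------------------------------------------------------
# GAT


def init_gat_weights(n_features: int, config: GATConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    k, f = config.n_heads, config.head_features
    return {
        "W1": _glorot(rng, (k, n_features, f)),
        "a_src1": _glorot(rng, (k, f, 1))[:, :, 0],
        "a_dst1": _glorot(rng, (k, f, 1))[:, :, 0],
        "W2": _glorot(rng, (1, k * f, 1)),
        "a_src2": _glorot(rng, (1, 1, 1))[:, :, 0],
        "a_dst2": _glorot(rng, (1, 1, 1))[:, :, 0],
    }


def _attention_layer_forward(x, w, a_src, a_dst, mask, slope, weight_mod=None):
    """Multi-head attention aggregation.

    x: (N, F_in); w: (K, F_in, F); a_src/a_dst: (K, F); mask: (N, N) boolean
    neighbourhoods including self-loops; weight_mod: optional (N, N) matrix
    of edge weights (self-loop 1) for post-softmax modulation.
    Returns per-head outputs (K, N, F) before activation, plus a cache.
    """
    z = np.einsum("nf,kfo->kno", x, w)
    s = np.einsum("kno,ko->kn", z, a_src)
    t = np.einsum("kno,ko->kn", z, a_dst)
    e = s[:, :, None] + t[:, None, :]
    pre = _leaky(e, slope)
    neg = np.where(mask[None, :, :], pre, -np.inf)
    m = neg.max(axis=2, keepdims=True)
    ex = np.exp(neg - m)
    ex = np.where(mask[None, :, :], ex, 0.0)
    denom = ex.sum(axis=2, keepdims=True)
    alpha_soft = ex / denom
    if weight_mod is not None:
        b = alpha_soft * weight_mod[None, :, :]
        r = b.sum(axis=2, keepdims=True)
        alpha = b / r
    else:
        alpha = alpha_soft
    out = np.einsum("kuv,kvf->kuf", alpha, z)
    cache = {
        "z": z, "e": e, "alpha_soft": alpha_soft, "alpha": alpha,
        "mask": mask, "weight_mod": weight_mod, "slope": slope,
    }
    return out, alpha, cache


def _attention_layer_backward(x, w, a_src, a_dst, cache, dout):
    """Backward pass of one attention layer; dout: (K, N, F)."""
    z, alpha = cache["z"], cache["alpha"]
    mask = cache["mask"]
    dalpha = np.einsum("kuf,kvf->kuv", dout, z)
    dz = np.einsum("kuv,kuf->kvf", alpha, dout)
    if cache["weight_mod"] is not None:
        # alpha = (alpha_soft * M) / rowsum; backprop the renormalisation.
        a_s = cache["alpha_soft"]
        m_mod = cache["weight_mod"][None, :, :]
        b = a_s * m_mod
        r = b.sum(axis=2, keepdims=True)
        row_dot = (dalpha * (b / r)).sum(axis=2, keepdims=True)
        db = (dalpha - row_dot) / r
        dalpha = db * m_mod
        alpha_sm = a_s
    else:
        alpha_sm = alpha
    # softmax backward (row-wise over neighbours)
    row_dot = (dalpha * alpha_sm).sum(axis=2, keepdims=True)
    de_pre = alpha_sm * (dalpha - row_dot)
    de = de_pre * _leaky_grad(cache["e"], cache["slope"])
    de = np.where(mask[None, :, :], de, 0.0)
    ds = de.sum(axis=2)
    dt = de.sum(axis=1)
    dz += ds[:, :, None] * a_src[:, None, :] + dt[:, :, None] * a_dst[:, None, :]
    da_src = np.einsum("kno,kn->ko", z, ds)
    da_dst = np.einsum("kno,kn->ko", z, dt)
    dw = np.einsum("nf,kno->kfo", x, dz)
    dx = np.einsum("kno,kfo->nf", dz, w)
    return dx, dw, da_src, da_dst


def _gat_masks(adj):
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T) or np.any(a < 0) or np.any(np.diag(a) != 0):
        raise DataError("adjacency must be symmetric, nonnegative, zero-diagonal")
    mask = (a > 0) | np.eye(a.shape[0], dtype=bool)
    weight_mod = a + np.eye(a.shape[0])
    return mask, weight_mod


def _gat_forward(adj_mask, weight_mod, x, weights, config, drop_masks=None):
    dm = drop_masks or [None, None]
    wm = weight_mod if config.weighted_attention else None
    x0 = _apply_dropout(x, dm[0])
    out1, _, cache1 = _attention_layer_forward(
        x0, weights["W1"], weights["a_src1"], weights["a_dst1"],
        adj_mask, config.leaky_relu_slope, wm,
    )
    act1 = _elu(out1)
    n = x.shape[0]
    h1 = np.transpose(act1, (1, 0, 2)).reshape(n, -1)  # concat heads -> (N, K*F)
    h1d = _apply_dropout(h1, dm[1])
    out2, _, cache2 = _attention_layer_forward(
        h1d, weights["W2"], weights["a_src2"], weights["a_dst2"],
        adj_mask, config.leaky_relu_slope, wm,
    )
    logits = out2.mean(axis=0)[:, 0]  # average heads (single head: identity)
    cache = {"x0": x0, "out1": out1, "h1": h1, "h1d": h1d,
             "cache1": cache1, "cache2": cache2, "dm": dm}
    return logits, h1, cache


def _gat_backward(x, weights, config, cache, dlogits):
    k2 = weights["W2"].shape[0]
    dout2 = np.broadcast_to(
        dlogits[None, :, None] / k2, (k2,) + dlogits.shape + (1,)
    ).copy()
    dh1d, dW2, da_src2, da_dst2 = _attention_layer_backward(
        cache["h1d"], weights["W2"], weights["a_src2"], weights["a_dst2"],
        cache["cache2"], dout2,
    )
    dh1 = _apply_dropout(dh1d, cache["dm"][1])
    n = dh1.shape[0]
    k, f = weights["W1"].shape[0], weights["W1"].shape[2]
    dact1 = np.transpose(dh1.reshape(n, k, f), (1, 0, 2))
    dout1 = dact1 * _elu_grad(cache["out1"])
    _, dW1, da_src1, da_dst1 = _attention_layer_backward(
        cache["x0"], weights["W1"], weights["a_src1"], weights["a_dst1"],
        cache["cache1"], dout1,
    )
    return {
        "W1": dW1, "a_src1": da_src1, "a_dst1": da_dst1,
        "W2": dW2, "a_src2": da_src2, "a_dst2": da_dst2,
    }


def gat_forward(
    adj: np.ndarray,
    x: np.ndarray,
    weights: dict[str, np.ndarray],
    config: GATConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode forward pass.

    Returns (per-node risk, concatenated multi-head embeddings of the first
    layer, dimension K*F).
    """
    config = config or GATConfig()
    mask, weight_mod = _gat_masks(adj)
    logits, h1, _ = _gat_forward(mask, weight_mod, np.asarray(x, dtype=float), weights, config)
    if not np.all(np.isfinite(logits)):
        raise TrainingError("non-finite activations in GAT output layer")
    return _sigmoid(logits), h1


def attention_coefficients(
    adj: np.ndarray,
    x: np.ndarray,
    weights: dict[str, np.ndarray],
    config: GATConfig | None = None,
    layer: int = 1,
) -> np.ndarray:
    """Attention coefficients alpha of one GAT layer, shape (K, N, N).

    For every node u and head k the coefficients over u's neighbourhood
    (self-loop included) sum to 1.  Entries outside the neighbourhood are 0.
    """
    config = config or GATConfig()
    mask, weight_mod = _gat_masks(adj)
    x = np.asarray(x, dtype=float)
    wm = weight_mod if config.weighted_attention else None
    if layer == 1:
        _, alpha, _ = _attention_layer_forward(
            x, weights["W1"], weights["a_src1"], weights["a_dst1"],
            mask, config.leaky_relu_slope, wm,
        )
        return alpha
    if layer == 2:
        logits_in, h1, _ = _gat_forward(mask, weight_mod, x, weights, config)
        _, alpha, _ = _attention_layer_forward(
            h1, weights["W2"], weights["a_src2"], weights["a_dst2"],
            mask, config.leaky_relu_slope, wm,
        )
        return alpha
    raise ConfigurationError(f"layer must be 1 or 2, got {layer}")


# ---------------------------------------------------------------------------
# training


class EarlyStopping:
    """Validation-loss early stopping with best-state restoration.

    Stops once the number of consecutive epochs without improvement
    *exceeds* ``patience``, i.e. training waits ``patience`` epochs after
    the best epoch and halts on the following one.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record an epoch's validation loss; return True to stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait > self.patience


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model_kind: str,
    adj: np.ndarray,
    x: np.ndarray,
    labels: np.ndarray,
    masks: SplitMasks,
    config: GCNConfig | GATConfig | None = None,
) -> TrainedModel:
    """Train a GCN or GAT node classifier with BCE loss and early stopping.

    Dropout is active only during training steps; validation loss is
    monitored every epoch and the best-validation weights are restored when
    training stops.  Deterministic under ``config.seed``.
    """
    if model_kind not in ("gcn", "gat"):
        raise ConfigurationError(f"model_kind must be 'gcn' or 'gat', got {model_kind!r}")
    if config is None:
        config = GCNConfig() if model_kind == "gcn" else GATConfig()
    config.validate()
    masks.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigurationError("labels must be binary")

    rng = np.random.default_rng(config.seed + 1)
    n_train = int(masks.train.sum())

    if model_kind == "gcn":
        s_norm = normalize_adjacency(adj)
        weights = init_gcn_weights(x.shape[1], config)

        def forward(drop):
            dm = (
                [_dropout_mask(rng, x.shape, config.dropout)] +
                [_dropout_mask(rng, (x.shape[0], config.hidden_size), config.dropout)
                 for _ in range(2)]
            ) if drop else None
            return _gcn_forward(s_norm, x, weights, config, dm)

        def backward(cache, dlogits):
            return _gcn_backward(s_norm, x, weights, config, cache, dlogits)
    else:
        mask_adj, weight_mod = _gat_masks(adj)
        weights = init_gat_weights(x.shape[1], config)
        h1_dim = config.n_heads * config.head_features

        def forward(drop):
            dm = (
                [_dropout_mask(rng, x.shape, config.dropout),
                 _dropout_mask(rng, (x.shape[0], h1_dim), config.dropout)]
            ) if drop else None
            return _gat_forward(mask_adj, weight_mod, x, weights, config, dm)

        def backward(cache, dlogits):
            return _gat_backward(x, weights, config, cache, dlogits)

    optimizer = _Adam(weights, config.learning_rate)
    stopper = EarlyStopping(config.patience)
    history: dict = {"train_loss": [], "val_loss": []}
    best_weights = copy.deepcopy(weights)

    for epoch in range(1, config.max_epochs + 1):
        logits, _, cache = forward(drop=True)
        loss = _bce_from_logits(logits, y, masks.train)
        if not np.isfinite(loss):
            raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")
        dlogits = np.where(masks.train, _sigmoid(logits) - y, 0.0) / n_train
        grads = backward(cache, dlogits)
        optimizer.step(weights, grads)

        eval_logits, _, _ = forward(drop=False)
        val_loss = _bce_from_logits(eval_logits, y, masks.val)
        history["train_loss"].append(loss)
        history["val_loss"].append(val_loss)
        improved = val_loss < stopper.best_loss
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_weights = copy.deepcopy(weights)
        if stop:
            break

    weights = best_weights
    history["best_epoch"] = stopper.best_epoch
    history["stopped_epoch"] = len(history["val_loss"])
    if model_kind == "gcn":
        logits, emb, _ = _gcn_forward(s_norm, x, weights, config)
    else:
        logits, emb, _ = _gat_forward(mask_adj, weight_mod, x, weights, config)
    return TrainedModel(
        kind=model_kind,
        config=config,
        weights=weights,
        history=history,
        predictions=_sigmoid(logits),
        embeddings=emb,
    )


# ---------------------------------------------------------------------------
# splits


def make_splits(
    labels: np.ndarray,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitMasks:
    """Stratified disjoint train/validation/test masks (default 60/20/20).

    Within each label class, shuffled indices are cut at
    round(m * r_train) and round(m * (r_train + r_val)), so split sizes are
    within one node of the target proportions per class.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if n < 5:
        raise ConfigurationError("make_splits requires at least 5 labelled nodes")
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r <= 0 for r in ratios):
        raise ConfigurationError("ratios must be positive and sum to 1")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigurationError(
            f"stratification requires both classes; found only {classes.tolist()}"
        )
    rng = np.random.default_rng(seed)
    train = np.zeros(n, dtype=bool)
    val = np.zeros(n, dtype=bool)
    test = np.zeros(n, dtype=bool)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        m = len(idx)
        c1 = int(round(m * ratios[0]))
        c2 = int(round(m * (ratios[0] + ratios[1])))
        train[idx[:c1]] = True
        val[idx[c1:c2]] = True
        test[idx[c2:]] = True
    masks = SplitMasks(train=train, val=val, test=test)
    masks.validate()
    return masks
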