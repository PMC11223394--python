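"""Transductive tissue-of-origin classification with a graph transformer.

Samples are nodes of an undirected graph built by k-nearest neighbors
(k = 5 by default, Euclidean distance on standardized features).  Two
graph-transformer layers (hidden width 64) propagate node latents with
dot-product attention over each node's neighborhood,

    a_uv = exp((W_Q z_u)^T (W_K z_v)) / sum_w exp((W_Q z_u)^T (W_K z_w)),
    z_u' = sum_v a_uv (W_V z_v) + z_u,

followed by an MLP head producing 5 class logits.  The softmax support
is the kNN neighborhood plus a self-loop (a dense variant over all
nodes is available behind a flag).  Training is transductive: every
node's features enter the graph, but only train/validation labels are
ever read; test labels are used solely for evaluation.  The loss is a
class-weighted focal loss (to counter class imbalance), optimized with
Adam at learning rate 1e-3; model selection is by stratified 10-fold
validation accuracy.

The network, its gradients and the Adam optimizer are implemented
directly in NumPy, which keeps the forward pass, the backward pass and
the attention masking fully inspectable and exactly reproducible from
one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

UNKNOWN = -1  # label code for unknown (test) nodes


@dataclass
class GraphDataset:
    """Node features, labels, masks and kNN adjacency for one graph.

    ``labels`` are integer class codes with ``-1`` for unknown nodes;
    ``train_mask`` marks the labeled pool used for cross-validation
    (per-fold validation splits are carved out of it), ``test_mask``
    the unknown nodes predicted transductively.
    """

    features: np.ndarray
    labels: np.ndarray
    adjacency: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length != number of nodes")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be N x N")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not self.adjacency.diagonal().all():
            raise ValueError("adjacency must include self-loops")
        if (self.train_mask & self.test_mask).any():
            raise ValueError("train and test masks overlap")
        if (self.labels[self.train_mask] == UNKNOWN).any():
            raise ValueError("train nodes must be labeled")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")


@dataclass
class TrainConfig:
    """Hyperparameters of graph construction and training."""

    k_neighbors: int = 5
    learning_rate: float = 1e-3
    focal_gamma: float = 2.0
    class_weights: np.ndarray | None = None  # default: inverse class frequency
    epochs: int = 300
    patience: int = 30
    seed: int = 0
    n_folds: int = 10
    hidden: int = 64
    n_layers: int = 2
    dense_softmax: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1 or self.n_folds < 2:
            raise ValueError("k_neighbors >= 1 and n_folds >= 2 required")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def build_knn_graph(features: np.ndarray, k: int) -> np.ndarray:
    """Boolean kNN adjacency: union-symmetrized, with self-loops.

    Each node links to its k nearest neighbors by Euclidean distance
    (self excluded); distance ties break deterministically by node
    index.  Requires N > k.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} nodes, got {n}")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    dist = cdist(features, features)
    np.fill_diagonal(dist, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for u in range(n):
        order = np.lexsort((idx, dist[u]))  # distance, then node index
        adj[u, order[:k]] = True
    adj |= adj.T
    np.fill_diagonal(adj, True)
    return adj


def init_parameters(
    d_in: int, hidden: int, n_classes: int, n_layers: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Glorot-style initialization of all learnable matrices."""

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, scale, size=(fan_in, fan_out))

    params = {"w_in": glorot(d_in, hidden), "b_in": np.zeros(hidden)}
    for l in range(n_layers):
        params[f"wq{l}"] = glorot(hidden, hidden)
        params[f"wk{l}"] = glorot(hidden, hidden)
        params[f"wv{l}"] = glorot(hidden, hidden)
    params["w1"] = glorot(hidden, hidden)
    params["b1"] = np.zeros(hidden)
    params["w2"] = glorot(hidden, n_classes)
    params["b2"] = np.zeros(n_classes)
    return params


def _masked_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    scores = np.where(mask, scores, -np.inf)
    scores = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(scores)
    return expd / expd.sum(axis=1, keepdims=True)


def gtn_layer_forward(
    z: np.ndarray,
    adjacency: np.ndarray,
    wq: np.ndarray,
    wk: np.ndarray,
    wv: np.ndarray,
    dense_softmax: bool = False,
    return_cache: bool = False,
):
    """One graph-transformer layer: masked attention + residual update.

    Attention logits are (W_Q z_u)^T (W_K z_v); the softmax runs over
    the neighborhood {v : a_uv = 1} (or all nodes when
    ``dense_softmax``).  Returns the next latents, or with
    ``return_cache`` a (latents, cache) pair where cache carries the
    attention matrix and projections for the backward pass.
    """
    if not np.isfinite(z).all():
        raise ValueError("non-finite latents entering layer")
    q = z @ wq
    k = z @ wk
    v = z @ wv
    mask = np.ones_like(adjacency, dtype=bool) if dense_softmax else adjacency.astype(bool)
    attn = _masked_softmax(q @ k.T, mask)
    z_next = attn @ v + z
    if return_cache:
        return z_next, {"z": z, "q": q, "k": k, "v": v, "attn": attn}
    return z_next


def _gtn_layer_backward(
    d_out: np.ndarray, cache: dict, wq: np.ndarray, wk: np.ndarray, wv: np.ndarray
):
    """Backward through one layer; returns (d_input, param grads)."""
    z, q, k, v, attn = cache["z"], cache["q"], cache["k"], cache["v"], cache["attn"]
    d_in = d_out.copy()  # residual branch
    d_v = attn.T @ d_out
    d_attn = d_out @ v.T
    # softmax backward (rows); off-mask entries of attn are exactly 0
    d_scores = attn * (d_attn - (d_attn * attn).sum(axis=1, keepdims=True))
    d_q = d_scores @ k
    d_k = d_scores.T @ q
    grads = {"wq": z.T @ d_q, "wk": z.T @ d_k, "wv": z.T @ d_v}
    d_in += d_q @ wq.T + d_k @ wk.T + d_v @ wv.T
    return d_in, grads


def forward(
    params: Mapping[str, np.ndarray],
    features: np.ndarray,
    adjacency: np.ndarray,
    n_layers: int = 2,
    dense_softmax: bool = False,
    return_cache: bool = False,
):
    """Full network forward pass: embed, L attention layers, MLP head.

    A rectifier sits between attention layers and inside the head.
    """
    cache: dict = {"layers": []}
    z = features @ params["w_in"] + params["b_in"]
    cache["z0"] = z
    for l in range(n_layers):
        z_next, layer_cache = gtn_layer_forward(
            z, adjacency, params[f"wq{l}"], params[f"wk{l}"], params[f"wv{l}"],
            dense_softmax=dense_softmax, return_cache=True,
        )
        if l < n_layers - 1:
            pre = z_next
            z = np.maximum(pre, 0.0)
            layer_cache["relu_pre"] = pre
        else:
            z = z_next
        cache["layers"].append(layer_cache)
    pre_head = z @ params["w1"] + params["b1"]
    hidden = np.maximum(pre_head, 0.0)
    logits = hidden @ params["w2"] + params["b2"]
    cache.update({"z_final": z, "pre_head": pre_head, "hidden": hidden})
    if return_cache:
        return logits, cache
    return logits


def backward(
    params: Mapping[str, np.ndarray],
    cache: dict,
    features: np.ndarray,
    d_logits: np.ndarray,
    n_layers: int = 2,
) -> dict[str, np.ndarray]:
    """Gradients of the scalar loss w.r.t. every parameter."""
    grads: dict[str, np.ndarray] = {}
    grads["w2"] = cache["hidden"].T @ d_logits
    grads["b2"] = d_logits.sum(axis=0)
    d_hidden = d_logits @ params["w2"].T
    d_pre = d_hidden * (cache["pre_head"] > 0.0)
    grads["w1"] = cache["z_final"].T @ d_pre
    grads["b1"] = d_pre.sum(axis=0)
    dz = d_pre @ params["w1"].T
    for l in reversed(range(n_layers)):
        layer_cache = cache["layers"][l]
        if "relu_pre" in layer_cache:
            dz = dz * (layer_cache["relu_pre"] > 0.0)
        dz, layer_grads = _gtn_layer_backward(
            dz, layer_cache, params[f"wq{l}"], params[f"wk{l}"], params[f"wv{l}"]
        )
        for name, g in layer_grads.items():
            grads[f"{name}{l}"] = g
    grads["w_in"] = features.T @ dz
    grads["b_in"] = dz.sum(axis=0)
    return grads


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


def focal_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    gamma: float = 2.0,
    class_weights: np.ndarray | None = None,
) -> float:
    """Mean focal loss: -w_y (1 - p_y)^gamma log p_y over labeled nodes.

    At gamma = 0 with unit weights this is exactly cross-entropy.
    Unknown labels (-1) in the batch raise.
    """
    loss, _ = _focal_loss_and_grad(logits, labels, gamma, class_weights)
    return loss


def _focal_loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    gamma: float,
    class_weights: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    labels = np.asarray(labels)
    if (labels < 0).any():
        raise ValueError("unknown label in loss batch")
    n, n_classes = logits.shape
    probs = softmax(logits)
    p_y = np.clip(probs[np.arange(n), labels], 1e-12, 1.0)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[labels]
    one_minus = 1.0 - p_y
    focal = one_minus**gamma
    loss = float(np.mean(-w * focal * np.log(p_y)))
    # dL/dp_y, then chain through the softmax
    if gamma == 0.0:
        d_py = -w / p_y
    else:
        d_py = w * (
            gamma * one_minus ** (gamma - 1.0) * np.log(p_y) - focal / p_y
        )
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    d_logits = (d_py * p_y)[:, None] * (onehot - probs) / n
    return loss, d_logits


def stratified_folds(labels: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per sample; per-class counts across folds differ by <= 1."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < n_folds:
            raise ValueError(
                f"class {cls!r} has {cnt} members, fewer than n_folds={n_folds}"
            )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for f, (_, val_idx) in enumerate(splitter.split(np.zeros((len(labels), 1)), labels)):
        folds[val_idx] = f
    return folds


class _Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1**self.t)
            v_hat = self.v[key] / (1 - self.beta2**self.t)
            params[key] = params[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _inverse_frequency_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return w / w.mean()


def train_transductive(
    dataset: GraphDataset, config: TrainConfig
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Stratified k-fold training; returns best-fold parameters + metrics.

    For each fold the labeled pool splits into train/validation; the
    network trains with focal loss and Adam, early-stopping on
    validation accuracy.  The parameters of the fold with the highest
    validation accuracy are returned along with per-fold metrics.
    Fully deterministic given ``config.seed``.
    """
    x = dataset.features
    n_classes = int(dataset.labels.max()) + 1
    labeled_idx = np.flatnonzero(dataset.train_mask)
    folds = stratified_folds(dataset.labels[labeled_idx], config.n_folds, config.seed)
    fold_metrics: list[dict] = []
    best: tuple[float, int, dict] | None = None
    for f in range(config.n_folds):
        val_idx = labeled_idx[folds == f]
        train_idx = labeled_idx[folds != f]
        rng = np.random.default_rng((config.seed * 1000 + f) % (2**31))
        params = init_parameters(
            x.shape[1], config.hidden, n_classes, config.n_layers, rng
        )
        optimizer = _Adam(params, config.learning_rate)
        weights = (
            np.asarray(config.class_weights, dtype=float)
            if config.class_weights is not None
            else _inverse_frequency_weights(dataset.labels[train_idx], n_classes)
        )
        best_val, best_epoch, best_params = -1.0, -1, None
        stall = 0
        for epoch in range(config.epochs):
            logits, cache = forward(
                params, x, dataset.adjacency, config.n_layers,
                dense_softmax=config.dense_softmax, return_cache=True,
            )
            loss, d_rows = _focal_loss_and_grad(
                logits[train_idx], dataset.labels[train_idx],
                config.focal_gamma, weights,
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"fold {f}: non-finite loss at epoch {epoch}")
            d_logits = np.zeros_like(logits)
            d_logits[train_idx] = d_rows
            grads = backward(params, cache, x, d_logits, config.n_layers)
            optimizer.step(params, grads)
            val_pred = forward(
                params, x, dataset.adjacency, config.n_layers,
                dense_softmax=config.dense_softmax,
            )[val_idx].argmax(axis=1)
            val_acc = float(np.mean(val_pred == dataset.labels[val_idx]))
            if val_acc > best_val:
                best_val, best_epoch = val_acc, epoch
                best_params = {k: v.copy() for k, v in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
        fold_metrics.append(
            {"fold": f, "val_accuracy": best_val, "best_epoch": best_epoch,
             "final_train_loss": loss, "n_train": len(train_idx), "n_val": len(val_idx)}
        )
        logger.info("fold %d: val accuracy %.3f at epoch %d", f, best_val, best_epoch)
        if best is None or best_val > best[0]:
            best = (best_val, f, best_params)
    assert best is not None
    return best[2], fold_metrics


def predict_nodes(
    params: Mapping[str, np.ndarray],
    dataset: GraphDataset,
    mask: np.ndarray,
    n_layers: int = 2,
    dense_softmax: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class codes and softmax probabilities for masked nodes."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (dataset.features.shape[0],):
            raise ValueError("boolean mask length != number of nodes")
        idx = np.flatnonzero(mask)
    else:
        idx = mask.astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= dataset.features.shape[0]):
            raise ValueError("mask references absent nodes")
    logits = forward(
        params, dataset.features, dataset.adjacency, n_layers,
        dense_softmax=dense_softmax,
    )
    probs = softmax(logits[idx])
    return probs.argmax(axis=1), probs
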