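"""Word-level CNN classifier with exact analytic gradients, in pure numpy.

Architecture: an embedding lookup turns a padded index sequence of length n
into a document matrix A (n x k).  For each filter width h, a bank of
linear filters w (flattened h*k vectors) slides over all n-h+1 word windows,
o_i = w . A[i:i+h-1]; a bias and activation give the feature map
c_i = f(o_i + b); global max pooling keeps the single largest response per
filter (recording its position for gradient routing).  Pooled responses
from all widths are concatenated, passed through a fully-connected hidden
layer with inverted dropout, and a softmax layer yields class
probabilities trained under mean cross-entropy.

Gradients are derived by hand and checked against central finite
differences in the test suite; no autodiff framework is involved.  The PAD
embedding row is frozen at zero and receives no gradient, so padding is
exactly the "zero vector" the document matrix construction assumes.
Weight-norm regularization follows the max-norm convention of the word-CNN
lineage: after each optimizer application, any constrained row/column whose
l2 norm exceeds the cap s is rescaled onto the sphere of radius s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from downpourtext.preprocess import PAD_INDEX, EncodedDocument

__all__ = [
    "ModelConfig", "ModelParams", "ForwardCache", "desk_model_config",
    "init_params", "embed_document", "convolve_pool", "forward",
    "loss", "batch_loss", "backward", "batch_gradients",
    "apply_norm_constraints", "predict", "predict_batch",
    "save_params", "load_params", "zero_gradients",
]

_LOSS_EPS = 1e-12  # clamp for -log p[label] when a probability underflows


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and regularization hyperparameters.

    Defaults are the full-scale configuration: 1500-token documents,
    300-dimensional embeddings initialized uniform in (-0.025, 0.025),
    300 filters for each width in {3, 4, 5}, a 300-unit rectifier hidden
    layer with dropout 0.5, and a max-norm cap of 3 on word vectors, filter
    weight vectors and dense columns.  Hidden size, activation and norm cap
    are documented package choices where the study leaves them open.
    """

    embed_dim: int = 300
    filter_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 300
    hidden_units: int = 300
    dropout_rate: float = 0.5
    activation: str = "relu"
    norm_cap: float = 3.0
    embed_init_bound: float = 0.025
    max_len: int = 1500

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.filters_per_width < 1 or self.hidden_units < 1:
            raise ValueError("embed_dim, filters_per_width, hidden_units must be positive")
        if not self.filter_widths:
            raise ValueError("at least one filter width required")
        if any(h < 1 or h > self.max_len for h in self.filter_widths):
            raise ValueError("filter widths must lie in 1..max_len")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        if self.norm_cap <= 0:
            raise ValueError("norm_cap must be positive")

    @property
    def pooled_dim(self) -> int:
        return len(self.filter_widths) * self.filters_per_width


def desk_model_config(**overrides) -> ModelConfig:
    """The desk-scale architecture: 100-token documents, 48-dim embeddings,
    24 filters per width {3,4,5}, a 96-unit hidden layer.  Small enough to
    train in seconds on one CPU while keeping every structural feature of
    the full-scale model."""
    defaults = dict(
        embed_dim=48, filters_per_width=24, hidden_units=96, max_len=100,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def _act(name: str, x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) if name == "relu" else np.tanh(x)


def _act_grad(name: str, x: np.ndarray, fx: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype) if name == "relu" else 1.0 - fx * fx


@dataclass
class ModelParams:
    """Named parameter tensors: embedding, per-width filter banks, dense layers."""

    tensors: dict[str, np.ndarray]
    vocab_size: int
    n_classes: int

    def copy(self) -> "ModelParams":
        return ModelParams(
            tensors={k: v.copy() for k, v in self.tensors.items()},
            vocab_size=self.vocab_size,
            n_classes=self.n_classes,
        )

    def __getitem__(self, key: str) -> np.ndarray:
        return self.tensors[key]


def init_params(
    config: ModelConfig, vocab_size: int, n_classes: int, seed: int = 0
) -> ModelParams:
    """Seeded initialization: embeddings uniform within the stated bound
    (PAD row zero), other weights uniform scaled by 1/sqrt(fan_in), zero biases."""
    if vocab_size < 1 or n_classes < 2:
        raise ValueError("need vocab_size >= 1 and n_classes >= 2")
    rng = np.random.default_rng(seed)
    b = config.embed_init_bound
    tensors: dict[str, np.ndarray] = {}
    emb = rng.uniform(-b, b, size=(vocab_size, config.embed_dim))
    emb[PAD_INDEX] = 0.0
    tensors["embedding"] = emb
    for h in config.filter_widths:
        fan_in = h * config.embed_dim
        bound = (1.0 / fan_in) ** 0.5
        tensors[f"conv{h}_W"] = rng.uniform(
            -bound, bound, size=(config.filters_per_width, fan_in)
        )
        tensors[f"conv{h}_b"] = np.zeros(config.filters_per_width)
    d = config.pooled_dim
    bound = (1.0 / d) ** 0.5
    tensors["hidden_W"] = rng.uniform(-bound, bound, size=(d, config.hidden_units))
    tensors["hidden_b"] = np.zeros(config.hidden_units)
    bound = (1.0 / config.hidden_units) ** 0.5
    tensors["out_W"] = rng.uniform(-bound, bound, size=(config.hidden_units, n_classes))
    tensors["out_b"] = np.zeros(n_classes)
    return ModelParams(tensors=tensors, vocab_size=vocab_size, n_classes=n_classes)


def zero_gradients(params: ModelParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.tensors.items()}


def embed_document(doc: EncodedDocument, params: ModelParams) -> np.ndarray:
    """Stack word vectors into the document matrix A (max_len x embed_dim)."""
    idx = doc.indices
    if idx.max(initial=0) >= params.vocab_size or idx.min(initial=0) < 0:
        raise ValueError("document index outside vocabulary range")
    return params.tensors["embedding"][idx]


def _windows(A: np.ndarray, h: int) -> np.ndarray:
    """All n-h+1 sliding windows of A, flattened to rows of length h*k."""
    n, k = A.shape
    view = np.lib.stride_tricks.sliding_window_view(A, (h, k))
    return view.reshape(n - h + 1, h * k)


def convolve_pool(
    A: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "relu"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convolve a filter bank over all word windows and max-pool each feature map.

    Returns ``(pooled, argmax, preact_at_argmax)`` where ``pooled[j]`` is the
    maximum of filter *j*'s feature map ``c_i = f(o_i + b_j)`` over the
    n-h+1 window start positions, ``argmax[j]`` the position attaining it
    (lowest index on ties, numpy argmax convention).
    """
    h = W.shape[1] // A.shape[1]
    win = _windows(A, h)
    pre = win @ W.T + b  # (n-h+1, F)
    c = _act(activation, pre)
    arg = c.argmax(axis=0)
    cols = np.arange(W.shape[0])
    return c[arg, cols], arg, pre[arg, cols]


@dataclass
class ForwardCache:
    """Intermediate quantities retained for the backward pass."""

    A: np.ndarray
    pooled: np.ndarray
    argmax: dict[int, np.ndarray]
    preact: dict[int, np.ndarray]
    hidden_pre: np.ndarray
    hidden_act: np.ndarray
    dropout_mask: np.ndarray
    dropped: np.ndarray
    probs: np.ndarray
    label_index: int = -1


def forward(
    doc: EncodedDocument,
    params: ModelParams,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    train: bool = False,
    dropout_mask: np.ndarray | None = None,
) -> ForwardCache:
    """Full forward pass; in training mode an inverted-dropout mask is drawn
    from ``rng`` (or supplied explicitly) so evaluation needs no rescaling."""
    A = embed_document(doc, params)
    pooled_parts: list[np.ndarray] = []
    argmax: dict[int, np.ndarray] = {}
    preact: dict[int, np.ndarray] = {}
    for h in config.filter_widths:
        p, a, pre = convolve_pool(
            A, params[f"conv{h}_W"], params[f"conv{h}_b"], config.activation
        )
        pooled_parts.append(p)
        argmax[h] = a
        preact[h] = pre
    pooled = np.concatenate(pooled_parts)

    z = pooled @ params["hidden_W"] + params["hidden_b"]
    hact = _act(config.activation, z)
    if dropout_mask is not None:
        mask = dropout_mask
    elif train and config.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode forward with dropout needs an rng or mask")
        keep = 1.0 - config.dropout_rate
        mask = (rng.random(config.hidden_units) < keep) / keep
    else:
        mask = np.ones(config.hidden_units)
    dropped = hact * mask

    logits = dropped @ params["out_W"] + params["out_b"]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in forward pass")
    shifted = logits - logits.max()
    exp = np.exp(shifted)
    probs = exp / exp.sum()
    return ForwardCache(
        A=A, pooled=pooled, argmax=argmax, preact=preact,
        hidden_pre=z, hidden_act=hact, dropout_mask=mask, dropped=dropped,
        probs=probs, label_index=doc.label_index,
    )


def loss(probs: np.ndarray, label_index: int) -> float:
    """Cross-entropy -log p[label], epsilon-clamped against underflow."""
    return float(-np.log(max(probs[label_index], _LOSS_EPS)))


def batch_loss(
    docs: list[EncodedDocument], params: ModelParams, config: ModelConfig
) -> float:
    """Mean evaluation-mode cross-entropy over a list of documents."""
    total = 0.0
    for doc in docs:
        total += loss(forward(doc, params, config).probs, doc.label_index)
    return total / len(docs)


def backward(
    cache: ForwardCache,
    doc: EncodedDocument,
    params: ModelParams,
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Exact gradients of the single-document cross-entropy w.r.t. every tensor.

    Max pooling routes each filter's gradient only to its argmax window; the
    embedding gradient scatters window contributions back onto the rows of
    the index sequence, with the PAD row forced to zero afterwards.
    """
    if cache.label_index < 0:
        raise ValueError("cache/document carries no label; cannot take loss gradient")
    grads = zero_gradients(params)
    dlogits = cache.probs.copy()
    dlogits[cache.label_index] -= 1.0

    grads["out_W"] = np.outer(cache.dropped, dlogits)
    grads["out_b"] = dlogits
    ddropped = params["out_W"] @ dlogits
    dhact = ddropped * cache.dropout_mask
    dz = dhact * _act_grad(config.activation, cache.hidden_pre, cache.hidden_act)
    grads["hidden_W"] = np.outer(cache.pooled, dz)
    grads["hidden_b"] = dz
    dpooled = params["hidden_W"] @ dz

    dA = np.zeros_like(cache.A)
    F = config.filters_per_width
    k = config.embed_dim
    for wi, h in enumerate(config.filter_widths):
        dp = dpooled[wi * F: (wi + 1) * F]
        do = dp * _act_grad(
            config.activation, cache.preact[h], _act(config.activation, cache.preact[h])
        )
        arg = cache.argmax[h]
        win = _windows(cache.A, h)
        grads[f"conv{h}_W"] = do[:, None] * win[arg]
        grads[f"conv{h}_b"] = do
        W = params[f"conv{h}_W"].reshape(F, h, k)
        contrib = do[:, None, None] * W  # (F, h, k)
        for j in range(F):
            dA[arg[j]: arg[j] + h] += contrib[j]

    gE = grads["embedding"]
    np.add.at(gE, doc.indices, dA)
    gE[PAD_INDEX] = 0.0
    return grads


def batch_gradients(
    docs: list[EncodedDocument],
    params: ModelParams,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    train: bool = True,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean loss and mean gradients over a mini-batch (documents in order)."""
    if not docs:
        raise ValueError("empty mini-batch")
    total_loss = 0.0
    acc: dict[str, np.ndarray] | None = None
    for doc in docs:
        cache = forward(doc, params, config, rng=rng, train=train)
        total_loss += loss(cache.probs, doc.label_index)
        g = backward(cache, doc, params, config)
        if acc is None:
            acc = g
        else:
            for key in acc:
                acc[key] += g[key]
    assert acc is not None
    inv = 1.0 / len(docs)
    for key in acc:
        acc[key] *= inv
    return total_loss * inv, acc


def apply_norm_constraints(params: ModelParams, s: float) -> ModelParams:
    """Max-norm constraint, in place: rescale any word vector, filter weight
    vector, or dense column whose l2 norm exceeds ``s`` down to norm ``s``."""
    if s <= 0:
        raise ValueError("norm cap must be positive")

    def cap_rows(mat: np.ndarray) -> None:
        norms = np.linalg.norm(mat, axis=1)
        over = norms > s
        if over.any():
            mat[over] *= (s / norms[over])[:, None]

    cap_rows(params.tensors["embedding"])
    params.tensors["embedding"][PAD_INDEX] = 0.0
    for key, mat in params.tensors.items():
        if key.startswith("conv") and key.endswith("_W"):
            cap_rows(mat)
    for key in ("hidden_W", "out_W"):
        mat = params.tensors[key]
        norms = np.linalg.norm(mat, axis=0)
        over = norms > s
        if over.any():
            mat[:, over] *= s / norms[over]
    return params


def predict(doc: EncodedDocument, params: ModelParams, config: ModelConfig) -> int:
    """Evaluation-mode argmax class; ties resolve to the lowest class index."""
    return int(np.argmax(forward(doc, params, config).probs))


def predict_batch(
    docs: list[EncodedDocument], params: ModelParams, config: ModelConfig
) -> np.ndarray:
    return np.array([predict(doc, params, config) for doc in docs], dtype=np.int64)


def save_params(params: ModelParams, config: ModelConfig, path) -> None:
    """Single .npz archive of named arrays plus a JSON sidecar of the config."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **params.tensors)
    sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
    meta = {
        "vocab_size": params.vocab_size,
        "n_classes": params.n_classes,
        "config": {
            "embed_dim": config.embed_dim,
            "filter_widths": list(config.filter_widths),
            "filters_per_width": config.filters_per_width,
            "hidden_units": config.hidden_units,
            "dropout_rate": config.dropout_rate,
            "activation": config.activation,
            "norm_cap": config.norm_cap,
            "embed_init_bound": config.embed_init_bound,
            "max_len": config.max_len,
        },
    }
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_params(path) -> tuple[ModelParams, ModelConfig]:
    path = str(path)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    cfg = dict(meta["config"])
    cfg["filter_widths"] = tuple(cfg["filter_widths"])
    config = ModelConfig(**cfg)
    with np.load(npz_path) as archive:
        tensors = {k: archive[k].copy() for k in archive.files}
    params = ModelParams(
        tensors=tensors,
        vocab_size=int(meta["vocab_size"]),
        n_classes=int(meta["n_classes"]),
    )
    return params, config
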