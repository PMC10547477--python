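"""Multimodal autoencoder embeddings of genes from stacked network layers.

Six weighted adjacency layers (neighborhood, fusion, cooccurrence,
coexpression, experimental, database) over a common gene index are each fed
through their own ReLU encoder into a single shared bounded embedding layer,
then decoded back per layer; the loss is the sum of per-layer binary
cross-entropies against the adjacency rows. Training uses Adam with
mini-batches on a random 90% of genes, the remaining 10% monitoring
validation loss, and the weights from the epoch with the lowest validation
loss produce the final embedding for all genes. The implementation is plain
NumPy with manual backpropagation, fully determined by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYER_NAMES = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experimental",
    "database",
)


class EmbeddingError(ValueError):
    pass


@dataclass
class NetworkStack:
    """Ordered named adjacency layers over one gene index.

    Each layer is symmetric, max-normalized to [0, 1], zero-diagonal.
    """

    genes: list[str]
    layers: dict[str, np.ndarray]

    def __post_init__(self):
        n = len(self.genes)
        for name, m in self.layers.items():
            if m.shape != (n, n):
                raise EmbeddingError(f"layer {name}: shape {m.shape} != ({n}, {n})")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def matrices(self) -> list[np.ndarray]:
        return [self.layers[k] for k in self.layers]


def build_stack(
    edge_lists: dict[str, pd.DataFrame],
    genes: list[str],
) -> NetworkStack:
    """Assemble symmetric max-normalized layers from per-layer edge lists.

    Edge lists have columns (geneA, geneB, weight), weight >= 0. Asymmetric
    inputs are symmetrized by the max rule; each layer is divided by its
    maximum weight; genes absent from a layer keep zero rows.
    """
    idx = {g: i for i, g in enumerate(genes)}
    layers: dict[str, np.ndarray] = {}
    for name, df in edge_lists.items():
        m = np.zeros((len(genes), len(genes)))
        unknown = sorted(
            set(df["geneA"]).union(df["geneB"]) - idx.keys()
        )
        if unknown:
            raise EmbeddingError(f"layer {name}: edges reference unknown genes {unknown}")
        if (df["weight"] < 0).any():
            raise EmbeddingError(f"layer {name}: negative edge weight")
        for a, b, w in df[["geneA", "geneB", "weight"]].itertuples(index=False):
            i, j = idx[a], idx[b]
            if i == j:
                continue
            w = float(w)
            m[i, j] = max(m[i, j], w)
            m[j, i] = max(m[j, i], w)
        mx = m.max()
        if mx > 0:
            m /= mx
        else:
            logger.warning("layer %s is empty; all-zero matrix", name)
        layers[name] = m
    return NetworkStack(genes=list(genes), layers=layers)


def rwr_ppmi(stack: NetworkStack, restart: float = 0.5, steps: int = 3) -> NetworkStack:
    """Optional random-walk-with-restart + PPMI preprocessing of each layer."""
    out = {}
    for name, a in stack.layers.items():
        deg = a.sum(axis=1, keepdims=True)
        p = np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)
        n = a.shape[0]
        acc = np.zeros_like(a)
        cur = np.eye(n)
        for _ in range(steps):
            cur = restart * np.eye(n) + (1 - restart) * (cur @ p)
            acc += cur
        col = acc.sum(axis=0, keepdims=True)
        row = acc.sum(axis=1, keepdims=True)
        tot = acc.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log(np.where(acc > 0, acc * tot / np.where(row * col > 0, row * col, 1), 1))
        ppmi = np.maximum(pmi, 0)
        mx = ppmi.max()
        out[name] = ppmi / mx if mx > 0 else ppmi
    return NetworkStack(genes=list(stack.genes), layers=out)


@dataclass
class AutoencoderConfig:
    hidden: int = 256
    embedding_dim: int = 256
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-3
    validation_fraction: float = 0.10
    activation: str = "sigmoid"  # embedding-layer activation: sigmoid or tanh
    seed: int = 0
    preprocess_rwr_ppmi: bool = False


@dataclass
class EmbeddingMatrix:
    genes: list[str]
    values: np.ndarray  # genes x d
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i}" for i in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=self.genes, columns=cols)


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable


_EMB_ACT = {"sigmoid": _sigmoid, "tanh": np.tanh}
_EMB_ACT_GRAD = {
    "sigmoid": lambda z: z * (1.0 - z),
    "tanh": lambda z: 1.0 - z * z,
}


class _Params(dict):
    def copy_values(self):
        return {k: v.copy() for k, v in self.items()}


def _init_params(n: int, n_layers: int, h: int, d: int, rng: np.random.Generator) -> _Params:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    p = _Params()
    for l in range(n_layers):
        p[f"W1_{l}"] = glorot(n, h)
        p[f"b1_{l}"] = np.zeros(h)
        p[f"W3_{l}"] = glorot(d, h)
        p[f"b3_{l}"] = np.zeros(h)
        p[f"W4_{l}"] = glorot(h, n)
        p[f"b4_{l}"] = np.zeros(n)
    p["W2"] = glorot(n_layers * h, d)
    p["b2"] = np.zeros(d)
    return p


def _forward(params: _Params, xs: list[np.ndarray], act: str):
    n_layers = len(xs)
    h1 = [_relu(x @ params[f"W1_{l}"] + params[f"b1_{l}"]) for l, x in enumerate(xs)]
    hcat = np.concatenate(h1, axis=1)
    z = _EMB_ACT[act](hcat @ params["W2"] + params["b2"])
    g = [_relu(z @ params[f"W3_{l}"] + params[f"b3_{l}"]) for l in range(n_layers)]
    y = [_sigmoid(gl @ params[f"W4_{l}"] + params[f"b4_{l}"]) for l, gl in enumerate(g)]
    return h1, hcat, z, g, y


def _bce(y: np.ndarray, t: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(t * np.log(y + eps) + (1 - t) * np.log(1 - y + eps)))


def _loss(params: _Params, xs: list[np.ndarray], act: str) -> float:
    *_, y = _forward(params, xs, act)
    return sum(_bce(yl, xl) for yl, xl in zip(y, xs))


def _gradients(params: _Params, xs: list[np.ndarray], act: str):
    n_layers = len(xs)
    B = xs[0].shape[0]
    h1, hcat, z, g, y = _forward(params, xs, act)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dz = np.zeros_like(z)
    for l in range(n_layers):
        n_units = xs[l].shape[1]
        # d(mean BCE)/d(pre-sigmoid) = (y - t) / (B * n_units)
        dpre4 = (y[l] - xs[l]) / (B * n_units)
        grads[f"W4_{l}"] = g[l].T @ dpre4
        grads[f"b4_{l}"] = dpre4.sum(axis=0)
        dg = dpre4 @ params[f"W4_{l}"].T
        dpre3 = dg * (g[l] > 0)
        grads[f"W3_{l}"] = z.T @ dpre3
        grads[f"b3_{l}"] = dpre3.sum(axis=0)
        dz += dpre3 @ params[f"W3_{l}"].T
    dpre2 = dz * _EMB_ACT_GRAD[act](z)
    grads["W2"] = hcat.T @ dpre2
    grads["b2"] = dpre2.sum(axis=0)
    dhcat = dpre2 @ params["W2"].T
    h = h1[0].shape[1]
    for l in range(n_layers):
        dh = dhcat[:, l * h : (l + 1) * h]
        dpre1 = dh * (h1[l] > 0)
        grads[f"W1_{l}"] = xs[l].T @ dpre1
        grads[f"b1_{l}"] = dpre1.sum(axis=0)
    return grads


def train_autoencoder(stack: NetworkStack, config: AutoencoderConfig) -> EmbeddingMatrix:
    """Train the multimodal autoencoder and return per-gene embeddings.

    The embedding is extracted with the weights from the epoch of minimum
    validation loss; training is fully seeded and bit-reproducible.
    """
    n = stack.n_genes
    if n < 2:
        raise EmbeddingError("need at least 2 genes")
    cfg = config
    if cfg.embedding_dim >= n:
        logger.warning("embedding dim %d >= n genes %d", cfg.embedding_dim, n)
    work = rwr_ppmi(stack) if cfg.preprocess_rwr_ppmi else stack
    mats = work.matrices()
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(n, len(mats), cfg.hidden, cfg.embedding_dim, rng)

    n_val = max(1, int(round(cfg.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xs_train = [m[train_idx] for m in mats]
    xs_val = [m[val_idx] for m in mats]

    # Adam state
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best = {"epoch": -1, "val": np.inf, "params": params.copy_values()}
    val_history: list[float] = []
    n_train = len(train_idx)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb = [x[batch] for x in xs_train]
            grads = _gradients(params, xb, cfg.activation)
            step += 1
            for k in params:
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
                mhat = m_state[k] / (1 - beta1**step)
                vhat = v_state[k] / (1 - beta2**step)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        val_loss = _loss(params, xs_val, cfg.activation)
        if not np.isfinite(val_loss):
            raise EmbeddingError(
                f"non-finite validation loss at epoch {epoch} "
                f"(lr={cfg.learning_rate}, activation={cfg.activation})"
            )
        val_history.append(val_loss)
        if val_loss < best["val"]:
            best = {"epoch": epoch, "val": val_loss, "params": params.copy_values()}

    final = best["params"]
    _, _, z, _, _ = _forward(final, mats, cfg.activation)
    meta = {
        "epochs_run": cfg.epochs,
        "selected_epoch": int(best["epoch"]),
        "val_loss": float(best["val"]),
        "train_loss": _loss(final, xs_train, cfg.activation),
        "val_history": [float(v) for v in val_history],
        "activation": cfg.activation,
        "seed": cfg.seed,
    }
    return EmbeddingMatrix(genes=list(stack.genes), values=z, meta=meta)


def export_embeddings(emb: EmbeddingMatrix, path) -> None:
    """Write a TSV of gene x dimensions with metadata comment lines."""
    if len(emb.genes) == 0:
        raise EmbeddingError("empty embedding matrix")
    with open(path, "w") as fh:
        fh.write(f"# selected_epoch={emb.meta.get('selected_epoch')}\n")
        fh.write(f"# epochs_run={emb.meta.get('epochs_run')}\n")
        fh.write(f"# val_loss={emb.meta.get('val_loss')}\n")
        fh.write(f"# seed={emb.meta.get('seed')}\n")
        emb.to_frame().to_csv(fh, sep="\t", index_label="gene", float_format="%.10g")


def read_embeddings(path) -> EmbeddingMatrix:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col="gene")
    for key in ("selected_epoch", "epochs_run", "seed"):
        if meta.get(key, "None") != "None":
            meta[key] = int(meta[key])
    if meta.get("val_loss", "None") != "None":
        meta["val_loss"] = float(meta["val_loss"])
    return EmbeddingMatrix(genes=list(df.index), values=df.to_numpy(), meta=meta)
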