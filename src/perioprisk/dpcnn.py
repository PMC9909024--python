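"""Deep pyramid CNN (DPCNN) text-feature extractor, implemented in NumPy.

Architecture (word level): a region-embedding convolution over
``region_size``-token windows, followed by ``n_blocks`` repetitions of
{max-pool window 3 stride 2  ->  pre-activation residual pair of width-3
convolutions}, a final global max pool that collapses any document to one
``n_feature_maps`` vector, and a linear classification head. The stride-2
pooling halves the internal sequence length at every block — the "pyramid" —
so cost stays linear in document length while the receptive field doubles.

The network is trained with Adam on binary cross-entropy; forward and
backward passes are hand-written vectorised NumPy (single CPU, bit
reproducible for a fixed seed). The pre-head pooled vector is the text
feature handed to downstream classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import clean_text
from .text import EmbeddingMatrix, Vocabulary

logger = logging.getLogger(__name__)


def pooled_length(length: int, window: int = 3, stride: int = 2) -> int:
    """Sequence length after one valid max-pool: floor((L - window)/stride) + 1."""
    if length < window:
        return 1
    return (length - window) // stride + 1


@dataclass(frozen=True)
class DpcnnConfig:
    """Hyperparameters of the pyramid text network.

    ``pool_stride`` is fixed at 2 (the defining down-sampling rate);
    ``n_blocks`` must leave the internal sequence length >= 1 after all
    poolings of a ``max_doc_len`` input.
    """

    n_feature_maps: int = 250
    region_size: int = 3
    n_blocks: int = 2
    pool_window: int = 3
    pool_stride: int = 2
    max_doc_len: int = 128
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 15
    batch_size: int = 32
    patience: int = 3
    fine_tune_embeddings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_stride != 2:
            raise ValueError("pool_stride is fixed at 2 in the pyramid design")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        # strict recurrence (no short-input clamp): every pooling must see >= 1 token
        L = self.max_doc_len
        for _ in range(self.n_blocks):
            L = (L - self.pool_window) // self.pool_stride + 1
            if L < 1:
                raise ValueError(
                    f"n_blocks={self.n_blocks} collapses a {self.max_doc_len}-token "
                    "document below length 1"
                )

    def internal_lengths(self, length: int | None = None) -> list[int]:
        """Predicted sequence length after each block's pooling."""
        L = self.max_doc_len if length is None else length
        lengths = []
        for _ in range(self.n_blocks):
            L = pooled_length(L, self.pool_window, self.pool_stride)
            lengths.append(L)
        return lengths


# ---------------------------------------------------------------------------
# layer primitives (forward returns a cache for the matching backward)
# ---------------------------------------------------------------------------


def _conv_same(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
    """Width-k convolution with same-length zero padding. x: (B, L, F_in)."""
    B, L, Fi = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
    idx = np.arange(L)[:, None] + np.arange(k)[None, :]
    cols = xp[:, idx, :].reshape(B, L, k * Fi)
    out = cols @ W + b
    return out, (cols, xp.shape, idx, x.shape, W)


def _conv_same_backward(dY: np.ndarray, cache, k: int):
    cols, xp_shape, idx, x_shape, W = cache
    B, L, Fi = x_shape
    dW = cols.reshape(-1, k * Fi).T @ dY.reshape(-1, dY.shape[-1])
    db = dY.sum(axis=(0, 1))
    dcols = (dY @ W.T).reshape(B, L, k, Fi)
    dxp = np.zeros(xp_shape)
    np.add.at(dxp, (slice(None), idx, slice(None)), dcols)
    pad = (k - 1) // 2
    dx = dxp[:, pad : pad + L, :]
    return dx, dW, db


def _maxpool(x: np.ndarray, window: int, stride: int):
    """Valid max-pool along the length axis; short inputs pool globally."""
    B, L, F = x.shape
    if L < window:
        arg = x.argmax(axis=1)  # (B, F)
        out = x.max(axis=1, keepdims=True)
        return out, ("global", arg, x.shape)
    out_len = (L - window) // stride + 1
    starts = np.arange(out_len) * stride
    idx = starts[:, None] + np.arange(window)[None, :]
    windows = x[:, idx, :]  # (B, out_len, window, F)
    arg = windows.argmax(axis=2)  # (B, out_len, F)
    out = windows.max(axis=2)
    return out, ("strided", arg, x.shape, starts)


def _maxpool_backward(dY: np.ndarray, cache):
    kind = cache[0]
    dx = np.zeros(cache[2])
    if kind == "global":
        _, arg, shape = cache
        B, _, F = shape
        bi = np.arange(B)[:, None]
        fi = np.arange(F)[None, :]
        np.add.at(dx, (bi, arg, fi), dY[:, 0, :])
        return dx
    _, arg, shape, starts = cache
    B, _, F = shape
    out_len = arg.shape[1]
    bi = np.arange(B)[:, None, None]
    fi = np.arange(F)[None, None, :]
    pos = starts[None, :, None] + arg  # (B, out_len, F)
    np.add.at(dx, (bi, pos, fi), dY)
    return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


@dataclass
class TextFeatureModel:
    """Vocabulary + embeddings + trained pyramid-CNN feature extractor.

    ``extract`` yields an ``n_feature_maps``-long vector for any document
    length; the classification head is only used during training.
    """

    vocabulary: Vocabulary
    config: DpcnnConfig
    params: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return self.config.n_feature_maps

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, return_internals: bool = False):
        """Forward pass on a (B, max_doc_len) index batch.

        Returns ``(features, logits)`` — features are the pre-head pooled
        vectors — plus, optionally, the list of internal sequence lengths
        observed after each block's pooling.
        """
        cfg = self.config
        p = self.params
        caches: dict = {}
        E = p["emb"][X]  # (B, L, D)
        caches["X"] = X
        x, caches["region"] = _conv_same(E, p["region_W"], p["region_b"], cfg.region_size)
        lengths = []
        block_caches = []
        for b in range(cfg.n_blocks):
            x, pool_cache = _maxpool(x, cfg.pool_window, cfg.pool_stride)
            lengths.append(x.shape[1])
            a1 = np.maximum(x, 0.0)
            c1, cc1 = _conv_same(a1, p[f"b{b}_W1"], p[f"b{b}_b1"], 3)
            a2 = np.maximum(c1, 0.0)
            c2, cc2 = _conv_same(a2, p[f"b{b}_W2"], p[f"b{b}_b2"], 3)
            block_caches.append((pool_cache, x, a1, cc1, c1, a2, cc2))
            x = x + c2
        feat = x.max(axis=1)  # (B, F) global max pool
        caches["gmax_arg"] = x.argmax(axis=1)
        caches["gmax_shape"] = x.shape
        caches["blocks"] = block_caches
        logits = feat @ p["head_w"] + p["head_b"][0]
        caches["feat"] = feat
        self._caches = caches
        if return_internals:
            return feat, logits, lengths
        return feat, logits

    def _backward(self, dlogits: np.ndarray, drop_mask: np.ndarray | None):
        cfg = self.config
        p = self.params
        c = self._caches
        grads: dict[str, np.ndarray] = {}
        feat = c["feat"]
        f_used = feat if drop_mask is None else feat * drop_mask
        grads["head_w"] = f_used.T @ dlogits
        grads["head_b"] = np.array([dlogits.sum()])
        dfeat = np.outer(dlogits, p["head_w"])
        if drop_mask is not None:
            dfeat = dfeat * drop_mask
        B, L_last, F = c["gmax_shape"]
        dx = np.zeros((B, L_last, F))
        bi = np.arange(B)[:, None]
        fi = np.arange(F)[None, :]
        np.add.at(dx, (bi, c["gmax_arg"], fi), dfeat)
        for b in reversed(range(cfg.n_blocks)):
            pool_cache, x_in, a1, cc1, c1, a2, cc2 = c["blocks"][b]
            dc2 = dx  # residual: dx flows to both branch and skip
            da2, dW2, db2 = _conv_same_backward(dc2, cc2, 3)
            grads[f"b{b}_W2"] = dW2
            grads[f"b{b}_b2"] = db2
            dc1 = da2 * (c1 > 0)
            da1, dW1, db1 = _conv_same_backward(dc1, cc1, 3)
            grads[f"b{b}_W1"] = dW1
            grads[f"b{b}_b1"] = db1
            dx_pooled = dx + da1 * (x_in > 0)
            dx = _maxpool_backward(dx_pooled, pool_cache)
        dE, dWr, dbr = _conv_same_backward(dx, c["region"], cfg.region_size)
        grads["region_W"] = dWr
        grads["region_b"] = dbr
        if cfg.fine_tune_embeddings:
            demb = np.zeros_like(p["emb"])
            np.add.at(demb, c["X"], dE)
            demb[0] = 0.0  # padding row frozen
            grads["emb"] = demb
        return grads

    # -- inference ----------------------------------------------------------

    def extract(self, docs: list[list[str]], batch_size: int = 256) -> np.ndarray:
        """Feature matrix (n_docs, n_feature_maps); empty documents -> zero rows."""
        n = len(docs)
        out = np.zeros((n, self.feature_dim))
        nonempty = [i for i, d in enumerate(docs) if d]
        if len(nonempty) < n:
            logger.warning("%d document(s) empty; emitting zero feature rows", n - len(nonempty))
        X = np.stack(
            [self.vocabulary.encode(docs[i], self.config.max_doc_len) for i in nonempty]
        ) if nonempty else np.zeros((0, self.config.max_doc_len), dtype=np.int64)
        for s in range(0, len(nonempty), batch_size):
            feat, _ = self.forward(X[s : s + batch_size])
            out[nonempty[s : s + batch_size]] = feat
        return out


def _init_params(
    vocab: Vocabulary, embeddings: EmbeddingMatrix, config: DpcnnConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    D = embeddings.dim
    F = config.n_feature_maps
    k = config.region_size

    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    params = {
        "emb": embeddings.matrix.copy(),
        "region_W": he(k * D, (k * D, F)),
        "region_b": np.zeros(F),
        "head_w": np.zeros(F),
        "head_b": np.zeros(1),
    }
    for b in range(config.n_blocks):
        params[f"b{b}_W1"] = he(3 * F, (3 * F, F))
        params[f"b{b}_b1"] = np.zeros(F)
        params[f"b{b}_W2"] = he(3 * F, (3 * F, F))
        params[f"b{b}_b2"] = np.zeros(F)
    return params


def dpcnn_forward(doc: np.ndarray, model: TextFeatureModel):
    """Convenience single-document forward: returns (feature vector, class score)."""
    X = np.asarray(doc, dtype=np.int64).reshape(1, -1)
    feat, logits = model.forward(X)
    return feat[0], float(logits[0])


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = np.clip(logits, -30, 30)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))
    dlogits = (p - y) / len(y)
    return float(loss), dlogits


def train_dpcnn(
    train_docs: list[list[str]],
    train_labels,
    val_docs: list[list[str]],
    val_labels,
    vocabulary: Vocabulary,
    embeddings: EmbeddingMatrix,
    config: DpcnnConfig,
) -> TextFeatureModel:
    """Train the pyramid network with Adam + early stopping on validation loss.

    Returns the best-validation checkpoint; per-epoch train/validation losses
    are kept on ``model.history``. Deterministic for a fixed config seed.
    """
    y_tr = np.asarray(train_labels, dtype=float)
    y_va = np.asarray(val_labels, dtype=float)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(config.seed)
    params = _init_params(vocabulary, embeddings, config, rng)
    model = TextFeatureModel(vocabulary=vocabulary, config=config, params=params)

    X_tr = np.stack([vocabulary.encode(d, config.max_doc_len) for d in train_docs])
    X_va = np.stack([vocabulary.encode(d, config.max_doc_len) for d in val_docs])

    opt = _Adam(params, config.lr)
    best_loss, best_params, since_best = np.inf, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_tr))
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            feat, logits = model.forward(X_tr[idx])
            drop_mask = None
            if config.dropout > 0:
                drop_mask = (rng.random(feat.shape) >= config.dropout) / (1 - config.dropout)
                logits = (feat * drop_mask) @ params["head_w"] + params["head_b"][0]
            loss, dlogits = _bce_with_logits(logits, y_tr[idx])
            grads = model._backward(dlogits, drop_mask)
            opt.step(params, grads)
            params["emb"][0] = 0.0
            epoch_loss += loss
            n_batches += 1

        val_loss = 0.0
        for s in range(0, len(X_va), 256):
            _, logits = model.forward(X_va[s : s + 256])
            l, _ = _bce_with_logits(logits, y_va[s : s + 256])
            val_loss += l * len(logits)
        val_loss /= len(X_va)
        model.history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_loss": val_loss}
        )
        if val_loss < best_loss - 1e-6:
            best_loss, since_best = val_loss, 0
            best_params = {k: v.copy() for k, v in params.items()}
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def extract_text_features(cohort, model: TextFeatureModel) -> pd.DataFrame:
    """Patients x n_feature_maps text-feature matrix, rows in cohort order.

    Each patient's documents are concatenated in fixed order (chief complaint,
    preoperative diagnosis, examination conclusions), cleaned and tokenised;
    patients with no text at all get a zero row.
    """
    docs = [clean_text(rec.document_text()) for rec in cohort.records]
    feats = model.extract(docs)
    cols = [f"text__f{i}" for i in range(model.feature_dim)]
    return pd.DataFrame(feats, index=[r.patient_id for r in cohort.records], columns=cols)


def cohort_corpus(cohort) -> list[list[str]]:
    """Tokenised concatenated documents of every record (vocabulary/embedding corpus)."""
    return [clean_text(rec.document_text()) for rec in cohort.records]
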