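"""Skip-gram word-vector trainer with negative sampling (SGNS), in NumPy.

Single-threaded and fully seeded, so training is bit-reproducible. Scale
target is a clinical corpus of a few thousand short documents; minibatched
vector arithmetic keeps that in the seconds range on one CPU.
"""

from __future__ import annotations

import numpy as np

from .text import EmbeddingMatrix, Vocabulary


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _apply_averaged(W: np.ndarray, idx: np.ndarray, grads: np.ndarray, lr: float) -> None:
    """W[idx] -= lr * per-row mean of grads (rows may repeat within idx)."""
    acc = np.zeros_like(W)
    np.add.at(acc, idx, grads)
    counts = np.bincount(idx, minlength=W.shape[0])
    active = counts > 0
    W[active] -= lr * acc[active] / counts[active, None]


def _skipgram_pairs(sequences: list[np.ndarray], window: int, rng: np.random.Generator):
    """(center, context) index pairs with the usual dynamic window shrinkage."""
    centers, contexts = [], []
    for seq in sequences:
        n = len(seq)
        if n < 2:
            continue
        spans = rng.integers(1, window + 1, size=n)
        for i in range(n):
            b = spans[i]
            lo, hi = max(0, i - b), min(n, i + b + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(seq[i])
                    contexts.append(seq[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_word_vectors(
    corpus: list[list[str]],
    vocabulary: Vocabulary,
    dim: int = 32,
    window: int = 5,
    epochs: int = 3,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.025,
    batch_size: int = 2048,
) -> EmbeddingMatrix:
    """Train skip-gram embeddings with ``negative`` sampled contrasts per pair.

    Negatives are drawn from the unigram distribution raised to 3/4. The
    padding row (index 0) stays zero; tokens never seen in the corpus keep
    their small random initialisation. Deterministic for a fixed seed.
    """
    if dim <= 0:
        raise ValueError("embedding dim must be positive")
    rng = np.random.default_rng(seed)
    V = vocabulary.size
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))
    w_in[vocabulary.pad_index] = 0.0

    sequences = [vocabulary.encode(doc) for doc in corpus]
    sequences = [s[s != vocabulary.pad_index] for s in sequences]

    counts = np.zeros(V)
    for s in sequences:
        np.add.at(counts, s, 1.0)
    counts[vocabulary.pad_index] = 0.0
    noise = counts**0.75
    total = noise.sum()
    if total == 0:
        raise ValueError("corpus has no in-vocabulary tokens")
    noise /= total

    seen = counts > 0
    for _ in range(epochs):
        centers, contexts = _skipgram_pairs(sequences, window, rng)
        if centers.size == 0:
            break
        order = rng.permutation(centers.size)
        centers, contexts = centers[order], contexts[order]
        for start in range(0, centers.size, batch_size):
            c_idx = centers[start : start + batch_size]
            o_idx = contexts[start : start + batch_size]
            B = c_idx.size
            neg_idx = rng.choice(V, size=(B, negative), p=noise)

            c = w_in[c_idx]  # (B, D)
            o = w_out[o_idx]  # (B, D)
            o_neg = w_out[neg_idx]  # (B, K, D)

            g_pos = _sigmoid(np.einsum("bd,bd->b", c, o)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", c, o_neg))  # (B, K)

            dc = g_pos[:, None] * o + np.einsum("bk,bkd->bd", g_neg, o_neg)
            do = g_pos[:, None] * c
            dneg = g_neg[:, :, None] * c[:, None, :]

            # rows hit several times in a batch take the *average* of their
            # pair gradients: a plain sum scales the step by the occurrence
            # count and diverges on small vocabularies
            _apply_averaged(w_in, c_idx, dc, lr)
            out_idx = np.concatenate([o_idx, neg_idx.ravel()])
            out_grad = np.concatenate([do, dneg.reshape(-1, dim)])
            _apply_averaged(w_out, out_idx, out_grad, lr)
            w_in[vocabulary.pad_index] = 0.0

    # guarantee nonzero rows for every seen token (degenerate corpora aside)
    zero_rows = seen & (np.linalg.norm(w_in, axis=1) == 0.0)
    if zero_rows.any():  # pragma: no cover - defensive
        w_in[zero_rows] = (rng.random((int(zero_rows.sum()), dim)) - 0.5) / dim
    return EmbeddingMatrix(w_in)
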