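"""Vocabulary building and token encoding for the clinical-text branch."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


@dataclass
class Vocabulary:
    """Dense token -> index map with fixed special indices (pad=0, unk=1)."""

    token_to_index: dict[str, int]
    index_to_token: list[str] = field(default_factory=list)

    pad_index: int = 0
    unk_index: int = 1

    def __post_init__(self) -> None:
        if not self.index_to_token:
            self.index_to_token = [""] * len(self.token_to_index)
            for t, i in self.token_to_index.items():
                self.index_to_token[i] = t
        assert self.token_to_index[PAD_TOKEN] == self.pad_index

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def __len__(self) -> int:
        return self.size

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def encode(self, tokens: list[str], max_len: int | None = None) -> np.ndarray:
        """Map tokens to indices (unknowns -> unk); pad/truncate to ``max_len``."""
        ids = [self.token_to_index.get(t, self.unk_index) for t in tokens]
        if max_len is not None:
            ids = ids[:max_len] + [self.pad_index] * max(0, max_len - len(ids))
        return np.asarray(ids, dtype=np.int64)


def build_vocabulary(corpus: list[list[str]], min_count: int = 1) -> Vocabulary:
    """Build a vocabulary from a tokenised corpus.

    Tokens seen at least ``min_count`` times get dense indices starting at 2
    (0 = padding, 1 = unknown), ordered by descending frequency then
    lexicographically — the assignment is deterministic.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts = Counter(tok for doc in corpus for tok in doc)
    kept = sorted((t for t, c in counts.items() if c >= min_count), key=lambda t: (-counts[t], t))
    mapping = {PAD_TOKEN: 0, UNK_TOKEN: 1}
    for i, tok in enumerate(kept, start=2):
        mapping[tok] = i
    return Vocabulary(mapping)


@dataclass
class EmbeddingMatrix:
    """size x dim word-vector matrix; row 0 (padding) is all zeros and frozen."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.matrix[0] = 0.0

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def size(self) -> int:
        return self.matrix.shape[0]
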