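"""Feature-level fusion of the three modality blocks.

Two modes:

* ``concat`` (default) — column-wise concatenation in fixed modality order
  (text, tabular, monitoring) with a provenance map recording each segment's
  (modality, offset, width). This is what the single-modality experiment
  groups need, since a learned joint layer cannot run with modalities absent.
* ``learned`` — a single fully-connected layer (concat width -> fused_dim,
  ReLU) trained with a temporary logistic head on the training partition;
  the head is discarded and the layer's activations become the multimodal
  features for every partition. Missing tabular cells are filled with -1
  before entering the dense layer (a dense layer cannot route NaN the way a
  tree can).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITY_ORDER = ("text", "tabular", "monitoring")


@dataclass(frozen=True)
class FusionConfig:
    mode: str = "concat"  # {"concat", "learned"}
    fused_dim: int = 64
    # full-batch gradient descent: small steps, many epochs (the layer is tiny)
    lr: float = 0.05
    epochs: int = 500
    seed: int = 0
    mask: tuple[str, ...] = MODALITY_ORDER

    def __post_init__(self) -> None:
        if self.mode not in ("concat", "learned"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if not self.mask:
            raise ValueError("modality mask must be nonempty")
        unknown = set(self.mask) - set(MODALITY_ORDER)
        if unknown:
            raise ValueError(f"unknown modalities in mask: {sorted(unknown)}")
        if self.mode == "learned" and self.fused_dim < 1:
            raise ValueError("learned fusion requires fused_dim >= 1")


@dataclass
class FusedMatrix:
    """Fused feature matrix plus per-segment provenance.

    ``provenance`` maps modality -> (offset, width); offsets tile the columns
    exactly in concat mode.
    """

    values: pd.DataFrame
    provenance: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def segment(self, modality: str) -> pd.DataFrame:
        off, w = self.provenance[modality]
        return self.values.iloc[:, off : off + w]


def fuse_concat(
    text: pd.DataFrame | None,
    tabular: pd.DataFrame | None,
    monitoring: pd.DataFrame | None,
    mask: tuple[str, ...] = MODALITY_ORDER,
) -> FusedMatrix:
    """Concatenate masked modality blocks column-wise in fixed order."""
    blocks = {"text": text, "tabular": tabular, "monitoring": monitoring}
    chosen = [(m, blocks[m]) for m in MODALITY_ORDER if m in mask]
    missing = [m for m, b in chosen if b is None]
    if missing:
        raise ValueError(f"masked modality without a feature block: {missing}")
    lengths = {len(b) for _, b in chosen}
    if len(lengths) > 1:
        raise ValueError(f"modality blocks are not row-aligned: lengths {sorted(lengths)}")
    provenance: dict[str, tuple[int, int]] = {}
    offset = 0
    parts = []
    for m, b in chosen:
        provenance[m] = (offset, b.shape[1])
        offset += b.shape[1]
        parts.append(b.reset_index(drop=True))
    values = pd.concat(parts, axis=1)
    values.index = chosen[0][1].index
    return FusedMatrix(values=values, provenance=provenance)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@dataclass
class LearnedFusion:
    """Weights of the supervised fully-connected fusion layer."""

    W: np.ndarray  # (concat_width, fused_dim)
    b: np.ndarray  # (fused_dim,)
    columns: list[str]

    def transform(self, concat: FusedMatrix) -> FusedMatrix:
        X = np.nan_to_num(concat.values.to_numpy(dtype=float), nan=-1.0)
        H = np.maximum(X @ self.W + self.b, 0.0)
        cols = [f"fused__f{i}" for i in range(self.W.shape[1])]
        out = pd.DataFrame(H, index=concat.values.index, columns=cols)
        return FusedMatrix(values=out, provenance={"fused": (0, self.W.shape[1])})


def fuse_learned(
    train: FusedMatrix,
    train_labels,
    config: FusionConfig,
    others: dict[str, FusedMatrix] | None = None,
) -> tuple[LearnedFusion, FusedMatrix, dict[str, FusedMatrix]]:
    """Train the fusion layer on the training partition, apply it everywhere.

    With ``epochs == 0`` and ``fused_dim`` equal to the concatenated width the
    layer is initialised to the identity, so outputs equal the ReLU-activated
    inputs (a useful sanity anchor). The temporary logistic head used to
    supervise the layer is discarded.
    """
    import logging

    logger = logging.getLogger(__name__)
    y = np.asarray(train_labels, dtype=float)
    X = np.nan_to_num(train.values.to_numpy(dtype=float), nan=-1.0)
    n, width = X.shape
    if config.fused_dim >= width:
        logger.warning("fused_dim %d >= concatenated width %d: no compression", config.fused_dim, width)
    rng = np.random.default_rng(config.seed)
    if config.fused_dim == width:
        W = np.eye(width)
    else:
        W = rng.normal(0.0, np.sqrt(2.0 / width), size=(width, config.fused_dim))
    b = np.zeros(config.fused_dim)
    w_head = np.zeros(config.fused_dim)
    b_head = 0.0

    for _ in range(config.epochs):
        H = np.maximum(X @ W + b, 0.0)
        p = _sigmoid(H @ w_head + b_head)
        dlogit = (p - y) / n
        dH = np.outer(dlogit, w_head) * (H > 0)
        gW = X.T @ dH
        gb = dH.sum(axis=0)
        gw_head = H.T @ dlogit
        gb_head = dlogit.sum()
        W -= config.lr * gW
        b -= config.lr * gb
        w_head -= config.lr * gw_head
        b_head -= config.lr * gb_head

    layer = LearnedFusion(W=W, b=b, columns=list(train.values.columns))
    fused_train = layer.transform(train)
    fused_others = {name: layer.transform(m) for name, m in (others or {}).items()}
    return layer, fused_train, fused_others
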