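"""Tree-based feature selection (TBFS) for the preoperative tabular block.

A gradient-boosted tree ensemble is fitted to the (missing-value-laden)
numeric block and attributes are ranked by normalized gain importance; the
retained subset size k is chosen on the validation partition with a parsimony
rule: the smallest k whose validation ROC-AUC is within a small tolerance of
the best candidate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

#: booster settings for the ranking/selection fits: shallow trees, many rounds
RANKER_PARAMS = dict(
    max_depth=4,
    n_estimators=200,
    learning_rate=0.3,
    tree_method="hist",
    n_jobs=1,
    eval_metric="logloss",
)

#: validation-AUC slack of the parsimony rule for choosing k
PARSIMONY_TOL = 0.005


@dataclass(frozen=True)
class ImportanceRanking:
    """Attributes ordered by normalized gain importance (non-increasing).

    Scores sum to 1; ties break by attribute name. ``method`` records the
    importance type used (gain by default; weight/cover selectable).
    """

    ordering: tuple[tuple[str, float], ...]
    method: str = "gain"
    seed: int = 0

    @property
    def attributes(self) -> list[str]:
        return [a for a, _ in self.ordering]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.ordering])

    def top(self, k: int) -> list[str]:
        return self.attributes[:k]


@dataclass
class SelectionResult:
    """Chosen attribute subset plus the validation-AUC curve over candidate k."""

    selected: list[str]
    k: int
    curve: dict[int, float] = field(default_factory=dict)
    ranking: ImportanceRanking | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": self.selected,
                "k": self.k,
                "curve": {str(k): v for k, v in self.curve.items()},
                "ranking": list(self.ranking.ordering) if self.ranking else None,
                "method": self.ranking.method if self.ranking else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        obj = json.loads(text)
        ranking = None
        if obj.get("ranking") is not None:
            ranking = ImportanceRanking(
                tuple((a, float(s)) for a, s in obj["ranking"]), method=obj.get("method", "gain")
            )
        return cls(
            selected=list(obj["selected"]),
            k=int(obj["k"]),
            curve={int(k): float(v) for k, v in obj["curve"].items()},
            ranking=ranking,
        )


def _ranker(seed: int) -> XGBClassifier:
    return XGBClassifier(random_state=seed, **RANKER_PARAMS)


def rank_features(
    train: pd.DataFrame, labels, seed: int = 0, method: str = "gain"
) -> ImportanceRanking:
    """Rank tabular attributes by boosted-tree importance on the training data.

    Missing values pass to the booster natively (NaN). Importances are
    normalized to sum to 1; attributes the booster never split on (including
    constants) score exactly 0. Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("rank_features requires both classes in the labels")
    model = _ranker(seed)
    model.fit(train.to_numpy(dtype=float), y)
    booster = model.get_booster()
    booster.feature_names = list(train.columns)
    raw = booster.get_score(importance_type=method)
    scores = np.array([raw.get(c, 0.0) for c in train.columns], dtype=float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    else:  # no split anywhere (degenerate); fall back to uniform
        scores = np.full(len(scores), 1.0 / len(scores))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], train.columns[i]))
    ordering = tuple((train.columns[i], float(scores[i])) for i in order)
    return ImportanceRanking(ordering, method=method, seed=seed)


def select_k(
    ranking: ImportanceRanking,
    train: pd.DataFrame,
    train_labels,
    val: pd.DataFrame,
    val_labels,
    candidate_ks: list[int],
    seed: int = 0,
) -> SelectionResult:
    """Refit on each top-k subset, score validation ROC-AUC, pick the smallest
    k within ``PARSIMONY_TOL`` of the best score."""
    if not candidate_ks:
        raise ValueError("candidate_ks must be nonempty")
    n_attrs = len(ranking.ordering)
    if any(k > n_attrs or k < 1 for k in candidate_ks):
        raise ValueError(f"candidate ks must lie in [1, {n_attrs}]")
    y_tr = np.asarray(train_labels)
    y_va = np.asarray(val_labels)
    curve: dict[int, float] = {}
    for k in sorted(set(candidate_ks)):
        cols = ranking.top(k)
        model = _ranker(seed)
        model.fit(train[cols].to_numpy(dtype=float), y_tr)
        scores = model.predict_proba(val[cols].to_numpy(dtype=float))[:, 1]
        curve[k] = float(roc_auc_score(y_va, scores))
    best = max(curve.values())
    chosen = min(k for k, v in curve.items() if v >= best - PARSIMONY_TOL)
    return SelectionResult(selected=ranking.top(chosen), k=chosen, curve=curve, ranking=ranking)


def transform(tabular: pd.DataFrame, selection: SelectionResult) -> pd.DataFrame:
    """Column subset in ranking order; missing values preserved."""
    missing = [c for c in selection.selected if c not in tabular.columns]
    if missing:
        raise KeyError(f"selection refers to columns absent from the tabular block: {missing}")
    return tabular[selection.selected]
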