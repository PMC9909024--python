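"""Experiment harness: the four modality groups, six classifiers, metric panel.

Groups follow the standard multimodal ablation design:

* G1 — preoperative tabular block only (tree-based feature selection),
* G2 — intraoperative monitoring only (DSM duration + moment features),
* G3 — clinical text only (pyramid-CNN features),
* G4 — all three modalities fused.

Discipline: every fitted component (normalization statistics, feature
ranking, vocabulary, word vectors, the text network, the fusion layer) is
estimated on the training partition, model selection uses the validation
partition, and the test partition is scored exactly once per experiment and
classifier — a second evaluation raises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import CLASSIFIER_KINDS, ClassifierSpec, fit_classifier, panel_from_scores
from .cohort import (
    Cohort,
    SplitSpec,
    fit_normalization,
    normalize_frame,
    select_top_monitoring_attributes,
    split_cohort,
)
from .dpcnn import DpcnnConfig, cohort_corpus, extract_text_features, train_dpcnn
from .dsm import RangeCatalogue, extract_dsm_features
from .fusion import FusedMatrix, FusionConfig, fuse_concat, fuse_learned
from .tbfs import rank_features, select_k, transform
from .text import build_vocabulary
from .word2vec import train_word_vectors

logger = logging.getLogger(__name__)

GROUPS = ("G1", "G2", "G3", "G4")

GROUP_MODALITIES: dict[str, tuple[str, ...]] = {
    "G1": ("tabular",),
    "G2": ("monitoring",),
    "G3": ("text",),
    "G4": ("text", "tabular", "monitoring"),
}

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class ExperimentGroup:
    """One ablation group and its modality recipe."""

    id: str

    def __post_init__(self) -> None:
        if self.id not in GROUPS:
            raise ValueError(f"unknown group {self.id!r}; choose from {GROUPS}")

    @property
    def modalities(self) -> tuple[str, ...]:
        return GROUP_MODALITIES[self.id]


@dataclass(frozen=True)
class PipelineConfig:
    """Scaled desk-size defaults for the end-to-end pipeline.

    The text network and embedding sizes here are deliberately small (32
    feature maps, 32-dim vectors) so a full multimodal experiment on a
    thousand-patient cohort runs in well under a minute per seed on one CPU;
    every knob is forwarded from the module configs and can be raised.
    """

    n_monitoring: int = 6
    candidate_ks: tuple[int, ...] = (10, 25, 50)
    embedding_dim: int = 32
    w2v_window: int = 5
    w2v_epochs: int = 3
    vocab_min_count: int = 1
    dpcnn: DpcnnConfig = field(
        default_factory=lambda: DpcnnConfig(
            n_feature_maps=32,
            n_blocks=2,
            max_doc_len=64,
            dropout=0.1,
            lr=2e-3,
            epochs=8,
            batch_size=64,
            patience=3,
        )
    )
    fusion: FusionConfig = field(default_factory=FusionConfig)
    sampling_interval: float | None = None  # None = gap-weighted durations


class PartitionReuseError(RuntimeError):
    """Raised when an experiment tries to score the test partition twice."""


@dataclass
class ModalityFeatures:
    """Per-partition, per-modality feature blocks with single-touch test guard."""

    features: dict[str, dict[str, pd.DataFrame]]  # modality -> partition -> frame
    labels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    _test_consumed: set = field(default_factory=set)

    def block(self, modality: str, partition: str) -> pd.DataFrame:
        return self.features[modality][partition]

    def assemble(self, group: ExperimentGroup, partition: str) -> FusedMatrix:
        mods = group.modalities
        return fuse_concat(
            self.features.get("text", {}).get(partition) if "text" in mods else None,
            self.features.get("tabular", {}).get(partition) if "tabular" in mods else None,
            self.features.get("monitoring", {}).get(partition) if "monitoring" in mods else None,
            mask=mods,
        )

    def consume_test(self, tag) -> None:
        if tag in self._test_consumed:
            raise PartitionReuseError(f"test partition already scored for {tag}")
        self._test_consumed.add(tag)


def compute_modality_features(
    cohort: Cohort,
    split: SplitSpec,
    config: PipelineConfig | None = None,
    modalities: tuple[str, ...] = ("text", "tabular", "monitoring"),
) -> ModalityFeatures:
    """Split the cohort and compute each requested modality's feature blocks.

    All estimation happens on the training partition; validation is used only
    for model selection (retained-k, early stopping).
    """
    config = config or PipelineConfig()
    train, val, test = split_cohort(cohort, split)
    parts = {"train": train, "val": val, "test": test}
    labels = {p: c.labels for p, c in parts.items()}
    feats: dict[str, dict[str, pd.DataFrame]] = {}
    meta: dict = {"split_seed": split.seed, "n": {p: len(c) for p, c in parts.items()}}

    missing = [m for m in modalities if m not in ("text", "tabular", "monitoring")]
    if missing:
        raise ValueError(f"unknown modalities: {missing}")

    if "tabular" in modalities:
        stats = fit_normalization(train.tabular_frame())
        frames = {p: normalize_frame(c.tabular_frame(), stats) for p, c in parts.items()}
        ranking = rank_features(frames["train"], labels["train"], seed=split.seed)
        width = frames["train"].shape[1]
        ks = sorted({min(k, width) for k in config.candidate_ks})
        selection = select_k(
            ranking, frames["train"], labels["train"], frames["val"], labels["val"], ks,
            seed=split.seed,
        )
        feats["tabular"] = {p: transform(frames[p], selection) for p in PARTITIONS}
        meta["tabular"] = {"k": selection.k, "curve": selection.curve, "selection": selection}

    if "monitoring" in modalities:
        catalogue = RangeCatalogue.default()
        attrs = select_top_monitoring_attributes(train, config.n_monitoring)
        feats["monitoring"] = {
            p: extract_dsm_features(parts[p], catalogue, attrs, config.sampling_interval)
            for p in PARTITIONS
        }
        meta["monitoring"] = {"attributes": attrs}

    if "text" in modalities:
        corpus = cohort_corpus(train)
        vocab = build_vocabulary(corpus, min_count=config.vocab_min_count)
        emb = train_word_vectors(
            corpus,
            vocab,
            dim=config.embedding_dim,
            window=config.w2v_window,
            epochs=config.w2v_epochs,
            seed=split.seed,
        )
        dp_cfg = replace(config.dpcnn, seed=split.seed)
        model = train_dpcnn(
            corpus, labels["train"], cohort_corpus(val), labels["val"], vocab, emb, dp_cfg
        )
        feats["text"] = {p: extract_text_features(parts[p], model) for p in PARTITIONS}
        meta["text"] = {"model": model, "vocab_size": vocab.size, "epochs_ran": len(model.history)}

    return ModalityFeatures(features=feats, labels=labels, meta=meta)


PANEL_COLUMNS = ("Illness", "Group", "Classifier", "P_Accuracy", "N_Accuracy",
                 "Sensitivity", "Specificity", "ROC")


@dataclass
class ExperimentResult:
    """Table shaped like the published per-illness result tables, plus details."""

    table: pd.DataFrame
    group: ExperimentGroup
    details: dict = field(default_factory=dict)


def default_specs(seed: int = 0, kinds=CLASSIFIER_KINDS) -> list[ClassifierSpec]:
    return [ClassifierSpec(kind=k, seed=seed) for k in kinds]


def run_group_experiment(
    cohort: Cohort,
    group: ExperimentGroup | str,
    specs: list[ClassifierSpec] | None = None,
    split: SplitSpec | None = None,
    config: PipelineConfig | None = None,
    features: ModalityFeatures | None = None,
) -> ExperimentResult:
    """Run one ablation group end to end: features -> fit -> single test scoring.

    ``features`` may carry precomputed modality blocks (shared across groups
    of the same seed); otherwise only the group's required modalities are
    computed. Raises if the cohort lacks a required modality.
    """
    if isinstance(group, str):
        group = ExperimentGroup(group)
    split = split or SplitSpec()
    config = config or PipelineConfig()
    specs = specs if specs is not None else default_specs(seed=split.seed)

    _check_modalities_present(cohort, group)
    if features is None:
        features = compute_modality_features(cohort, split, config, group.modalities)

    illness = cohort.records[0].illness if cohort.records else "unknown"
    fused = {p: features.assemble(group, p) for p in PARTITIONS}
    if config.fusion.mode == "learned" and group.id == "G4":
        _, fused_train, fused_rest = fuse_learned(
            fused["train"], features.labels["train"], config.fusion,
            {"val": fused["val"], "test": fused["test"]},
        )
        fused = {"train": fused_train, **fused_rest}

    rows, confusion, test_scores = [], {}, {}
    for spec in specs:
        model = fit_classifier(spec, fused["train"].values, features.labels["train"])
        features.consume_test((group.id, spec.kind, spec.seed))
        scores = model.predict_proba(fused["test"].values)
        test_scores[spec.kind] = scores
        panel = panel_from_scores(scores, features.labels["test"], spec.threshold)
        rows.append(
            {
                "Illness": illness,
                "Group": group.id,
                "Classifier": spec.kind,
                "P_Accuracy": panel.p_accuracy,
                "N_Accuracy": panel.n_accuracy,
                "Sensitivity": panel.sensitivity,
                "Specificity": panel.specificity,
                "ROC": panel.roc_auc,
            }
        )
        confusion[spec.kind] = {"TP": panel.tp, "FP": panel.fp, "TN": panel.tn, "FN": panel.fn}

    table = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    details = {
        "confusion": confusion,
        "seed": split.seed,
        "feature_width": fused["train"].width,
        "n": features.meta.get("n"),
        "provenance": fused["train"].provenance,
        "test_scores": test_scores,
        "test_labels": features.labels["test"],
    }
    return ExperimentResult(table=table, group=group, details=details)


def _check_modalities_present(cohort: Cohort, group: ExperimentGroup) -> None:
    need = group.modalities
    if "tabular" in need and not cohort.schema:
        raise ValueError(f"group {group.id} requires the tabular modality; cohort has none")
    if "monitoring" in need and not any(r.monitoring for r in cohort.records):
        raise ValueError(f"group {group.id} requires monitoring series; cohort has none")
    if "text" in need and not any(any(r.text.values()) for r in cohort.records):
        raise ValueError(f"group {group.id} requires clinical text; cohort has none")


def compare_groups(results: dict[str, pd.DataFrame | ExperimentResult]) -> pd.DataFrame:
    """Per-illness ranking of the ablation groups by test ROC-AUC.

    Accepts one result table per group (possibly with repeated seeds stacked);
    reports median AUC and the seed dispersion (min/max) per group and
    classifier, ranked within illness.
    """
    frames = []
    for gid, res in results.items():
        t = res.table if isinstance(res, ExperimentResult) else res
        frames.append(t.assign(Group=gid))
    allt = pd.concat(frames, ignore_index=True)
    summary = (
        allt.groupby(["Illness", "Group", "Classifier"], as_index=False)
        .agg(ROC_median=("ROC", "median"), ROC_min=("ROC", "min"), ROC_max=("ROC", "max"),
             n_seeds=("ROC", "count"))
    )
    summary["rank"] = summary.groupby(["Illness", "Classifier"])["ROC_median"].rank(
        ascending=False, method="min"
    )
    return summary.sort_values(["Illness", "Classifier", "rank"]).reset_index(drop=True)


def comparison_markdown(summary: pd.DataFrame) -> str:
    """Markdown rendering of the group-comparison summary table."""
    lines = ["| Illness | Classifier | Group | median AUC | min | max | rank |",
             "|---|---|---|---|---|---|---|"]
    for _, r in summary.iterrows():
        lines.append(
            f"| {r.Illness} | {r.Classifier} | {r.Group} | {r.ROC_median:.3f} "
            f"| {r.ROC_min:.3f} | {r.ROC_max:.3f} | {int(r['rank'])} |"
        )
    return "\n".join(lines)
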