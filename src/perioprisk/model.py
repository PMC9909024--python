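"""Model/Results surface over the multimodal risk pipeline.

``RiskModel`` is constructed from a :class:`~perioprisk.cohort.Cohort` (or
the on-disk cohort files) together with an ablation group, classifier
choices, a split protocol and pipeline configuration; ``fit()`` executes the
full pipeline — per-modality feature learning on the training partition,
model selection on validation, a single scoring pass on test — and returns a
:class:`RiskResults` carrying the metric panels, confusion counts and
diagnostics, with ``summary()`` and ROC plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CLASSIFIER_KINDS, ClassifierSpec
from .cohort import Cohort, SplitSpec, read_cohort, read_cohort_dir
from .experiment import (
    ExperimentGroup,
    ExperimentResult,
    PipelineConfig,
    run_group_experiment,
)


@dataclass
class RiskModel:
    """Multimodal perioperative critical-event risk model.

    Parameters
    ----------
    cohort:
        The assembled three-modality cohort.
    group:
        Ablation group id: "G1" (tabular), "G2" (monitoring), "G3" (text) or
        "G4" (all fused; default).
    classifiers:
        Classifier kinds for the head; defaults to all six.
    split:
        Train/validation/test protocol (70/20/10, stratified, seeded).
    config:
        Pipeline sizes (feature maps, embedding dim, candidate k, ...).
    """

    cohort: Cohort
    group: str = "G4"
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    split: SplitSpec = field(default_factory=SplitSpec)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_files(cls, tabular_path, monitoring_path=None, text_path=None, **kwargs) -> "RiskModel":
        return cls(cohort=read_cohort(tabular_path, monitoring_path, text_path), **kwargs)

    @classmethod
    def from_directory(cls, directory, **kwargs) -> "RiskModel":
        return cls(cohort=read_cohort_dir(directory), **kwargs)

    def fit(self, features=None) -> "RiskResults":
        """Run the pipeline end to end and score the test partition once."""
        specs = [ClassifierSpec(kind=k, seed=self.split.seed) for k in self.classifiers]
        result = run_group_experiment(
            self.cohort, self.group, specs, self.split, self.config, features=features
        )
        return RiskResults(model=self, result=result)


@dataclass
class RiskResults:
    """Fitted-pipeline results: metric panels, confusion counts, diagnostics."""

    model: RiskModel
    result: ExperimentResult

    @property
    def table(self) -> pd.DataFrame:
        """Illness x classifier metric panel (PPV, NPV, sensitivity, specificity, AUC)."""
        return self.result.table

    @property
    def confusion(self) -> dict:
        return self.result.details["confusion"]

    def auc(self, classifier: str = "XGBOOST") -> float:
        row = self.table[self.table["Classifier"] == classifier]
        if row.empty:
            raise KeyError(f"classifier {classifier!r} was not fitted")
        return float(row["ROC"].iloc[0])

    def summary(self) -> str:
        d = self.result.details
        n = d.get("n") or {}
        lines = [
            "Perioperative critical-event risk model",
            "=" * 55,
            f"Group:            {self.result.group.id} "
            f"({' + '.join(self.result.group.modalities)})",
            f"Illness task:     {self.table['Illness'].iloc[0]}",
            f"Split (seed {d['seed']}):   "
            f"train {n.get('train', '?')} / val {n.get('val', '?')} / test {n.get('test', '?')}",
            f"Fused width:      {d['feature_width']} "
            f"{dict(d['provenance'])}",
            "-" * 55,
        ]
        show = self.table.drop(columns=["Illness", "Group"]).copy()
        for c in ("P_Accuracy", "N_Accuracy", "Sensitivity", "Specificity", "ROC"):
            show[c] = show[c].map(lambda v: "   n/a" if v is None else f"{v:.3f}")
        lines.append(show.to_string(index=False))
        lines.append("-" * 55)
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Test-partition ROC curves, one per classifier head."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        y = self.result.details["test_labels"]
        for kind, scores in self.result.details["test_scores"].items():
            if len(np.unique(y)) < 2:
                continue
            fpr, tpr, _ = roc_curve(y, scores)
            ax.plot(fpr, tpr, label=f"{kind} (AUC {self.auc(kind):.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - Specificity")
        ax.set_ylabel("Sensitivity")
        ax.set_title(f"{self.result.group.id} test ROC")
        ax.legend(loc="lower right", fontsize=8)
        return ax
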