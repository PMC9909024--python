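"""Experiment harness, Model/Results surface and the command-line interface."""

import numpy as np
import pandas as pd
import pytest

from perioprisk import (
    ClassifierSpec,
    Cohort,
    ExperimentGroup,
    PatientRecord,
    RiskModel,
    SplitSpec,
    compare_groups,
    compute_modality_features,
    run_group_experiment,
)
from perioprisk.experiment import PartitionReuseError, comparison_markdown

SPLIT = SplitSpec(seed=11)


SPLIT2 = SplitSpec(seed=12)


@pytest.fixture(scope="module")
def tiny_features(tiny_cohort, tiny_pipeline_config):
    return compute_modality_features(tiny_cohort, SPLIT, tiny_pipeline_config)


@pytest.fixture(scope="module")
def tiny_features2(tiny_cohort, tiny_pipeline_config):
    return compute_modality_features(tiny_cohort, SPLIT2, tiny_pipeline_config)


def _tabular_only_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    records = [
        PatientRecord(
            patient_id=f"p{i}", label=int(i < n // 4),
            tabular={f"a{j}": float(rng.normal() + (j < 2) * (i < n // 4)) for j in range(6)},
        )
        for i in range(n)
    ]
    return Cohort(records, schema=[f"a{j}" for j in range(6)])


def test_group_recipes_fixed():
    assert ExperimentGroup("G1").modalities == ("tabular",)
    assert ExperimentGroup("G2").modalities == ("monitoring",)
    assert ExperimentGroup("G3").modalities == ("text",)
    assert ExperimentGroup("G4").modalities == ("text", "tabular", "monitoring")
    with pytest.raises(ValueError):
        ExperimentGroup("G5")


def test_missing_modality_raises(tiny_pipeline_config):
    cohort = _tabular_only_cohort()
    res = run_group_experiment(cohort, "G1", [ClassifierSpec("XGBOOST")],
                               SplitSpec(seed=0), tiny_pipeline_config)
    assert len(res.table) == 1
    with pytest.raises(ValueError, match="text"):
        run_group_experiment(cohort, "G3", [ClassifierSpec("XGBOOST")],
                             SplitSpec(seed=0), tiny_pipeline_config)


def test_g4_row_count_matches_specs(tiny_cohort, tiny_pipeline_config, tiny_features):
    specs = [ClassifierSpec(k, seed=11) for k in ("LR", "RF", "XGBOOST")]
    res = run_group_experiment(tiny_cohort, "G4", specs, SPLIT,
                               tiny_pipeline_config, features=tiny_features)
    assert len(res.table) == 3
    assert set(res.table["Classifier"]) == {"LR", "RF", "XGBOOST"}
    assert res.details["feature_width"] == sum(w for _, w in res.details["provenance"].values())


def test_test_partition_scored_exactly_once(tiny_cohort, tiny_pipeline_config, tiny_features):
    spec = [ClassifierSpec("NB", seed=11)]
    run_group_experiment(tiny_cohort, "G1", spec, SPLIT, tiny_pipeline_config,
                         features=tiny_features)
    with pytest.raises(PartitionReuseError):
        run_group_experiment(tiny_cohort, "G1", spec, SPLIT, tiny_pipeline_config,
                             features=tiny_features)


def test_partition_sizes_follow_protocol(tiny_features):
    n = tiny_features.meta["n"]
    total = sum(n.values())
    assert n["train"] == int(0.7 * total)
    assert n["val"] == int(0.2 * total)
    assert n["test"] == total - n["train"] - n["val"]


def test_compare_groups_ties_and_completeness():
    rows = []
    for g in ("G1", "G2"):
        for clf in ("LR", "XGBOOST"):
            rows.append({"Illness": "heart", "Group": g, "Classifier": clf,
                         "P_Accuracy": 1.0, "N_Accuracy": 1.0, "Sensitivity": 1.0,
                         "Specificity": 1.0, "ROC": 0.9})
    t = pd.DataFrame(rows)
    summary = compare_groups({"G1": t[t.Group == "G1"], "G2": t[t.Group == "G2"]})
    assert (summary["rank"] == 1).all()  # identical AUCs tie at rank 1
    assert len(summary) == 4  # every group x classifier cell present
    md = comparison_markdown(summary)
    assert "G1" in md and "XGBOOST" in md


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


def test_riskmodel_fit_summary_and_auc(tiny_cohort, tiny_pipeline_config, tiny_features2):
    model = RiskModel(cohort=tiny_cohort, group="G4", classifiers=("XGBOOST", "LR"),
                      split=SPLIT2, config=tiny_pipeline_config)
    results = model.fit(features=tiny_features2)
    assert isinstance(results.auc("XGBOOST"), float)
    with pytest.raises(KeyError):
        results.auc("RF")
    text = results.summary()
    assert "G4" in text and "XGBOOST" in text and "ROC" in text
    assert str(tiny_features2.meta["n"]["train"]) in text
    assert set(results.confusion) == {"XGBOOST", "LR"}


def test_riskmodel_plot_roc(tiny_cohort, tiny_pipeline_config, tiny_features2):
    import matplotlib

    matplotlib.use("Agg")
    model = RiskModel(cohort=tiny_cohort, group="G1", classifiers=("XGBOOST",),
                      split=SPLIT2, config=tiny_pipeline_config)
    results = model.fit(features=tiny_features2)
    ax = results.plot_roc()
    assert ax.get_legend() is not None


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_synth_then_run(tmp_path):
    import yaml
    from click.testing import CliRunner

    from perioprisk.cli import main

    cfg = {
        "n_positive": 20, "n_control": 60, "n_tabular_attrs": 10,
        "n_informative_tabular": 3, "tabular_effect": 2.0,
        "monitoring_attrs": ["HR"], "series_length_minutes": 10,
        "vocab_size": 20, "doc_length": 6,
    }
    cfg_path = tmp_path / "gen.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    runner = CliRunner()
    out_dir = tmp_path / "cohort"
    r = runner.invoke(main, ["synth", "--config", str(cfg_path), "--seed", "5",
                             "--out", str(out_dir)])
    assert r.exit_code == 0, r.output
    assert (out_dir / "tabular.csv").exists()

    res_dir = tmp_path / "results"
    r = runner.invoke(main, ["run", "--cohort-dir", str(out_dir), "--group", "G1",
                             "--classifiers", "XGBOOST", "--seed", "5",
                             "--out", str(res_dir)])
    assert r.exit_code == 0, r.output
    assert (res_dir / "G1_results.csv").exists()
    table = pd.read_csv(res_dir / "G1_results.csv")
    assert list(table["Classifier"]) == ["XGBOOST"]

    r = runner.invoke(main, ["compare", str(res_dir / "G1_results.csv")])
    assert r.exit_code == 0, r.output
    assert "G1" in r.output
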