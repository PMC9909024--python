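# perioprisk

Multimodal machine-learning prediction of perioperative critical adverse
events (heart, hepatic, renal and respiratory failure) from the three kinds
of data an anesthesiology service actually holds about a surgical patient:

* **preoperative numeric tests and demographics** — a wide tabular block
  (~200 attributes) riddled with missing values,
* **intraoperative monitoring series** — vital signs (HR, SBP, SpO₂, …)
  sampled through the operation,
* **unstructured clinical text** — chief complaint, preoperative diagnosis
  and examination conclusions.

The package is aimed at clinical-ML researchers who want a tested, fully
reproducible implementation of the feature-level fusion pipeline plus a
synthetic cohort generator, since real perioperative cohorts are private.

## The model

Each modality gets its own feature branch; the branches are fused and fed to
a gradient-boosted tree classifier (per-illness binary task, cases vs a
shared control group):

1. **Text branch (DPCNN).** Tokens are embedded with skip-gram/negative-
   sampling word vectors, then a deep pyramid CNN — region-embedding
   convolution, residual two-convolution blocks interleaved with max-pooling
   of window 3 and stride 2, and a final global max pool — compresses any
   document into one fixed-length feature vector. The stride-2 pooling
   halves the internal sequence length per block (hence "pyramid"), so the
   receptive field grows exponentially at linear cost.
2. **Tabular branch (TBFS, tree-based feature selection).** A boosted-tree
   ensemble is fitted to the min-max-normalized tabular block (missing
   values routed natively); attributes are ranked by normalized gain
   importance and the retained subset size k is chosen on the validation
   partition with a parsimony rule.
3. **Monitoring branch (DSM, data statistical method).** Every monitored
   vital sign is summarised by its out-of-normal-range duration in minutes
   (normal intervals per the shipped clinical range catalogue, closed
   bounds) plus seven population moments:

   μ = (1/T) Σᵢ xᵢ,  σ² = (1/T) Σᵢ (xᵢ − μ)²,
   Skewness(X) = (1/T) Σᵢ ((xᵢ − μ)/σ)³,  Kurtosis(X) = (1/T) Σᵢ ((xᵢ − μ)/σ)⁴,

   together with max, min and σ. Note the divisor T (population form) and
   the raw, non-excess kurtosis (≈ 3 for Gaussian data).
4. **Fusion + head.** Feature blocks are concatenated (optionally passed
   through a supervised fully-connected fusion layer) and classified with
   XGBoost; logistic regression, random forest, Gaussian naive Bayes, KNN
   and AdaBoost are available as baselines (missing cells are filled with
   −1 for those, XGBoost handles them natively).

Evaluation follows the imbalanced-cohort panel: P_Accuracy (positive
predictive value), N_Accuracy (negative predictive value), Sensitivity,
Specificity and ROC-AUC, computed on a held-out 10% test partition of a
stratified 70/20/10 split. Four ablation groups are built in: G1 tabular
only, G2 monitoring only, G3 text only, G4 all three fused.

The DPCNN and the word-vector trainer are implemented in pure NumPy
(hand-written forward/backward passes, Adam), so the whole pipeline runs
single-threaded on a CPU and is bit-reproducible for a fixed seed.

## Worked example

```python
from perioprisk import RiskModel, SplitSpec, generate_cohort
from perioprisk.presets import study_generator_config

# synthetic 1,000-patient cohort, ~1:6 imbalance, signal in all modalities
cohort = generate_cohort(study_generator_config(seed=7))
model = RiskModel(cohort=cohort, group="G4", classifiers=("LR", "RF", "XGBOOST"),
                  split=SplitSpec(seed=7))
results = model.fit()
print(results.summary())
```

```
Perioperative critical-event risk model
=======================================================
Group:            G4 (text + tabular + monitoring)
Illness task:     heart
Split (seed 7):   train 700 / val 200 / test 100
Fused width:      105 {'text': (0, 32), 'tabular': (32, 25), 'monitoring': (57, 48)}
-------------------------------------------------------
Classifier P_Accuracy N_Accuracy Sensitivity Specificity   ROC
        LR      1.000      1.000       1.000       1.000 1.000
        RF      1.000      0.977       0.857       1.000 1.000
   XGBOOST      1.000      0.989       0.929       1.000 0.995
-------------------------------------------------------
```

The summary reads: on the 100-patient test partition the fused (G4) model
saw a 105-dimensional feature vector per patient (32 text features, the 25
tabular attributes retained by TBFS, 6 vitals × 8 DSM statistics); the
XGBoost head recovered 92.9% of the critical-event cases with no false
positives, with a test AUC of 0.995. `results.plot_roc()` draws the test ROC
curves; `results.confusion` holds the raw counts.

The same pipeline is scriptable from the shell:

```bash
perioprisk synth --config gen.yaml --seed 7 --out cohort/
perioprisk run --cohort-dir cohort/ --group G4 --seed 7 --out results/
perioprisk compare results/G4_results.csv
```

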