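# Methods

## Task and data model

The package predicts, per patient and per critical illness (heart, hepatic,
renal, respiratory failure), a binary perioperative critical-adverse-event
outcome from three modalities: a preoperative tabular block, intraoperative
monitoring series, and clinical text. Each illness is an independent binary
task against a shared control group; no multiclass head exists. A cohort is
a list of patient records sharing one ordered tabular schema — feature
vectors are order-dependent, so schema order is serialized with the cohort.

## Preprocessing rules

* **Nearest preoperative test.** For each laboratory attribute the most
  recent non-null value dated within 14 days before surgery is used; when
  the nearest record is null the search walks backward chronologically
  inside the window. Anything older is treated as missing. Observations
  dated after surgery are a validation error, never silently dropped.
* **Normalization.** Min-max scaling to the closed interval [0, 1]
  ("interval (0, 1)" is read as informal phrasing, not an open interval).
  Scaling statistics come from the **training partition only** — anything
  else would leak test information — and out-of-range validation/test
  values are clipped to [0, 1] so the stated invariant holds everywhere.
  A constant attribute maps to 0.5 rather than dividing by zero; an
  attribute with no observed training value is dropped with a warning.
* **Text cleaning.** Lowercasing, symbol stripping, whitespace
  tokenization, intra-word hyphens retained ("t-wave" stays one token).
  The synthetic corpus is pre-tokenized, so no language-specific word
  segmentation is needed or implemented.
* **Split.** Stratified 70/20/10 train/validation/test with exact sizes
  (train ⌊0.7n⌋, validation ⌊0.2n⌋, test the remainder); per-class
  allocation uses largest-remainder rounding, so each partition's positive
  count deviates from its ideal share by less than one record. Repeated
  seeded splits (a seed loop) stand in for cross-validation; the explicit
  single split is what the harness reports.
* **Monitoring indicator choice.** Attributes are ranked by patient
  coverage (number of patients with a nonempty series, computed on the
  training partition) and the top n kept; ties break by attribute name.

## Text branch

Word vectors are skip-gram with negative sampling (5 negatives, unigram^3/4
noise distribution, dynamic window), implemented in NumPy, single-threaded
and seeded. One non-obvious numerical choice: when a vocabulary row occurs
several times inside a minibatch, its accumulated gradient is **averaged**,
not summed — summing scales the effective step by the occurrence count and
diverges on small vocabularies.

The pyramid network is: region-embedding convolution (window 3) → n_blocks
× {max-pool window 3 stride 2 → pre-activation residual pair of width-3
convolutions} → global max pool → linear head. Internal length follows
Lₖ = ⌊(Lₖ₋₁ − 3)/2⌋ + 1; a configuration whose blocks would drive the
length below 1 is rejected at construction. Zeroing a block's convolution
weights reduces it exactly to its pooling — the residual identity used as a
structural test. Training is Adam on binary cross-entropy with early
stopping (patience 3) on validation loss, returning the best-validation
checkpoint. Embeddings are fine-tuned by default (freeze flag available);
the padding row is pinned to zero throughout. The pre-head pooled vector is
the text feature; the logistic head exists only to supervise training.
Defaults (250 feature maps, region 3, pool window 3/stride 2) follow the
standard pyramid design; the pipeline preset shrinks them (32 maps, 32-dim
embeddings, 64-token documents) to desk scale. Documents are assembled in
the fixed order chief complaint → preoperative diagnosis → examination
conclusions; one text model is trained per illness task. Patients with no
text get an exact zero feature row.

## Tabular branch (TBFS)

Ranking fit: XGBoost with shallow trees (depth 4), 200 rounds, default
shrinkage, histogram splits, missing values routed natively. Importance
type is gain (weight/cover selectable), normalized to sum to 1; attributes
never split on score exactly 0, ties break by name. Subset size k is chosen
by refitting on each candidate top-k, scoring validation ROC-AUC, and
taking the smallest k within 0.005 of the best (parsimony rule). Selection
never sees the test partition; monotone containment (top-k ⊆ top-(k+1))
holds by construction from the single ranking.

## Monitoring branch (DSM)

Per attribute: out-of-range minutes plus max, min, mean, variance, standard
deviation, skewness, kurtosis, flattened in that fixed order (8 × n_attrs
columns, named `{attr}__{stat}`). Deliberate fidelity choices:

* variance uses divisor **T** (population form), not T−1;
* kurtosis is the **raw** fourth standardized moment (Gaussian ≈ 3), not
  excess;
* σ = 0 (or an exactly constant series — guarded separately because a
  one-ulp rounding of the mean can fake unit skewness) yields
  skewness = kurtosis = 0, so classifiers never see non-finite features;
* standardized deviations are computed before raising to powers, since
  σ⁴ underflows for near-constant series long before z⁴ does.

Durations: each sample is attributed the gap to the next timestamp; the
last sample gets the median gap (a lone sample counts one minute). A
fixed-interval fast path serves regularly sampled series. Normal intervals
are closed — boundary values count as normal. The shipped range catalogue
is data (YAML), 15 vitals; the MAP/MBP upper bound 10,000 is a "no upper
limit" sentinel kept verbatim. Absent series produce an all-zero block with
a separate presence flag (not an extra matrix column).

## Fusion and classification

Concatenation in fixed modality order (text, tabular, monitoring) with a
provenance map is the default: the single-modality ablation groups cannot
pass through a joint learned layer, and tree heads consume the
concatenation directly. The literal learned fusion — one fully-connected
ReLU layer trained with a temporary logistic head on the training
partition, head then discarded — is provided as an option; it trains
full-batch (500 epochs, step 0.05; the layer is tiny) and fills missing
cells with −1 before the dense product. Fusion and the classifier head are
trained sequentially, never jointly; DPCNN weights are frozen once text
features are extracted.

Classifier heads: LR, RF, Gaussian NB, KNN, AdaBoost, XGBoost with pinned
baseline hyperparameters (so runs stay stable as library defaults drift).
XGBoost receives NaN natively; every other kind gets the −1 fill (the
sklearn implementations of NB/KNN/forests reject NaN, and −1 is out of band
after [0, 1] scaling). Decision threshold is 0.5. No resampling or class
weighting by default; a weight flag is available. P_Accuracy/N_Accuracy are
implemented as positive/negative predictive value: in heavily imbalanced
respiratory-failure-like settings a panel of (P_Accuracy 1, low
sensitivity, specificity 1) is consistent with precision under few
predicted positives and inconsistent with a per-class recall reading.
One-class ground truth yields an explicit `None` AUC sentinel. The test
partition is scored exactly once per experiment and classifier; a second
touch raises.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline relies on,
not clinical realism: label imbalance at a multi-year single-centre scale
(defaults 609 cases vs 4,223 controls), per-cell missingness, and
label-dependent signal planted independently per modality — a standardized
mean shift on a subset of tabular attributes; contiguous out-of-range
excursion blocks in positive patients' vitals (contiguous rather than
i.i.d. spikes, so duration features carry signal the moments alone do not);
and a signal-token vocabulary, disjoint from the noise vocabulary, mixed
into positive documents at a controllable rate. One master seed drives
three independent sub-streams, so any modality can be nulled without
perturbing the others. In-range vitals follow a bounded random walk inside
the normal interval; for the two sentinel-bounded attributes (MAP/MBP)
in-range draws use [lo, lo+80] since uniform over [60, 10000] would be
physiologically meaningless. What the generator does **not** model —
realistic marginal distributions, inter-vital correlation, informative
missingness, real clinical language — bounds what passing tests show: they
validate the pipeline's mechanics and statistical discipline, not clinical
performance.

The canonical study conditions used by the calibration and ablation checks
are pinned once in `perioprisk.presets`: 1,000 patients (143 cases, 857
controls, ~1:6), 120 tabular attributes of which 15 informative at Cohen's
d = 1.0, 30% missingness, six monitored vitals at 60 one-minute samples
with excursion probability 0.8, a 300-token vocabulary with 30 signal
tokens at rate 0.3, and five fixed seeds. Medians (signal checks) or means
(null calibration) over the five seeds are compared against the bands,
since a single 100-patient test partition puts ±0.09 of seed noise on an
AUC under the null.

## Known limitations

* CPU-scale NumPy training: fine for thousands of short documents, not for
  large corpora or long documents.
* The learned fusion layer is a single dense layer with a logistic probe;
  no attention, gating or score-level fusion.
* No calibration analysis, survival/time-to-event modelling, or
  hyperparameter search; baseline hyperparameters are pinned, not tuned.
* Repeated surgeries per patient, HL7/FHIR ingestion and de-identification
  are out of scope.
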