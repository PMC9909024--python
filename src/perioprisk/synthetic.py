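"""Synthetic perioperative cohort generator.

Real perioperative EHR cohorts are private, so the pipeline is exercised on
generated cohorts that reproduce the statistical structure the model relies
on: strong class imbalance (hundreds of cases against thousands of controls),
heavy missingness in the preoperative tabular block, and label-dependent
signal planted *independently* in each modality —

* tabular: a handful of informative attributes whose positive-class mean is
  shifted by a standardized effect (Cohen's d); the rest is pure noise;
* monitoring: controls stay inside the clinical normal range, positive
  patients receive contiguous out-of-range excursion blocks (contiguous, not
  i.i.d. spikes, so the *duration* features carry signal the point-wise
  moments alone do not);
* text: positive documents mix tokens from a dedicated signal vocabulary,
  disjoint from the noise vocabulary, at a controllable rate.

One master seed drives three independent sub-streams (tabular / monitoring /
text) so a single modality can be regenerated or nulled without perturbing
the others. With every effect parameter at zero the two classes are
exchangeable in all modalities — the null-calibration condition.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Cohort, PatientRecord

#: sampling caps for the two attributes whose catalogue upper bound is the
#: 10000 "unbounded" sentinel — in-range draws use [lo, lo+80] instead
_SENTINEL_CAP = 80.0

_DEFAULT_MONITORING = ["HR", "SBP", "DBP", "RR", "SpO2", "T"]

_SURGERY_DATE = _dt.date(2019, 10, 28)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults mirror a realistic hospital scale.

    The default imbalance (609 cases vs 4223 controls) matches the magnitude
    of a multi-year single-centre critical-event cohort. Effect parameters are
    per modality: ``tabular_effect`` is the standardized mean shift of
    informative attributes, ``abnormal_excursion_prob`` the chance a positive
    patient shows an out-of-range excursion in a given vital sign, and
    ``signal_token_rate`` the chance a positive document token comes from the
    signal vocabulary.
    """

    n_positive: int = 609
    n_control: int = 4223
    n_tabular_attrs: int = 200
    n_informative_tabular: int = 20
    tabular_effect: float = 1.0
    missing_rate: float = 0.30
    monitoring_attrs: tuple[str, ...] = tuple(_DEFAULT_MONITORING)
    series_length_minutes: int = 60
    abnormal_excursion_prob: float = 0.8
    vocab_size: int = 300
    n_signal_tokens: int = 30
    doc_length: int = 45
    signal_token_rate: float = 0.30
    illness: str = "heart"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_tabular > self.n_tabular_attrs:
            raise ValueError("n_informative_tabular cannot exceed n_tabular_attrs")
        for name in ("missing_rate", "abnormal_excursion_prob", "signal_token_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        for name in ("n_tabular_attrs", "series_length_minutes", "vocab_size", "doc_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a three-modality cohort; byte-identical for a fixed seed."""
    from .dsm import RangeCatalogue

    rng_tab, rng_mon, rng_text = _substreams(config.seed)
    catalogue = RangeCatalogue.default()

    n = config.n_positive + config.n_control
    labels = np.array([1] * config.n_positive + [0] * config.n_control)
    ids = [f"p{i:05d}" for i in range(n)]
    schema = [f"attr_{j:03d}" for j in range(config.n_tabular_attrs)]
    informative = schema[: config.n_informative_tabular]

    # --- tabular block -----------------------------------------------------
    X = rng_tab.normal(0.0, 1.0, size=(n, config.n_tabular_attrs))
    X[labels == 1, : config.n_informative_tabular] += config.tabular_effect
    missing_mask = rng_tab.random(size=X.shape) < config.missing_rate

    # --- monitoring block --------------------------------------------------
    monitoring_per_patient: list[dict] = []
    L = config.series_length_minutes
    t_axis = np.arange(L, dtype=float)
    for i in range(n):
        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for attr in config.monitoring_attrs:
            lo, hi = catalogue[attr]
            hi_draw = min(hi, lo + _SENTINEL_CAP)
            span = hi_draw - lo
            # smooth in-range trajectory: midpoint + bounded random walk
            base = lo + span * (0.25 + 0.5 * rng_mon.random())
            wobble = np.cumsum(rng_mon.normal(0.0, span * 0.02, size=L))
            vals = np.clip(base + wobble, lo + 0.02 * span, hi_draw - 0.02 * span)
            if labels[i] == 1 and rng_mon.random() < config.abnormal_excursion_prob:
                exc_len = max(3, int(rng_mon.integers(L // 10, max(L // 3, L // 10 + 1))))
                start = int(rng_mon.integers(0, L - exc_len + 1))
                direction = -1.0 if hi >= 9000 or rng_mon.random() < 0.5 else 1.0
                magnitude = span * (0.1 + 0.3 * rng_mon.random())
                bound = lo if direction < 0 else hi_draw
                vals[start : start + exc_len] = bound + direction * magnitude
            series[attr] = (t_axis.copy(), vals)
        monitoring_per_patient.append(series)

    # --- text block --------------------------------------------------------
    noise_vocab = np.array([f"w{k:04d}" for k in range(config.vocab_size)])
    signal_vocab = np.array([f"sig{k:03d}" for k in range(config.n_signal_tokens)])
    per_doc = max(1, config.doc_length // 3)
    texts: list[dict[str, str]] = []
    for i in range(n):
        docs = {}
        for name in ("chief_complaint", "preop_diagnosis", "exam_conclusions"):
            toks = noise_vocab[rng_text.integers(0, config.vocab_size, size=per_doc)].copy()
            if labels[i] == 1 and config.signal_token_rate > 0 and config.n_signal_tokens > 0:
                sig_mask = rng_text.random(per_doc) < config.signal_token_rate
                toks[sig_mask] = signal_vocab[
                    rng_text.integers(0, config.n_signal_tokens, size=int(sig_mask.sum()))
                ]
            docs[name] = " ".join(toks)
        texts.append(docs)

    # --- assemble, in shuffled order so class blocks are not contiguous ----
    order = np.random.default_rng(np.random.SeedSequence([config.seed, 3])).permutation(n)
    records = []
    for i in order:
        tab = {
            schema[j]: (None if missing_mask[i, j] else float(X[i, j]))
            for j in range(config.n_tabular_attrs)
        }
        records.append(
            PatientRecord(
                patient_id=ids[i],
                label=int(labels[i]),
                illness=config.illness,
                tabular=tab,
                text=texts[i],
                monitoring=monitoring_per_patient[i],
                surgery_date=_SURGERY_DATE,
            )
        )
    cohort = Cohort(records, schema=schema, monitoring_attributes=list(config.monitoring_attrs))
    cohort.informative_attributes = informative  # provenance for tests/diagnostics
    return cohort


def null_config(base: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``base`` with every label-dependent effect switched off."""
    return replace(base, tabular_effect=0.0, abnormal_excursion_prob=0.0, signal_token_rate=0.0)


def generate_worked_fixture() -> Cohort:
    """A tiny hand-checkable cohort with known abnormal durations and moments.

    Patient ``hf01`` holds a heart-rate series sampled once per minute: 10
    samples at 120 bpm (above the [50, 100] normal range) followed by 50
    samples at 70 bpm, so its abnormal HR duration is exactly 10 minutes.
    ``ctl01`` is entirely in range (all-zero abnormal block), and ``tri01``
    carries the three-point series [1, 2, 3] under a unit-interval catalogue
    check (mean 2, variance 2/3, skewness 0, kurtosis 1.5).
    """
    t60 = np.arange(60, dtype=float)
    hr_hf = np.concatenate([np.full(10, 120.0), np.full(50, 70.0)])
    hr_ctl = np.full(60, 75.0)

    records = [
        PatientRecord(
            patient_id="hf01",
            label=1,
            illness="heart",
            tabular={"attr_000": 1.2, "attr_001": None},
            text={
                "chief_complaint": "sig001 w0001 sig002",
                "preop_diagnosis": "sig003 w0002",
                "exam_conclusions": "w0003 sig001",
            },
            monitoring={"HR": (t60.copy(), hr_hf), "SBP": (t60.copy(), np.full(60, 120.0))},
            surgery_date=_SURGERY_DATE,
        ),
        PatientRecord(
            patient_id="ctl01",
            label=0,
            illness="heart",
            tabular={"attr_000": -0.3, "attr_001": 0.5},
            text={
                "chief_complaint": "w0001 w0004",
                "preop_diagnosis": "w0005",
                "exam_conclusions": "w0006 w0007",
            },
            monitoring={"HR": (t60.copy(), hr_ctl), "SBP": (t60.copy(), np.full(60, 110.0))},
            surgery_date=_SURGERY_DATE,
        ),
        PatientRecord(
            patient_id="tri01",
            label=0,
            illness="heart",
            tabular={"attr_000": 0.0, "attr_001": 0.1},
            text={"chief_complaint": "w0001", "preop_diagnosis": "", "exam_conclusions": ""},
            monitoring={"HR": (np.array([0.0, 1.0, 2.0]), np.array([61.0, 62.0, 63.0]))},
            surgery_date=_SURGERY_DATE,
        ),
    ]
    return Cohort(records, schema=["attr_000", "attr_001"], monitoring_attributes=["HR", "SBP"])
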