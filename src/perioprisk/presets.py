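"""Canonical study conditions for simulation experiments.

These presets pin, once, the synthetic-cohort scale and pipeline sizes used
throughout the package's own calibration and ablation studies: a
1,000-patient cohort at 1:6 case-control imbalance with moderate effect
sizes per modality, and a desk-size pipeline (32-map text network, 32-dim
word vectors, six monitored vitals). Signal can be restricted to any subset
of modalities — the others are generated under the null — which is how the
signal-localization and null-calibration checks are built.
"""

from __future__ import annotations

from dataclasses import replace

from .synthetic import GeneratorConfig

ALL_MODALITIES = ("tabular", "monitoring", "text")

#: effect sizes under the "signal on" condition, per modality
STUDY_EFFECTS = {
    "tabular_effect": 1.0,
    "abnormal_excursion_prob": 0.8,
    "signal_token_rate": 0.30,
}


def study_generator_config(seed: int, signal=ALL_MODALITIES) -> GeneratorConfig:
    """1,000-patient cohort (143 cases vs 857 controls, ~1:6) with signal
    planted only in the named modalities; the rest are null."""
    signal = tuple(signal)
    unknown = set(signal) - set(ALL_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    return GeneratorConfig(
        n_positive=143,
        n_control=857,
        n_tabular_attrs=120,
        n_informative_tabular=15,
        tabular_effect=STUDY_EFFECTS["tabular_effect"] if "tabular" in signal else 0.0,
        missing_rate=0.30,
        monitoring_attrs=("HR", "SBP", "DBP", "RR", "SpO2", "T"),
        series_length_minutes=60,
        abnormal_excursion_prob=(
            STUDY_EFFECTS["abnormal_excursion_prob"] if "monitoring" in signal else 0.0
        ),
        vocab_size=300,
        n_signal_tokens=30,
        doc_length=45,
        signal_token_rate=STUDY_EFFECTS["signal_token_rate"] if "text" in signal else 0.0,
        seed=seed,
    )


def null_generator_config(seed: int) -> GeneratorConfig:
    """Study-scale cohort with every effect at zero (classes exchangeable)."""
    return study_generator_config(seed, signal=())


def derive_seed(base: int, *path: int) -> int:
    """Stable small sub-seed (< 2^31) derived from a base seed and a path."""
    import numpy as np

    ss = np.random.SeedSequence([int(base), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))
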