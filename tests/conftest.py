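import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from perioprisk import (  # noqa: E402
    DpcnnConfig,
    GeneratorConfig,
    PipelineConfig,
    generate_cohort,
    generate_worked_fixture,
)


@pytest.fixture(scope="session")
def worked_cohort():
    """Tiny hand-checkable cohort (known abnormal minutes and moments)."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def tiny_generator_config():
    """A fast cohort config for pipeline plumbing tests (seconds, not minutes)."""
    return GeneratorConfig(
        n_positive=30,
        n_control=90,
        n_tabular_attrs=20,
        n_informative_tabular=5,
        tabular_effect=1.5,
        missing_rate=0.2,
        monitoring_attrs=("HR", "SBP", "RR"),
        series_length_minutes=20,
        vocab_size=50,
        n_signal_tokens=8,
        doc_length=15,
        signal_token_rate=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_generator_config):
    return generate_cohort(tiny_generator_config)


@pytest.fixture(scope="session")
def tiny_pipeline_config():
    return PipelineConfig(
        n_monitoring=3,
        candidate_ks=(5, 20),
        embedding_dim=12,
        w2v_epochs=2,
        dpcnn=DpcnnConfig(
            n_feature_maps=8, n_blocks=2, max_doc_len=32, dropout=0.0,
            lr=5e-3, epochs=3, batch_size=32, patience=2,
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
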