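import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fhrva.preprocessing import estimate_floatingline, extract_fhrv
from fhrva.synthetic_ctg import ArtifactSpec, GeneratorConfig, generate_record

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FS = 4.0


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """Artifact-free 25-min record configuration used across tests."""
    return GeneratorConfig(
        duration_s=1500.0,
        seed=123,
        artifact_spec=ArtifactSpec(outlier_fraction=0.0, gap_count=0, gap_length_s=0.0),
    )


@pytest.fixture(scope="session")
def record_truth(clean_config):
    return generate_record(clean_config)


@pytest.fixture(scope="session")
def fhrv_sig(record_truth):
    record, _ = record_truth
    fl = estimate_floatingline(record.fhr, record.sampling_rate)
    return extract_fhrv(record.fhr, fl, record.sampling_rate)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
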