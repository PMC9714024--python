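import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated synthetic families shared by search/eval tests."""
    from knnhom.benchmarks import SyntheticParams, generate_synthetic

    return generate_synthetic(
        SyntheticParams(
            n_families=10,
            members_per_family=6,
            dim=32,
            intra_family_sigma=0.05,
            seq_length=80,
            mutation_rate=0.1,
            seed=42,
        )
    )
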