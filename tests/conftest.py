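import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest multi-gene cohort shared by pipeline-level tests."""
    from lrnkit.synthetic import CascadeConfig, simulate_lrn_cascade

    cfg = CascadeConfig(n_samples=300, n_genes=12, n_phenotypes=2, seed=314)
    return simulate_lrn_cascade(cfg)


@pytest.fixture(scope="session")
def small_mapping(small_dataset):
    from lrnkit.pipeline import run_mapping

    return run_mapping(small_dataset, n_perm=300, seed=9)
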