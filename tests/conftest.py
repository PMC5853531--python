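import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsamap import SimConfig, GenomeLayout, simulate_bsa_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast two-chromosome scenario used by unit tests."""
    kwargs = dict(
        layout=GenomeLayout.from_pairs([("chr1", 8_000_000), ("chr2", 8_000_000)]),
        snp_spacing=10_000.0,
        n_progeny=100,
        bulk_size=28,
        causal_locus=("chr2", 4_000_000),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_bsa_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
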