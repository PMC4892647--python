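import pytest
from hypothesis import settings

from mirhet.simulate import SyntheticConfig, gen_paired_study

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study():
    """One fixed synthetic paired study shared across tests."""
    return gen_paired_study(SyntheticConfig(seed=42))


@pytest.fixture()
def small_cfg():
    """A fast, reduced-size study configuration."""
    return SyntheticConfig(n_patients=8, k=3, seed=7)
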