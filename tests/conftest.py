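import numpy as np
import pytest

from irlnc import synth


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    return synth.SynthConfig(
        n_normal=5,
        n_pulpitis=7,
        n_mrna=300,
        n_lnc=40,
        n_immune_sets=10,
        genes_per_set=12,
        n_planted_lnc=6,
        rho=0.8,
        de_frac=0.1,
        de_effect=2.0,
        noise_sd=0.4,
        subtype_effect=1.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return synth.generate_bundle(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
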