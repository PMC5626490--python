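import numpy as np
import pytest

from phigate import RateSet, TraceMeta


@pytest.fixture(scope="session")
def default_rates() -> RateSet:
    """WT-like simulator defaults: ~1 s interbursts, ~10 ms flickers."""
    return RateSet(k_CO=1.0, k_OC=2.0, k_OF=10.0, k_FO=100.0)


@pytest.fixture(scope="session")
def default_meta() -> TraceMeta:
    return TraceMeta(fs=1000.0, fc=50.0, baseline=0.0,
                     unitary_amplitude=-0.8, noise_sd=0.15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
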