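import numpy as np
import pytest

import letdist as ld


@pytest.fixture(scope="session")
def leukemia():
    """Bundled 46-patient leukemia recurrence sample (randomly censored)."""
    return ld.load_fixture("leukemia46").sample


@pytest.fixture(scope="session")
def letf_362():
    """The reference heavy-tailed model: lam=3 on Fréchet(alpha=6, beta=2)."""
    return ld.LETModel(3.0, ld.make_frechet(6.0, 2.0))


@pytest.fixture(scope="session")
def lete_11():
    """Light-tailed reference model: lam=1 on Exponential(rate 1)."""
    return ld.LETModel(1.0, ld.make_exponential(1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
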