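import numpy as np
import pytest

from protlen import GammaParams, SyntheticSpec, simulate_proteome


@pytest.fixture
def rng():
    return np.random.default_rng(20120201)


@pytest.fixture(scope="session")
def gamma_proteome():
    """A mid-size synthetic proteome from a gamma length law, with its
    ground-truth ledger; shared across tests that only read it."""
    spec = SyntheticSpec(
        species_code="SYN_GAM",
        model="gamma_free",
        params_dict={"shape": 2.3, "rate": 0.006},
        n=3000,
        seed=11,
        min_length=30,
    )
    return simulate_proteome(spec)
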