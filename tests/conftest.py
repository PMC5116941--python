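import warnings

import pytest

from methanofba import build_core_model


@pytest.fixture(scope="session")
def core_model():
    """The default (bifurcating, pooled-Fd) core methanogenesis model."""
    return build_core_model()


@pytest.fixture(scope="session")
def nonbifurcating_model():
    return build_core_model(hdr_mode="nonbifurcating")


@pytest.fixture(autouse=True)
def _quiet_thermo_warnings():
    """The ledger warns about exchanges without formation energies (H2S,
    NH3, ...); that is expected behaviour, not test noise."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="no formation energy", category=UserWarning
        )
        yield
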