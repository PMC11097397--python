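import pytest

from pondch4.synthetic import LandscapeConfig, simulate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A 400-pond, 7-year synthetic landscape shared across tests."""
    return simulate_landscape(
        LandscapeConfig(n_ponds=400, years=(2000, 2006)), seed=11
    )
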