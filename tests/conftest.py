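import pytest
from hypothesis import HealthCheck, settings

from dscft import SolventSpec, default_ion_pair
from dscft.quadrature import QuadratureConfig

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ions():
    """Monovalent opposite ions, diameter 3 A (the standard pair)."""
    return default_ion_pair()


@pytest.fixture(scope="session")
def water_like():
    """Water-like solvent bead at gas-phase-ish dipole: 1 D, 30 A^3, 300 K."""
    return SolventSpec(mu_bar=1.0)


@pytest.fixture(scope="session")
def quad():
    return QuadratureConfig()
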