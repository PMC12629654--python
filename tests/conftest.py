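import numpy as np
import pytest

from eatseg.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom that renders in well under a second."""
    return PhantomSpec(
        shape=(64, 64, 56),
        spacing=(2.4, 2.4, 2.4),
        paracardial_radius=12.0,
        paracardial_gap=2.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(CTVolume, PhantomTruth) pair shared across tests (read-only)."""
    return generate(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
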