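import numpy as np
import pytest

from fluoroplaque import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One noise-free phantom at the default study conditions."""
    return generate_phantom(PhantomSpec(seed=7))


def random_feasible_spec(rng, *, noise_sd=0.0):
    """Draw a PhantomSpec that is always geometrically feasible."""
    return PhantomSpec(
        height=int(rng.integers(48, 97)),
        width=int(rng.integers(48, 97)),
        plaque_fraction=float(rng.uniform(0.0, 0.5)),
        tooth_fraction=float(rng.uniform(0.2, 0.8)),
        restoration_fraction=float(rng.uniform(0.0, 0.1)),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
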