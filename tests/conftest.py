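import numpy as np
import pytest

from nodulect.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def benign_phantom():
    """The default benign phantom (fixed seed) used across mask-quality tests."""
    spec = PhantomSpec()
    return generate_phantom(spec, np.random.default_rng(0))


@pytest.fixture(scope="session")
def random_gray_cube():
    """A seeded 12^3 gray cube with a ball mask, for texture-feature oracles."""
    rng = np.random.default_rng(42)
    gray = rng.integers(0, 256, size=(12, 12, 12)).astype(np.float64)
    zz, yy, xx = np.meshgrid(*[np.arange(12)] * 3, indexing="ij")
    mask = (zz - 5.5) ** 2 + (yy - 5.5) ** 2 + (xx - 5.5) ** 2 <= 25
    return gray, mask
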