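import numpy as np
import pytest

from hydropore.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One quick 256×256 phantom with 12 pores, shared across tests."""
    spec = PhantomSpec(height=256, width=256, n_pores=12, radius_max=14, seed=42)
    img, gt = generate_phantom(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def benchmark_phantoms():
    """The ten fixed-seed benchmark phantoms (512², 50 disks, σ=8, 40-level ramp)."""
    out = []
    for seed in range(10):
        spec = PhantomSpec(seed=seed)
        out.append((spec, *generate_phantom(spec)))
    return out
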