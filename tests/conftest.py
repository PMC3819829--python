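import numpy as np
import pytest

from mediqtl import SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_dataset():
    """A 50x50 dataset with one strongly mediated trio (SNP 3 -> probe 7 -> trait)."""
    spec = SimulationSpec(
        n_samples=200,
        n_snps=50,
        n_probes=50,
        maf_range=(0.2, 0.5),  # common variants: planted effects carry nominal power
        planted_trios=[(3, 7, 0.8, 0.8)],
        missing_rate=0.02,
        seed=2024,
    )
    g, e, p, truth = simulate_dataset(spec)
    return g, e, p, truth


@pytest.fixture(scope="session")
def null_dataset():
    """A 60x40 dataset with no genetic effects at all."""
    spec = SimulationSpec(n_samples=150, n_snps=60, n_probes=40,
                          missing_rate=0.02, seed=77)
    g, e, p, truth = simulate_dataset(spec)
    return g, e, p, truth
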