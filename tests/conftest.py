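import numpy as np
import pytest

from pbsalink import synth


@pytest.fixture(scope="session")
def toy():
    """Small parameterized two-cluster complex with ligand."""
    return synth.make_toy_complex(synth.ToySpec(n_atoms_a=20, n_atoms_b=20, seed=3))


@pytest.fixture(scope="session")
def toy_with_ion():
    return synth.make_toy_complex(
        synth.ToySpec(n_atoms_a=20, n_atoms_b=20, ion=True, seed=3)
    )


@pytest.fixture(scope="session")
def jitter_ensemble(toy):
    """50-frame Gaussian-jitter ensemble (sigma 0.2 Å, no rocking)."""
    return synth.make_snapshot_ensemble(toy, 50, jitter_sd=0.2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
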