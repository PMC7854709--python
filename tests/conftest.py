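import numpy as np
import pytest

from qm7xtools.calculators import (
    HarmonicBackend,
    make_toy_molecule,
)
from qm7xtools.normal_modes import harmonic_analysis


@pytest.fixture(scope="session")
def toy5():
    """5-atom seeded toy molecule: (structure, harmonic model, morse topology)."""
    return make_toy_molecule(5, seed=3)


@pytest.fixture(scope="session")
def toy5_modes(toy5):
    s, model, _ = toy5
    return harmonic_analysis(model.hessian, s.masses, s)


@pytest.fixture(scope="session")
def toy5_backend(toy5):
    _, model, _ = toy5
    return HarmonicBackend(model)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
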