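import numpy as np
import pytest

from seirakit.tcmt import (CoupledSystem, MolecularOscillator, Resonator,
                           absorption_spectrum, system_from_ratios)
from seirakit.synthetic import default_grid


@pytest.fixture
def ftir_grid():
    """FTIR-like evaluation grid: 800-4000 cm^-1, 1687 points."""
    return default_grid()


@pytest.fixture
def oc_hmu_pmma_system():
    """Strongly coupled overcoupled device with a single carbonyl line
    (the canonical inversion fixture: all rates in cm^-1)."""
    return CoupledSystem(Resonator(1730.0, 400.0, 40.0),
                         (MolecularOscillator(1730.0, 10.0, 25.0),))


@pytest.fixture
def oc_hmu_pmma_spectrum(oc_hmu_pmma_system, ftir_grid):
    return absorption_spectrum(oc_hmu_pmma_system, ftir_grid)


@pytest.fixture
def reduced_oc():
    """f=10, xi=1, zero detuning in unit reference rates."""
    return system_from_ratios(10.0, 1.0, 0.0)


@pytest.fixture
def reduced_uc():
    """f=0.4, xi=0.5, zero detuning in unit reference rates."""
    return system_from_ratios(0.4, 0.5, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
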