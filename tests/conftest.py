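import numpy as np
import pytest

from triphoton.correlate import CorrelationBinning, TripleCorrelationEngine
from triphoton.intensity import (AtomSet, BeamGeometry, ShellGrid,
                                 expand_on_shells, intensity_from_atoms)

WAVELENGTH = 2.5   # A (5 keV beam)
K_CUT = 2.15       # 1/A

# Toy study conditions: 5 Gaussian pseudo-atoms compact enough that the
# recovery order L = 6 is close to band-limiting at k_cut (L ~ k_cut * R).
TOY_SEED = 10


@pytest.fixture(scope="session")
def toy_atoms() -> AtomSet:
    rng = np.random.default_rng(TOY_SEED)
    return AtomSet(rng.uniform(-3, 3, (5, 3)), rng.uniform(4, 9, 5),
                   rng.uniform(0.7, 1.1, 5))


@pytest.fixture(scope="session")
def geometry() -> BeamGeometry:
    return BeamGeometry(WAVELENGTH, K_CUT)


@pytest.fixture(scope="session")
def shell_grid() -> ShellGrid:
    return ShellGrid.uniform(8, K_CUT)


@pytest.fixture(scope="session")
def toy_model(toy_atoms, shell_grid):
    """Truth intensity of the toy molecule at the recovery order L = 6."""
    return expand_on_shells(lambda p: intensity_from_atoms(toy_atoms, p),
                            shell_grid, 6, wavelength=WAVELENGTH)


@pytest.fixture(scope="session")
def toy_model_l4(toy_atoms):
    grid = ShellGrid.uniform(5, 1.6)
    return expand_on_shells(lambda p: intensity_from_atoms(toy_atoms, p),
                            grid, 4, wavelength=WAVELENGTH)


@pytest.fixture(scope="session")
def binning(shell_grid) -> CorrelationBinning:
    return CorrelationBinning(shell_grid, n_alpha=16, wavelength=WAVELENGTH)


@pytest.fixture(scope="session")
def engine(shell_grid, binning) -> TripleCorrelationEngine:
    return TripleCorrelationEngine(shell_grid, 6, binning, WAVELENGTH)
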