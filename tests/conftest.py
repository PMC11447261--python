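import numpy as np
import pytest

from mucofilm.scenario_config import (CryptGeometry, SubstratumLattice,
                                      build_crypt_lattice)


@pytest.fixture(scope="session")
def crypt_lattice() -> SubstratumLattice:
    """Baseline 500x500 um crypt lattice (80/20/30 um pillars)."""
    return build_crypt_lattice(CryptGeometry())


@pytest.fixture()
def flat_lattice() -> SubstratumLattice:
    """100x100 um flat surface: a single solid base row, no pillars."""
    return build_crypt_lattice(CryptGeometry(width=100, height=100,
                                             pillar_height=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
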