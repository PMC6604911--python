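import numpy as np
import pytest

from dnapatite.crystal import (CrystalSpec, PoreSpec, build_supercell,
                               build_unit_cell, carve_pore)
from dnapatite.dna import SEQUENCE_I, build_canonical_duplex
from dnapatite.forcefield import build_topology, default_params


@pytest.fixture(scope="session")
def hap_spec():
    return CrystalSpec.packaged("hap")


@pytest.fixture(scope="session")
def fap_spec():
    return CrystalSpec.packaged("fap")


@pytest.fixture(scope="session")
def hap_cell(hap_spec):
    return build_unit_cell(hap_spec)


@pytest.fixture(scope="session")
def fap_cell(fap_spec):
    return build_unit_cell(fap_spec)


@pytest.fixture(scope="session")
def hap_supercell(hap_cell):
    return build_supercell(hap_cell, 6, 6, 7)


@pytest.fixture(scope="session")
def hap_carved(hap_supercell):
    return carve_pore(hap_supercell, PoreSpec((2, 2, 7)))


@pytest.fixture(scope="session")
def duplex_I():
    return build_canonical_duplex(SEQUENCE_I)


@pytest.fixture(scope="session")
def duplex_I_topology(duplex_I):
    return build_topology(duplex_I.structure)


@pytest.fixture(scope="session")
def ff_params():
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
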