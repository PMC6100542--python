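import numpy as np
import pytest

from octaspin.complexes import ComplexSpec
from octaspin.io import extract_target
from octaspin.ligands import load_ligand_library
from octaspin.synth import SynthConfig, generate_synthetic


@pytest.fixture(scope="session")
def library():
    return load_ligand_library()


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic dataset shared by read-only tests (60 complexes, 420 rows)."""
    return generate_synthetic(SynthConfig(n_complexes=60, seed=7))


@pytest.fixture(scope="session")
def small_splitting(small_synth):
    specs, y = extract_target(small_synth.table, "splitting")
    return specs, np.asarray(y)


@pytest.fixture
def hexacarbonyl(library):
    return ComplexSpec("Fe", 2, library["CO"], library["CO"], a_hf=0.20)


@pytest.fixture
def hexaammine(library):
    return ComplexSpec("Fe", 2, library["NH3"], library["NH3"], a_hf=0.20)
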