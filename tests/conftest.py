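import numpy as np
import pytest

from ptmdelta.geometry import generate_paired_ensembles
from ptmdelta.surrogate import load_calibration
from ptmdelta.topology import PTMState


@pytest.fixture(scope="session")
def calibration():
    return load_calibration()


@pytest.fixture(scope="session")
def lys_mono_pair():
    """Small paired ensemble for mono-methyl Lys, shared across tests."""
    return generate_paired_ensembles(PTMState("LYS", "monomethyl"),
                                     n_backbones=40, seed=11)


@pytest.fixture(scope="session")
def ser_glyco_pair():
    return generate_paired_ensembles(PTMState("SER", "alpha-GalNAc"),
                                     n_backbones=15, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
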