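import numpy as np
import pytest

from fndmc.systems import builtin_system
from fndmc.trials import make_trial


@pytest.fixture(scope="session")
def h_atom():
    return builtin_system("H")


@pytest.fixture(scope="session")
def he_atom():
    return builtin_system("He")


@pytest.fixture(scope="session")
def be_atom():
    return builtin_system("Be")


@pytest.fixture(scope="session")
def harmonic_well():
    return builtin_system("harmonic_well")


@pytest.fixture(scope="session")
def fermions_1d():
    return builtin_system("harmonic_fermions_1d")


@pytest.fixture(scope="session")
def hydrogenic_h(h_atom):
    return make_trial("hydrogenic", h_atom)


@pytest.fixture(scope="session")
def he_pade(he_atom):
    return make_trial("he_pade", he_atom, {"b": 0.35})


@pytest.fixture(scope="session")
def fermion_trial(fermions_1d):
    return make_trial("harmonic_fermions", fermions_1d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
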