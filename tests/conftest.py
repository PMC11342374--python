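import pytest

from peptoids.design_space import candidate_set, default_lipid_pool
from peptoids.monomers import default_monomer_set, get_monomer


@pytest.fixture(scope="session")
def mset():
    return default_monomer_set()


@pytest.fixture(scope="session")
def pool(mset):
    return default_lipid_pool(mset)


@pytest.fixture(scope="session")
def apd(mset):
    return get_monomer(mset, "Apd")


@pytest.fixture(scope="session")
def candidates(pool, apd):
    """Full feasible candidate set over the default pool, Apd headgroup."""
    return candidate_set(pool, apd)
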