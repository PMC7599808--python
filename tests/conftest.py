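import pytest

from evsmallrna import refsim


@pytest.fixture(scope="session")
def refs():
    """Small collision-free reference set shared across tests."""
    return refsim.generate_references(n_mirna=12, n_trna=8, n_background=6,
                                      seed=11)


@pytest.fixture(scope="session")
def big_refs():
    """Study-scale reference set (30 miRNAs, 20 isoacceptors)."""
    return refsim.generate_references(n_mirna=30, n_trna=20, n_background=8,
                                      seed=1)
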