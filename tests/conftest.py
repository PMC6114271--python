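import pytest

from herbnet.io import load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 70-compound screened-ingredient table."""
    return load_table1()


@pytest.fixture(scope="session")
def table1_degrees(table1):
    """Compound id -> published compound-target degree."""
    return {r.compound_id: r.degree for r in table1}
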