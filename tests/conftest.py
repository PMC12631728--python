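import numpy as np
import pytest

from sipsim.chem import EnrichmentSpec, natural_table, parse_formula


@pytest.fixture(scope="session")
def table():
    return natural_table()


@pytest.fixture(scope="session")
def glucose():
    return parse_formula("C6H12O6")


@pytest.fixture(scope="session")
def table_50(table):
    return table.enrich(EnrichmentSpec("C", 13, 0.5))


def assert_envelopes_close(a, b, tol):
    """Compare probability vectors of possibly different trimmed lengths."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = min(a.size, b.size)
    assert np.max(np.abs(a[:n] - b[:n])) <= tol
    if a.size > n:
        assert np.max(np.abs(a[n:])) <= tol
    if b.size > n:
        assert np.max(np.abs(b[n:])) <= tol
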