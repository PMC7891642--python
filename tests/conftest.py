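import numpy as np
import pandas as pd
import pytest

from ednafi import MotuTable, TraitTable, load_table1_fixture, load_table2_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture
def small_counts():
    """Two samples, three taxa, easy numbers."""
    data = pd.DataFrame(
        [[25.0, 75.0, 0.0], [10.0, 10.0, 80.0]],
        index=["s1", "s2"],
        columns=["tax_a", "tax_b", "tax_c"],
    )
    return MotuTable(data, method="eDNA", unit="counts")


@pytest.fixture
def disjoint_traits():
    """Three disjoint guilds partitioning three taxa."""
    return TraitTable(
        {
            "tax_a": frozenset({"BEN"}),
            "tax_b": frozenset({"PEL"}),
            "tax_c": frozenset({"RHE"}),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
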