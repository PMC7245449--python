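import numpy as np
import pandas as pd
import pytest

from malnutmap.anthropometry import ReferenceTable
from malnutmap.simulate import make_district_graph, make_reference_fixture
from malnutmap.spatial import build_adjacency


@pytest.fixture(scope="session")
def reference_table() -> ReferenceTable:
    return make_reference_fixture()


@pytest.fixture
def four_cycle():
    return build_adjacency([(1, 2), (2, 3), (3, 4), (4, 1)], 4)


@pytest.fixture(scope="session")
def lattice52():
    return make_district_graph(52, style="grid", seed=0)


@pytest.fixture
def tiny_reference() -> ReferenceTable:
    """Hand-sized table for exact interpolation checks."""
    rows = []
    for sex in ("male", "female"):
        for age, L, M, S in [(0, 1.0, 10.0, 0.10), (12, 0.5, 12.0, 0.12),
                             (24, 0.0, 14.0, 0.14)]:
            rows.append({"indicator": "height_for_age", "sex": sex,
                         "index_value": age, "L": L, "M": M, "S": S})
    return ReferenceTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
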