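import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from triway.synthetic import table1_fixture
from triway.table import (
    InformationTable,
    compute_partition,
    concept_from_decision,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def concept_yes(table1):
    return concept_from_decision(table1, "Yes")


@pytest.fixture(scope="session")
def partition_t0(table1):
    return compute_partition(table1, ("Localization",))


@pytest.fixture(scope="session")
def partition_t1(table1):
    return compute_partition(table1, ("Localization", "Interacting proteins"))


@pytest.fixture(scope="session")
def partition_t2(table1):
    return compute_partition(table1, table1.attributes)


def make_random_table(rng: np.random.Generator, n_objects=None, n_attrs=None,
                      n_values=3) -> InformationTable:
    """Small random categorical information table for property tests."""
    n = n_objects or int(rng.integers(2, 13))
    m = n_attrs or int(rng.integers(1, 4))
    ids = [f"x{i}" for i in range(n)]
    data = pd.DataFrame(
        {f"a{j}": [f"v{v}" for v in rng.integers(0, n_values, size=n)]
         for j in range(m)},
        index=ids,
    )
    decision = pd.Series(np.where(rng.random(n) < 0.5, "Y", "N"), index=ids)
    return InformationTable(data, decision, "d")
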