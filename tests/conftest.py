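import numpy as np
import pandas as pd
import pytest

from solartmle.cohort import CohortTable
from solartmle.nodes import NodeSpec
from solartmle.synthetic import default_solar_model, simulate, small_binary_model


@pytest.fixture(scope="session")
def small_model():
    return small_binary_model(seed=7)


@pytest.fixture(scope="session")
def solar_model():
    return default_solar_model()


@pytest.fixture(scope="session")
def solar_cohort(solar_model):
    """A study-sized cohort (n=121) with MAR missingness."""
    return simulate(solar_model, 121, seed=42)


@pytest.fixture(scope="session")
def big_binary_cohort(small_model):
    """Complete all-binary cohort, large enough for saturated fits."""
    return simulate(small_model, 20_000, seed=11, missingness=False)


def toy_specs() -> list[NodeSpec]:
    return [
        NodeSpec("W", "baseline", 1),
        NodeSpec("L1", "confounder", 1),
        NodeSpec("A1", "treatment", 1),
        NodeSpec("Y1", "outcome", 1),
        NodeSpec("L2", "confounder", 2),
        NodeSpec("A2", "treatment", 2),
        NodeSpec("Y2", "outcome", 2),
    ]


def toy_table(rows: list[dict]) -> CohortTable:
    specs = toy_specs()
    df = pd.DataFrame(rows, columns=[s.name for s in specs]).astype(float)
    return CohortTable(df, specs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
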