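import numpy as np
import pandas as pd
import pytest

from milasso.data_model import BoundsTable, DatasetTable, VariableMeta
from milasso.synthetic_data import SimulationDesign, generate_study

SMALL_TRUE_TERMS = (
    (("x01",), 1.5),
    (("x03",), -1.2),
    (("x07",), 1.0),
    (("x03", "x07"), 1.0),
)


@pytest.fixture(scope="session")
def small_design():
    """Reduced study used by the fast end-to-end tests."""
    return SimulationDesign(
        n_obs=60,
        n_numeric_predictors=12,
        n_temporal=2,
        true_terms=SMALL_TRUE_TERMS,
        missing_prob=0.10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return generate_study(small_design)


@pytest.fixture()
def toy_triple():
    """3-row table with one missing cell and a matching bound."""
    values = pd.DataFrame(
        {"a": [1.0, np.nan, 3.0], "b": [0.5, 0.6, 0.7], "y": [1.0, 2.0, 3.0]},
        index=pd.Index(["o1", "o2", "o3"], name="observation"),
    )
    table = DatasetTable(
        values=values,
        collection_day=pd.Series([5.0, 5.0, 5.0], index=values.index),
    )
    metas = [
        VariableMeta("a", "predictor"),
        VariableMeta("b", "predictor"),
        VariableMeta("y", "response"),
    ]
    bounds = BoundsTable({("o2", "a"): (1.5, 2.5)})
    return table, metas, bounds
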