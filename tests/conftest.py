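import numpy as np
import pandas as pd
import pytest

import ornaval as ov


@pytest.fixture(scope="session")
def default_table() -> ov.TraitTable:
    """One default-size synthetic table shared across read-only tests."""
    return ov.generate_traits(ov.default_params(), seed=11)


@pytest.fixture()
def tiny_df() -> pd.DataFrame:
    """Four plants, two plots, all design columns, three traits."""
    return pd.DataFrame(
        {
            "plant_id": ["p1", "p2", "p3", "p4"],
            "plot_id": ["C1", "C1", "W1", "W1"],
            "treatment": ["control", "control", "warming", "warming"],
            "year": [2017, 2017, 2017, 2017],
            "plant_height": [50.0, 48.5, 44.0, 43.0],
            "branch_number": [6, 7, 8, 8],
            "pedicel_length": [46.0, np.nan, 38.5, 39.0],
        }
    )


@pytest.fixture(scope="session")
def default_weights() -> ov.WeightSet:
    h = ov.default_hierarchy()
    crit, idx = ov.default_matrices()
    return ov.synthesize_weights(h, crit, idx)
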