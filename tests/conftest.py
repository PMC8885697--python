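import numpy as np
import pandas as pd
import pytest

from grinsyn.tables import PropertyTable, PROPERTY_COLUMNS


@pytest.fixture
def small_table():
    """Three mutations, complete measurements, WT reference."""
    wt = pd.Series({"glu_ec50_uM": 3.0, "gly_ec50_uM": 1.0, "deact_tau_ms": 50.0,
                    "current_density_pA_pF": 100.0, "open_prob": 0.5,
                    "surface_rel": 1.0})[PROPERTY_COLUMNS]
    data = pd.DataFrame(
        {
            "glu_ec50_uM": [30.0, 0.3, 3.0],
            "gly_ec50_uM": [1.0, 1.0, 1.0],
            "deact_tau_ms": [25.0, 200.0, 50.0],
            "current_density_pA_pF": [10.0, 100.0, 100.0],
            "open_prob": [0.25, 0.5, 0.5],
            "surface_rel": [0.5, 1.0, 1.0],
        },
        index=["LOF1", "GOF1", "NEUTRAL"],
    )[PROPERTY_COLUMNS]
    return PropertyTable(data, wt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
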