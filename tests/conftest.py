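import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ecometab.feature_io import FeatureMatrix, IncidenceMatrix
from ecometab.synthetic_data import SimDesign, simulate_experiment

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def small_fm() -> FeatureMatrix:
    """3 conditions x 2 replicates x 6 features, hand-written abundances."""
    labels = [
        "100.1000_1.0", "200.2000_2.0", "300.3000_3.0",
        "400.4000_4.0", "500.5000_5.0", "600.6000_6.0",
    ]
    rows = {
        "C27_T0_R1": [10, 20, 0, 5, 1, 0],
        "C27_T0_R2": [12, 18, 0, 4, 0, 0],
        "C16_T0_R1": [9, 0, 30, 5, 2, 0],
        "C16_T0_R2": [11, 0, 28, 6, 0, 1],
        "C4_T0_R1": [0, 0, 40, 5, 3, 2],
        "C4_T0_R2": [0, 0, 38, 4, 2, 0],
    }
    meta = pd.DataFrame(
        {
            "concentration": ["C27", "C27", "C16", "C16", "C4", "C4"],
            "time": ["T0"] * 6,
            "replicate": [1, 2, 1, 2, 1, 2],
            "mode": ["ESI+"] * 6,
        },
        index=list(rows),
    )
    ab = pd.DataFrame.from_dict(rows, orient="index", columns=labels).astype(float)
    return FeatureMatrix(abundance=ab, meta=meta)


@pytest.fixture
def small_incidence() -> IncidenceMatrix:
    """5 units x 10 species with S=10, Q1=4, Q2=2."""
    presence = np.zeros((5, 10), dtype=np.int8)
    # 4 species in all units
    presence[:, 0:4] = 1
    # 2 duplicates (exactly 2 units)
    presence[0:2, 4] = 1
    presence[3:5, 5] = 1
    # 4 uniques
    presence[0, 6] = 1
    presence[1, 7] = 1
    presence[2, 8] = 1
    presence[4, 9] = 1
    df = pd.DataFrame(
        presence,
        index=[f"u{i}" for i in range(5)],
        columns=[f"{100 + i}.0000_1.0" for i in range(10)],
    )
    return IncidenceMatrix(presence=df)


@pytest.fixture(scope="session")
def tiny_design() -> SimDesign:
    """Down-scaled design for fast end-to-end runs."""
    return SimDesign(s_pool=80, s_base=50, rare_induction=4, n_markers=5)


@pytest.fixture(scope="session")
def tiny_experiment(tiny_design):
    return simulate_experiment(tiny_design, seed=42)
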