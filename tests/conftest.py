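import numpy as np
import pandas as pd
import pytest

from osta_screen.scores import ScoreTable


@pytest.fixture(scope="session")
def toy_kkos_table() -> ScoreTable:
    """Synthetic stand-in score table for tests.

    The real published KKOS coefficient table is external configuration and
    is deliberately not bundled; this toy table only exercises the band
    lookup machinery.
    """
    return ScoreTable(
        name="toy-kkos (synthetic test table)",
        age_bands=[(50, 70, 0.0), (70, 120, -2.0)],
        weight_bands=[(20, 60, -1.0), (60, 250, 1.0)],
    )


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Hand-built 8-subject cohort covering all three diagnostic bands."""
    return pd.DataFrame({
        "id": [f"p{i}" for i in range(8)],
        "age": [55.0, 62.0, 70.0, 75.0, 78.0, 81.0, 84.0, 90.0],
        "weight": [80.0, 72.0, 65.0, 58.0, 66.0, 50.0, 45.0, 60.0],
        "height": [170.0, 168.0, 166.0, 164.0, 165.0, 160.0, 158.0, 162.0],
        "t_lumbar": [1.2, 0.3, -0.5, -1.5, -1.1, -2.6, -3.0, 0.4],
        "t_femoral_neck": [0.5, -0.4, -1.2, -1.8, -2.5, -2.9, -3.2, -1.0],
        "t_total_hip": [0.8, 0.0, -0.9, -1.6, -1.9, -2.7, -2.8, -0.6],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
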