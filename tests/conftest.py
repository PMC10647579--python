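import numpy as np
import pandas as pd
import pytest

from cavikit.cohort import GeneratorConfig, generate_regression_mode


@pytest.fixture(scope="session")
def six_row_table() -> pd.DataFrame:
    """Tiny hand-checkable cohort with exact values."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6],
            "age": [45.0, 55.0, 65.0, 72.0, 80.0, 92.0],
            "sex": ["F", "M", "F", "M", "F", "M"],
            "bmi": [31.0, 29.5, 27.0, 26.0, 24.5, 23.0],
            "sbp": [135.0, 142.0, 138.0, 140.0, 133.0, 147.0],
            "dbp": [88.0, 86.0, 82.0, 76.0, 72.0, 64.0],
            "cavi0": [10.2, 11.1, 12.4, 15.0, 17.8, 22.5],
            "cavi": [7.1, 7.6, 8.2, 9.1, 9.9, 11.3],
            "hypertension": [0, 1, 1, 1, 0, 1],
            "diabetes": [0, 0, 1, 0, 0, 1],
            "dyslipidemia": [1, 1, 0, 1, 0, 0],
            "smoking": [0, 1, 0, 0, 1, 0],
        }
    )


@pytest.fixture(scope="session")
def large_regression_cohort() -> pd.DataFrame:
    """Default-condition regression-mode cohort, n = 200,000, seed 1.

    Session-scoped: shared by the calibration and coefficient-recovery
    checks so the cohort is generated once.
    """
    return generate_regression_mode(GeneratorConfig(n=200_000, seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231024)
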