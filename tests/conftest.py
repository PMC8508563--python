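import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crcmeth import synthetic
from crcmeth.data_io import validate_pairing

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_sheet() -> pd.DataFrame:
    """Default study-design cohort: 125 persons, 30 MSI, paired samples."""
    return synthetic.simulate_cohort(synthetic.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def pairing(cohort_sheet):
    return validate_pairing(cohort_sheet)


@pytest.fixture(scope="session")
def small_sheet() -> pd.DataFrame:
    return synthetic.simulate_cohort(synthetic.CohortConfig(n_persons=8, n_msi=3, seed=5))


def tiny_sheet(rows) -> pd.DataFrame:
    """Hand-built sample sheet from (person, tissue, msi, location) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": f"{p}_{'T' if t == 'tumor' else 'N'}",
                "person_id": p,
                "tissue": t,
                "msi_status": m,
                "location": loc,
                "sex": "male",
                "age": 50.0,
                "stage": 2,
            }
            for p, t, m, loc in rows
        ]
    )
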