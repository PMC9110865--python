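import numpy as np
import pandas as pd
import pytest

from smileig.data_model import COLUMNS, Cohort
from smileig.synthetic_data import default_profiles, generate_center


def make_eye_row(**overrides) -> dict:
    """One internally consistent eye record (plano outcome, 20/20 vision)."""
    row = {
        "center_id": "A", "laterality": "right", "sex": "female", "age": 25.0,
        "pre_sd": -4.50, "pre_cd": -1.00, "pre_axis": 90.0, "pre_se": -5.00,
        "pre_udva": 0.10, "pre_cdva": 1.00, "pre_iop": 15.0,
        "pre_k1": 42.5, "pre_k2": 43.5, "pre_km": 43.0, "pre_cct": 540.0,
        "cap_thickness": 120.0, "optical_zone": 6.5, "laser_energy": 130.0,
        "max_lenticule": 90.0, "rst": 330.0, "nomogram": 0.50,
        "post_se_3m": 0.00, "post_udva": 1.00, "post_cdva": 1.00,
    }
    row.update(overrides)
    return row


def make_cohort(rows) -> Cohort:
    return Cohort(df=pd.DataFrame(rows)[list(COLUMNS)])


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohort(profiles):
    """A seeded 400-eye center-A cohort shared across tests."""
    return generate_center(profiles[0], np.random.default_rng(42), n_eyes=400)
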