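import numpy as np
import pandas as pd
import pytest

import gsos_screen as gs
from gsos_screen.synthetic import RISK_FACTOR_COLUMNS


@pytest.fixture(scope="session")
def small_panel():
    """2,000 individuals x 50 SNPs with strong within-block LD."""
    return gs.simulate_genotypes(2000, 50, block_size=10, block_rho=0.9, seed=11)


@pytest.fixture(scope="session")
def screening_cohort():
    """3,000 screening-eligible individuals with a pre-made polygenic score."""
    return gs.simulate_screening_cohort(3000, seed=21)


@pytest.fixture()
def individual():
    """A baseline eligible woman; tests mutate copies of this dict."""

    def make(**overrides):
        row = {
            "id": "x1",
            "age": 62.0,
            "sex": "female",
            "bmi": 25.0,
            **{f: False for f in RISK_FACTOR_COLUMNS},
            "prior_fracture": True,
            "fn_bmd_tscore": -1.0,
            "sos_std": 0.0,
            "gsos": 0.0,
        }
        row.update(overrides)
        return row

    return make


def trace_df_to_records(df: pd.DataFrame) -> list[dict]:
    return df.to_dict("records")
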