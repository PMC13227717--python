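import numpy as np
import pandas as pd
import pytest

import outcomewide as ow
from outcomewide import columns as C


@pytest.fixture(scope="session")
def small_spec():
    return ow.CohortSpec(n_countries=4, n_per_country=600,
                         confounder_count=12, item_missing_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    panel, truth = ow.generate_cohort(small_spec)
    return panel, truth


@pytest.fixture(scope="session")
def attrited_panel(small_spec):
    panel, truth = ow.generate_cohort(small_spec)
    panel = ow.inject_attrition(panel, target_range=(0.4, 0.8), seed=11,
                                truth=truth)
    return panel, truth


@pytest.fixture()
def design():
    return ow.SurveyDesign()


@pytest.fixture()
def iid_panel():
    """50 rows, unit weights, every respondent its own PSU, one stratum."""
    rng = np.random.default_rng(5)
    n = 50
    return pd.DataFrame({
        C.COUNTRY: "X",
        C.STRATUM: "s1",
        C.PSU: [f"p{i}" for i in range(n)],
        C.WEIGHT: 1.0,
        "x": rng.standard_normal(n),
        "y": rng.standard_normal(n),
    })
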