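import numpy as np
import pandas as pd
import pytest

import netmdmr as nm
from netmdmr.tabular import validate_cohort

GROUP_LEVELS = np.array(["P-high", "P-low", "changers"])


def make_cohort(n: int, seed: int = 0, groups=None) -> pd.DataFrame:
    """Small random but valid cohort table for unit tests."""
    rng = np.random.default_rng(seed)
    g = GROUP_LEVELS[rng.integers(0, 3, n)] if groups is None else np.asarray(groups)
    return validate_cohort(pd.DataFrame({
        "participant_id": [f"s{i:03d}" for i in range(n)],
        "group": g,
        "sex": rng.choice(["male", "female"], n),
        "age_years": rng.uniform(2.0, 4.5, n),
        "tbv_cm3": rng.uniform(900.0, 1200.0, n),
    }))


@pytest.fixture(scope="session")
def fpn():
    return nm.load_network_spec("FPN")


@pytest.fixture(scope="session")
def dmn():
    return nm.load_network_spec("DMN")


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort with the default planted scenario."""
    return nm.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def default_tscores(default_cohort):
    cohort, volumes, _ = default_cohort
    return nm.to_tscores(nm.to_proportions(volumes, cohort))
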