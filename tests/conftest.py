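import math

import pytest

from ctmon.io import load_table2, table2_variant_records
from ctmon.synthetic_cohort import CohortConfig, simulate_cohort

LN4_OVER_28 = math.log(4) / 28.0


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table2_records(table2):
    return table2_variant_records(table2)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient cohort with well-separated kinetics, shared across tests."""
    cfg = CohortConfig(
        n_patients=30,
        seed=11,
        growth_rate_range_nonresponder=(LN4_OVER_28, 0.08),
        decay_rate_range_responder=(-0.08, -LN4_OVER_28),
    )
    return simulate_cohort(cfg)
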