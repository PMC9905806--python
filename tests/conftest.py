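import numpy as np
import pandas as pd
import pytest

import mqeasl as mq


@pytest.fixture(scope="session")
def annotated_cohort():
    """One mid-sized simulated cohort with response columns appended."""
    records, truth = mq.generate_cohort(mq.CohortSpec(n=800, seed=7))
    return mq.annotate_cohort(records), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_survival_frame(times, events, **covs):
    df = pd.DataFrame({"time_months": times, "event": events})
    for k, v in covs.items():
        df[k] = v
    return df
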