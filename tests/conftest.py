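import numpy as np
import pandas as pd
import pytest

from ptmrhythm.types import TimeCourseTable

TIMEPOINTS = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0)


def make_table(values, timepoints=TIMEPOINTS, replicates=3, condition="labeled",
               feature_ids=None):
    """Build a TimeCourseTable from a feature x sample array."""
    values = np.asarray(values, dtype=float)
    cols = pd.MultiIndex.from_tuples(
        [(float(t), r) for t in timepoints for r in range(1, replicates + 1)],
        names=["timepoint", "replicate"])
    if feature_ids is None:
        feature_ids = [f"F{i + 1:03d}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                        columns=cols)
    return TimeCourseTable(data, condition=condition)


@pytest.fixture
def two_feature_table():
    rng = np.random.default_rng(0)
    return make_table(rng.lognormal(3, 0.5, size=(2, 18)))


@pytest.fixture
def sample_timepoints():
    return np.repeat(TIMEPOINTS, 3)
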