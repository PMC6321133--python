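import warnings

import pandas as pd
import pytest

from metabologenomics import SampleMetadata, generate_dataset

# the generators intentionally emit RuntimeWarnings for flagged conditions
# (constant features, undefined correlations); keep test output quiet
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study shared by read-only tests."""
    return generate_dataset(seed=1)


@pytest.fixture()
def small_meta():
    """A minimal 2-group design: 5 control + 5 AD samples, one timepoint."""
    rows = [(f"c{i}", "control", f"c{i}", 8) for i in range(5)] + \
           [(f"a{i}", "AD", f"a{i}", 8) for i in range(5)]
    df = pd.DataFrame(rows, columns=["sample_id", "group", "subject_id",
                                     "age_weeks"]).set_index("sample_id")
    return SampleMetadata(df)
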