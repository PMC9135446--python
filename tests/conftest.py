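import numpy as np
import pandas as pd
import pytest

from keystonet.io import OtuTable
from keystonet.synthetic import default_config, generate_dataset


@pytest.fixture
def small_table() -> OtuTable:
    """3 samples x 4 OTUs with both guilds represented."""
    counts = pd.DataFrame(
        [[10, 0, 5, 3], [8, 2, 7, 1], [12, 1, 6, 0]],
        index=["s1", "s2", "s3"],
        columns=["A1", "A2", "B1", "B2"],
    )
    taxonomy = pd.DataFrame(
        {
            "guild": ["AOA", "AOA", "AOB", "AOB"],
            "cluster": ["Nitrosotalea cluster 1.1", "Nitrososphaera cluster 9",
                        "Nitrosospira cluster 12", "Nitrosospira cluster 3a"],
            "genus": ["Nitrosotalea", "Nitrososphaera", "Nitrosospira",
                      "Nitrosospira"],
        },
        index=pd.Index(["A1", "A2", "B1", "B2"], name="otu_id"),
    )
    return OtuTable(counts, taxonomy)


@pytest.fixture(scope="session")
def dataset():
    """One synthetic dataset under the default study conditions."""
    return generate_dataset(default_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
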