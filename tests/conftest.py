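import numpy as np
import pandas as pd
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def small_counts():
    """Tiny genus count table covering guild members and fillers."""
    data = {
        "Faecalibacterium": [20, 5, 0, 10],
        "Roseburia": [10, 0, 5, 10],
        "Bacteroides": [30, 40, 50, 10],
        "Prevotella": [0, 20, 10, 10],
        "Eggerthella": [5, 0, 5, 10],
        "Klebsiella": [5, 5, 0, 10],
        "Bifidobacterium": [10, 10, 10, 10],
        "Blautia": [20, 20, 20, 40],
    }
    return pd.DataFrame(
        data, index=["s1", "s2", "s3", "s4"], dtype=int)
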