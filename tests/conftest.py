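import numpy as np
import pandas as pd
import pytest

from tubertrace import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240221)


@pytest.fixture
def small_table():
    """3 samples x 4 ASVs with simple counts."""
    data = pd.DataFrame(
        [[5, 0, 2, 0],
         [1, 3, 0, 0],
         [0, 0, 7, 4]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    meta = pd.DataFrame(
        {
            "sample_type": ["seed_tuber", "seed_tuber", "daughter_tuber"],
            "production_field": ["F1", "F2", "F1"],
            "variety": ["A", "A", "A"],
            "replicate": ["r1", "r1", "r1"],
            "marker": ["16S", "16S", "16S"],
        },
        index=["s1", "s2", "s3"],
    )
    return CountTable(data, meta)


@pytest.fixture
def random_table(rng):
    """20 samples x 50 ASVs of sparse Poisson counts with metadata."""
    counts = rng.poisson(3, size=(20, 50)) * rng.integers(0, 2, size=(20, 50))
    counts[:, 0] += 1  # avoid zero-total rows
    samples = [f"s{i}" for i in range(20)]
    asvs = [f"asv{j}" for j in range(50)]
    meta = pd.DataFrame(
        {
            "sample_type": ["seed_tuber"] * 10 + ["daughter_tuber"] * 10,
            "production_field": (["F1"] * 5 + ["F2"] * 5) * 2,
            "variety": ["A"] * 20,
            "replicate": [f"r{i % 5}" for i in range(20)],
            "marker": ["16S"] * 20,
        },
        index=samples,
    )
    return CountTable(pd.DataFrame(counts, index=samples, columns=asvs), meta)
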