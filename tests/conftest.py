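import numpy as np
import pytest

from dabench.core import CountTable, SampleMetadata, validate_experiment


@pytest.fixture
def small_table():
    rng = np.random.default_rng(0)
    counts = rng.poisson(20, size=(12, 8))
    return CountTable([f"f{i}" for i in range(12)],
                      [f"s{j}" for j in range(8)], counts)


@pytest.fixture
def two_group_exp(small_table):
    meta = SampleMetadata.from_groups(small_table.sample_ids,
                                      ["A"] * 4 + ["B"] * 4)
    return validate_experiment(small_table, meta, "group")


def random_table(seed, m=20, n=6, mean=30):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean, size=(m, n))
    return CountTable([f"f{i}" for i in range(m)],
                      [f"s{j}" for j in range(n)], counts)
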