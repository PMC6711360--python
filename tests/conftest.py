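import numpy as np
import pandas as pd
import pytest

import phylosym as ps


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic survey (93 samples), shared across tests."""
    table, info, taxonomy = ps.simulate_count_table(ps.GeneratorConfig(seed=20140101))
    return table, info, taxonomy


@pytest.fixture(scope="session")
def rarefied_dataset(default_dataset):
    table, info, taxonomy = default_dataset
    filtered = ps.filter_min_depth(table, 20_000)
    rarefied = ps.rarefy(filtered, 20_000, seed=7)
    return rarefied, info.for_samples(rarefied.sample_ids), taxonomy


@pytest.fixture
def toy_table():
    data = pd.DataFrame(
        [[6, 4, 0], [2, 8, 0], [0, 0, 10]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3"],
    )
    return ps.CountTable(data)


def random_nested_tree(labels, rng):
    from phylosym.phylosymbiosis import random_nested_topology

    return random_nested_topology(labels, rng)
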