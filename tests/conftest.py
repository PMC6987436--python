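import numpy as np
import pandas as pd
import pytest

from micronet.core import AbundanceTable
from micronet.network import SignedNetwork
from micronet.synthetic import CohortSpec, coupled_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default two-group synthetic cohort, shared across tests."""
    return coupled_cohort(CohortSpec(), seed=7)


@pytest.fixture(scope="session")
def merged_cohort_table(cohort):
    table_a, table_b, _, _ = cohort
    counts = table_a.counts.join(table_b.counts)
    labels = {**table_a.group_labels, **table_b.group_labels}
    return AbundanceTable(counts, labels)


@pytest.fixture
def toy_table():
    """5 taxa x 6 samples, two groups of 3, hand-checkable."""
    counts = pd.DataFrame(
        [
            [10, 12, 8, 3, 4, 5],
            [0, 5, 6, 7, 0, 9],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 0, 2, 3, 4],
            [9, 2, 5, 7, 2, 1],
        ],
        index=[f"t{i}" for i in range(1, 6)],
        columns=[f"s{j}" for j in range(1, 7)],
    )
    labels = {f"s{j}": ("G1" if j <= 3 else "G2") for j in range(1, 7)}
    return AbundanceTable(counts, labels)


def random_signed_network(n_nodes: int, p_edge: float, seed: int) -> SignedNetwork:
    rng = np.random.default_rng(seed)
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(-1, 1)
    return SignedNetwork([f"n{i:02d}" for i in range(n_nodes)], w)


@pytest.fixture
def random_network():
    return random_signed_network(20, 0.3, seed=11)
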