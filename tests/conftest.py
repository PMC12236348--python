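import numpy as np
import pandas as pd
import pytest

import gestnet as gn


@pytest.fixture(scope="session")
def default_gt():
    return gn.make_ground_truth()


@pytest.fixture(scope="session")
def subscales_1000(default_gt):
    """One mid-size synthetic subscale table shared across tests."""
    return gn.simulate_subscales(default_gt, 1000, seed=11)


@pytest.fixture(scope="session")
def network_1000(subscales_1000):
    """Edge-selected network on the shared table (modest bootstrap)."""
    return gn.bootstrap_edge_selection(subscales_1000, n_boot=300, seed=5)


@pytest.fixture(scope="session")
def partition_1000(network_1000):
    return gn.fast_greedy(network_1000)


def random_pd_correlation(rng, p):
    """Random positive-definite correlation matrix (for oracle tests)."""
    a = rng.standard_normal((p, p + 3))
    s = a @ a.T / (p + 3)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
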