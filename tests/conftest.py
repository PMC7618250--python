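import numpy as np
import pandas as pd
import pytest

import flocknet as fn
from flocknet.flocks import GroupByIndividual


@pytest.fixture(scope="session")
def small_experiment():
    """A small two-site simulated study shared across tests."""
    cfg = fn.SimConfig(
        n_sites=2,
        birds_per_site=15,
        days_pre=3,
        days_exp=5,
        flock_rate=1.0,
        seed=42,
    )
    pop, design, visits, truth = fn.simulate_experiment(cfg, min_records=10)
    return cfg, pop, design, visits, truth


def random_gbi(rng: np.random.Generator, n_birds: int, n_events: int) -> GroupByIndividual:
    """Random binary GBI where every event has at least one member."""
    mat = (rng.random((n_events, n_birds)) < rng.uniform(0.15, 0.6)).astype(np.int8)
    empty = mat.sum(axis=1) == 0
    mat[empty, rng.integers(0, n_birds, size=int(empty.sum()))] = 1
    tags = [f"b{i:02d}" for i in range(n_birds)]
    return GroupByIndividual(matrix=mat, tags=tags)


@pytest.fixture
def gbi_factory():
    return random_gbi


def sri_bruteforce(gbi: GroupByIndividual) -> np.ndarray:
    """Independent pairwise recount of the simple ratio index."""
    n = gbi.n_tags
    w = np.zeros((n, n))
    rows = gbi.matrix.astype(bool)
    for a in range(n):
        for b in range(a + 1, n):
            together = int(np.sum(rows[:, a] & rows[:, b]))
            either = int(np.sum(rows[:, a] | rows[:, b]))
            if either:
                w[a, b] = w[b, a] = together / either
    return w


def network_from_edges(nodes, edges) -> fn.SocialNetwork:
    """Build a SocialNetwork from (a, b, weight) triples."""
    index = {t: i for i, t in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, weight in edges:
        w[index[a], index[b]] = w[index[b], index[a]] = weight
    return fn.SocialNetwork(nodes=list(nodes), weights=w)


@pytest.fixture
def net_factory():
    return network_from_edges
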