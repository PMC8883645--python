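"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use naive enumeration (double loops over node
pairs, explicit contingency tables, restricted-growth-string partition
enumeration) so they stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from hicmag.contact_map import ContactMap
from hicmag.synthetic import CommunitySpec, simulate_community


# ------------------------------------------------------------------ fixtures

@pytest.fixture(scope="session")
def default_community():
    """The default synthetic community, shared read-only across tests."""
    return simulate_community(CommunitySpec(seed=0))


@pytest.fixture(scope="session")
def small_community():
    """A smaller 5-species community for fast pipeline-level tests."""
    return simulate_community(
        CommunitySpec(n_species=5, contigs_per_species=20, seed=7)
    )


@pytest.fixture
def two_clique_map():
    """Two unit-weight 4-cliques joined by a single unit edge."""
    n = 8
    a = np.zeros((n, n))
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            a[i, j] = a[j, i] = 1.0
    a[3, 4] = a[4, 3] = 1.0
    return ContactMap([f"c{i}" for i in range(n)], a)


# ------------------------------------------------------------------- oracles

def brute_force_pair_counts(truth: list, pred: list) -> tuple[int, int, int]:
    """TP/FP/FN over all unordered element pairs, by explicit double loop."""
    tp = fp = fn = 0
    n = len(truth)
    for i in range(n):
        for j in range(i + 1, n):
            same_t = truth[i] == truth[j]
            same_p = pred[i] == pred[j]
            if same_t and same_p:
                tp += 1
            elif same_p:
                fp += 1
            elif same_t:
                fn += 1
    return tp, fp, fn


def brute_force_fowlkes_mallows(truth: list, pred: list) -> float:
    tp, fp, fn = brute_force_pair_counts(truth, pred)
    denom = math.sqrt((tp + fp) * (tp + fn))
    return tp / denom if denom else 0.0


def brute_force_ari(truth: list, pred: list) -> float:
    """ARI from the contingency-table comb(., 2) formula."""
    n = len(truth)
    cont = Counter(zip(truth, pred))
    a = Counter(truth)
    b = Counter(pred)
    sum_nij = sum(math.comb(v, 2) for v in cont.values())
    sum_a = sum(math.comb(v, 2) for v in a.values())
    sum_b = sum(math.comb(v, 2) for v in b.values())
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_nij == expected else 0.0
    return (sum_nij - expected) / (max_index - expected)


def brute_force_nmi(truth: list, pred: list) -> float:
    """2 I(U;V) / (H(U) + H(V)) from the explicit contingency distribution."""
    n = len(truth)
    cont = Counter(zip(truth, pred))
    a = Counter(truth)
    b = Counter(pred)
    h_u = -sum(c / n * math.log(c / n) for c in a.values())
    h_v = -sum(c / n * math.log(c / n) for c in b.values())
    if h_u == 0 and h_v == 0:
        return 1.0
    mi = 0.0
    for (u, v), c in cont.items():
        p_uv = c / n
        mi += p_uv * math.log(p_uv / ((a[u] / n) * (b[v] / n)))
    return 2 * mi / (h_u + h_v)


def brute_force_potts_modularity(weights: np.ndarray, membership, gamma: float) -> float:
    """Double loop over all ordered node pairs, including i == j."""
    a = np.asarray(weights, dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = a.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += a[i, j] - gamma * k[i] * k[j] / two_m
    return q


def all_set_partitions(items: list):
    """Enumerate every set partition via restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def rec(pos: int, max_used: int):
        if pos == n:
            blocks: dict[int, list] = {}
            for idx, g in enumerate(rgs):
                blocks.setdefault(g, []).append(items[idx])
            yield list(blocks.values())
            return
        for g in range(max_used + 2):
            rgs[pos] = g
            yield from rec(pos + 1, max(max_used, g))

    yield from rec(1, 0)


def random_partition_pair(rng: np.random.Generator, max_n: int = 12):
    """A random (truth, pred) labeling pair of size 2..max_n."""
    n = int(rng.integers(2, max_n + 1))
    truth = rng.integers(0, int(rng.integers(1, n + 1)), size=n).tolist()
    pred = rng.integers(0, int(rng.integers(1, n + 1)), size=n).tolist()
    return truth, pred


def random_weighted_map(rng: np.random.Generator, max_nodes: int = 6) -> ContactMap:
    """A random symmetric weighted graph with at least one edge."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        a = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.7), k=1)
        a = a + a.T
        if a.sum() > 0:
            return ContactMap([f"n{i}" for i in range(n)], a)
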