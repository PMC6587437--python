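"""Shared fixtures and independent brute-force oracles.

The oracles here are literal transcriptions of the defining formulas
(triple loops, pair enumeration) and never share code with the package's
vectorized implementations they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from commpat.connectivity import BinaryNetwork
from commpat.detection import Partition


# ---------------------------------------------------------------- oracles

def naive_metrics(adj: np.ndarray, membership: np.ndarray) -> dict[str, float]:
    """Direct loop transcription of the five quality functions."""
    n = len(membership)
    comms = sorted(set(membership.tolist()))
    a1 = adj.astype(float).copy()
    np.fill_diagonal(a1, 1.0)
    a0 = adj.astype(float).copy()
    np.fill_diagonal(a0, 0.0)

    m = sum(a0[i, j] for i in range(n) for j in range(i + 1, n))
    deg = [sum(a0[i, j] for j in range(n)) for i in range(n)]

    # modularity
    q = 0.0
    if m > 0:
        for k in comms:
            nodes = [i for i in range(n) if membership[i] == k]
            internal = sum(a0[i, j] for i in nodes for j in nodes if i < j)
            mk = sum(deg[i] for i in nodes)
            q += 2 * internal / (2 * m) - (mk / (2 * m)) ** 2

    # global density
    num_i = den_i = num_e = den_e = 0.0
    for k in comms:
        nodes = [i for i in range(n) if membership[i] == k]
        others = [i for i in range(n) if membership[i] != k]
        num_i += sum(a1[x, y] for x in nodes for y in nodes)
        den_i += len(nodes) ** 2
        num_e += sum(a1[x, y] for x in nodes for y in others)
        den_e += len(nodes) * len(others)
    qgd_e = num_e / den_e if den_e > 0 else 0.0
    qgd = 0.5 * (num_i / den_i + 1.0 - qgd_e)

    # local density
    qld = 0.0
    for k in comms:
        nodes = [i for i in range(n) if membership[i] == k]
        others = [i for i in range(n) if membership[i] != k]
        qi = sum(a1[x, y] for x in nodes for y in nodes) / len(nodes) ** 2
        if others:
            qe = sum(a1[x, y] for x in nodes for y in others) / (len(nodes) * len(others))
        else:
            qe = 0.0
        qld += len(nodes) / (2.0 * n) * (qi + 1.0 - qe)

    # distance-based
    total = 0.0
    for x in range(n):
        for y in range(n):
            av = 1.0 if membership[x] == membership[y] else 0.0
            total += abs(a1[x, y] - av)
    qdb = total / n**2

    # node membership
    s = 0.0
    for x in range(n):
        own = [y for y in range(n) if membership[y] == membership[x]]
        rest = [y for y in range(n) if membership[y] != membership[x]]
        mu_own = sum(a1[x, y] for y in own) / len(own)
        mu_rest = sum(a1[x, y] for y in rest) / len(rest) if rest else 0.0
        s += mu_own + 1.0 - mu_rest
    qnm = s / (2.0 * n)

    return {"Q": q, "QGD": qgd, "QLD": qld, "QDB": qdb, "QNM": qnm}


def brute_rand(u, v) -> float:
    """Pair-by-pair Rand index over all C(N,2) node pairs."""
    u = list(u)
    v = list(v)
    n = len(u)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (u[i] == u[j]) == (v[i] == v[j]):
                agree += 1
    return agree / total


# --------------------------------------------------------------- builders

def random_graph(rng: np.random.Generator, n: int, p: float) -> BinaryNetwork:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(np.int8)
    return BinaryNetwork(adj, 0.5)


def random_partition(rng: np.random.Generator, n: int, kmax: int) -> Partition:
    k = int(rng.integers(1, min(kmax, n) + 1))
    membership = rng.integers(0, k, size=n)
    return Partition(tuple(int(c) + 1 for c in membership))


def clique_graph(sizes: list[int]) -> tuple[BinaryNetwork, Partition]:
    """Disjoint cliques and their natural partition."""
    n = sum(sizes)
    adj = np.zeros((n, n), dtype=np.int8)
    membership = []
    start = 0
    for k, s in enumerate(sizes):
        adj[start:start + s, start:start + s] = 1
        membership.extend([k + 1] * s)
        start += s
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, 0.5), Partition(tuple(membership))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
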