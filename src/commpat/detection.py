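"""Community detection by Newman's leading-eigenvector spectral method.

The network is recursively bisected using the leading eigenvector of the
generalized modularity matrix, with a deterministic single-node-move
refinement after each split.  Every choice that a naive spectral method
leaves ambiguous (eigenvector sign, scan order, tie handling) is pinned
down so repeated runs give identical partitions.  An exhaustive
set-partition oracle is provided for graphs with at most 10 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import BinaryNetwork

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one non-empty community.

    Stored in canonical form: communities are numbered 1..K in order of
    their lowest-index member.
    """

    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", canonicalize(self.assignment))

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def n_communities(self) -> int:
        return max(self.assignment) if self.assignment else 0

    def members(self, k: int) -> list[int]:
        return [i for i, c in enumerate(self.assignment) if c == k]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype=int)

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels or [f"n{i}" for i in range(self.n)]
        return pd.DataFrame({"node_label": labels, "community_id": self.assignment})


def canonicalize(assignment) -> tuple[int, ...]:
    """Renumber community ids 1..K in order of each community's lowest member."""
    mapping: dict[int, int] = {}
    out = []
    for c in assignment:
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out.append(mapping[c])
    return tuple(out)


def _modularity_from_membership(adj: np.ndarray, membership: np.ndarray, m: int) -> float:
    if m == 0:
        return 0.0
    q = 0.0
    deg = adj.sum(axis=1)
    for k in np.unique(membership):
        idx = membership == k
        internal2 = adj[np.ix_(idx, idx)].sum()  # 2 * internal edges
        dk = deg[idx].sum()
        q += internal2 / (2.0 * m) - (dk / (2.0 * m)) ** 2
    return float(q)


def _leading_eig(bg: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(bg)
    v = vecs[:, -1]
    # sign convention: lowest-index nonzero entry made nonnegative
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return float(vals[-1]), v


def _refine(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin refinement of a bisection (Newman-style).

    Each pass tentatively moves every node exactly once, always picking the
    unmoved node with the largest gain in s^T B s (even if negative, which
    lets the pass tunnel through local optima; ties resolve to the lowest
    index).  The best intermediate state with both sides non-empty is kept
    if it improves on the pass's starting point; passes repeat to a fixed
    point.
    """
    s = s.copy()
    n = len(s)
    diag = np.diag(bg).copy()
    obj = float(s @ bg @ s)
    for _ in range(100):  # passes repeat to a fixed point; hard cap for safety
        s_work = s.copy()
        g = bg @ s_work
        moved = np.zeros(n, dtype=bool)
        order = []
        cum = 0.0
        best_cum, best_step = 0.0, -1
        for step in range(n):
            # flipping s_i changes s^T B s by -4 s_i * sum_{j != i} B_ij s_j
            gains = -4.0 * s_work * (g - diag * s_work)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            cum += gains[i]
            s_work[i] = -s_work[i]
            g += 2.0 * s_work[i] * bg[:, i]
            moved[i] = True
            order.append(i)
            if cum > best_cum and not np.all(s_work == s_work[0]):
                best_cum, best_step = cum, step
        if best_step < 0:
            return s
        candidate = s.copy()
        for i in order[: best_step + 1]:
            candidate[i] = -candidate[i]
        # accept only a genuine improvement of the recomputed objective,
        # immune to incremental floating-point drift
        cand_obj = float(candidate @ bg @ candidate)
        if cand_obj <= obj + 1e-9:
            return s
        s, obj = candidate, cand_obj
    return s


def _bisect(
    adj: np.ndarray,
    deg: np.ndarray,
    m: int,
    nodes: np.ndarray,
    refine: bool,
    out: list[list[int]],
) -> None:
    if len(nodes) == 1:
        out.append(list(nodes))
        return
    sub = adj[np.ix_(nodes, nodes)].astype(float)
    k = deg[nodes]
    b = sub - np.outer(k, k) / (2.0 * m)
    bg = b - np.diag(b.sum(axis=1))  # generalized modularity matrix
    lam, v = _leading_eig(bg)
    if lam <= _EIG_TOL:
        out.append(list(nodes))
        return
    s = np.where(v >= 0, 1.0, -1.0)
    if refine:
        s = _refine(bg, s)
    dq = s @ bg @ s / (4.0 * m)
    if dq <= 1e-13 or np.all(s == s[0]):
        out.append(list(nodes))
        return
    _bisect(adj, deg, m, nodes[s > 0], refine, out)
    _bisect(adj, deg, m, nodes[s < 0], refine, out)


def _q_of_membership(adj: np.ndarray, memb: np.ndarray, deg: np.ndarray, m: int) -> float:
    q = 0.0
    for k in np.unique(memb):
        idx = memb == k
        q += adj[np.ix_(idx, idx)].sum() / (2.0 * m) - (deg[idx].sum() / (2.0 * m)) ** 2
    return float(q)


def _multiway_refine(
    adj: np.ndarray, deg: np.ndarray, m: int, memb: np.ndarray
) -> np.ndarray:
    """Kernighan-Lin pass over the whole partition.

    Every node is tentatively moved once per pass to its best target
    community (an empty community is always available, so new communities
    can nucleate); moves may be individually worsening, and the best
    intermediate partition is kept if it genuinely improves modularity.
    This recovers optima that recursive bisection cannot reach because they
    cross the first cut.  Deterministic: ties resolve to the lowest
    (node index, community id) pair.
    """
    memb = memb.copy()
    n = len(memb)
    obj = _q_of_membership(adj, memb, deg, m)
    for _ in range(100):
        work = memb.copy()
        k = int(work.max()) + 1
        onehot = np.zeros((n, k + 1))
        onehot[np.arange(n), work] = 1.0
        e = adj @ onehot                # edges from node i to community c
        d = deg @ onehot                # total degree per community
        moved = np.zeros(n, dtype=bool)
        cum = 0.0
        best_cum, best_step = 0.0, -1
        states: list[tuple[int, int, int]] = []  # (node, from, to)
        for _step in range(n):
            ecur = e[np.arange(n), work]
            dcur = d[work]
            # gain of moving i from its community a to c:
            # (e_ic - e_ia)/m - deg_i (d_c - d_a + deg_i) / (2 m^2)
            gains = (e - ecur[:, None]) / m \
                - deg[:, None] * (d[None, :] - dcur[:, None] + deg[:, None]) / (2.0 * m**2)
            gains[np.arange(n), work] = -np.inf
            gains[moved] = -np.inf
            flat = int(np.argmax(gains))
            i, c = divmod(flat, e.shape[1])
            a = int(work[i])
            cum += gains[i, c]
            work[i] = c
            e[:, a] -= adj[:, i]
            e[:, c] += adj[:, i]
            d[a] -= deg[i]
            d[c] += deg[i]
            moved[i] = True
            states.append((i, a, c))
            if cum > best_cum:
                best_cum, best_step = cum, _step
            if c == e.shape[1] - 1:  # used the empty slot: provide a fresh one
                e = np.column_stack([e, np.zeros(n)])
                d = np.append(d, 0.0)
        if best_step < 0:
            return memb
        candidate = memb.copy()
        for i, _a, c in states[: best_step + 1]:
            candidate[i] = c
        candidate = np.unique(candidate, return_inverse=True)[1]
        cand_obj = _q_of_membership(adj, candidate, deg, m)
        if cand_obj <= obj + 1e-10:
            return memb
        memb, obj = candidate, cand_obj
    return memb


def detect_communities(net: BinaryNetwork, refine: bool = True) -> Partition:
    """Partition a binary network by leading-eigenvector recursive bisection.

    Each connected component is processed independently (modularity
    optimization never merges components).  After each candidate split a
    deterministic Kernighan-Lin refinement of the bisection runs to a fixed
    point, and a final whole-partition node-moving pass polishes the result
    (``refine`` toggles both).  Splitting stops when the leading eigenvalue
    of the generalized modularity matrix is non-positive or the split does
    not increase modularity.  Isolated nodes become singleton communities;
    an edgeless network yields all singletons.
    """
    adj = net.adjacency.astype(float)
    n = net.n
    m = net.n_edges
    if m == 0:
        return Partition(tuple(range(1, n + 1)))
    deg = adj.sum(axis=1)
    n_comp, comp_labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[list[int]] = []
    for c in range(n_comp):
        nodes = np.flatnonzero(comp_labels == c)
        _bisect(adj, deg, m, nodes, refine, groups)
    assignment = np.zeros(n, dtype=int)
    for gid, nodes in enumerate(groups):
        assignment[nodes] = gid
    if refine:
        assignment = _multiway_refine(adj, deg, m, assignment)
    return Partition(tuple(int(a) + 1 for a in assignment))


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as restricted-growth strings."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[0..i-1])
    while True:
        yield a
        # next RGS in lexicographic order
        i = n - 1
        while i > 0:
            if a[i] <= b[i]:
                break
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = max(b[j - 1], a[j - 1])


def exhaustive_max_modularity(net: BinaryNetwork) -> Partition:
    """Globally maximize modularity by enumerating all set partitions.

    Only feasible for n <= 10 (Bell(10) = 115,975 partitions); larger inputs
    are refused.  Ties are broken toward the lexicographically smallest
    canonical assignment, which is the enumeration order itself.
    """
    n = net.n
    if n > 10:
        raise ValueError(f"exhaustive search refused for n={n} > 10")
    adj = net.adjacency.astype(float)
    m = net.n_edges
    if m == 0:
        return Partition(tuple(range(1, n + 1)))
    deg = adj.sum(axis=1)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    two_m = 2.0 * m
    best_q = -np.inf
    best: tuple[int, ...] | None = None
    for a in _set_partitions(n):
        k_count = max(a) + 1
        internal = [0.0] * k_count
        dsum = [0.0] * k_count
        for i, j in edges:
            if a[i] == a[j]:
                internal[a[i]] += 1.0
        for i in range(n):
            dsum[a[i]] += deg[i]
        q = sum(2.0 * internal[k] / two_m - (dsum[k] / two_m) ** 2 for k in range(k_count))
        if q > best_q + 1e-12:
            best_q = q
            best = tuple(a)
    assert best is not None
    return Partition(tuple(c + 1 for c in best))


def write_partition_tsv(part: Partition, path, labels: list[str] | None = None) -> None:
    part.to_frame(labels).to_csv(path, sep="\t", index=False)
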