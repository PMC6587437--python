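"""Five community-pattern quality functions for a (network, partition) pair.

Modularity Q compares the within-community edge fraction with its
expectation under a degree-preserving random null.  The other four metrics
contrast within-community density against between-community density in
different ways:

* global density Q_GD — pooled internal density averaged with pooled
  external anti-density;
* local density Q_LD — the same contrast computed per community and
  size-weighted;
* distance-based Q_DB — normalized entrywise L1 distance between the
  adjacency matrix and the ideal block matrix of the partition (0 is
  perfect);
* node membership Q_NM — per-node average affinity to its own community
  versus the rest of the graph.

Convention: the density-family metrics treat the adjacency diagonal as 1
(a node is trivially connected to itself), which is the unique choice
making their stated boundary values (1 for a perfect community structure,
0 for Q_DB) attainable.  Modularity uses the standard zero diagonal.
Degenerate terms with an empty complement (single-community partitions,
a community spanning all nodes) are defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import BinaryNetwork
from .detection import Partition

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Q", "QGD", "QLD", "QDB", "QNM")


@dataclass(frozen=True)
class MetricVector:
    """The five quality values for one (network, partition) pair."""

    q_modularity: float
    q_global_density: float
    q_local_density: float
    q_distance_based: float
    q_node_membership: float
    threshold: float = float("nan")
    subject_id: str = ""

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.q_modularity,
            self.q_global_density,
            self.q_local_density,
            self.q_distance_based,
            self.q_node_membership,
        )


def _community_sums(net: BinaryNetwork, part: Partition):
    """Per-community internal/external degree sums under the diagonal-1 convention."""
    a1 = net.adjacency.astype(float)
    np.fill_diagonal(a1, 1.0)
    c = part.as_array() - 1
    k = part.n_communities
    onehot = np.zeros((net.n, k))
    onehot[np.arange(net.n), c] = 1.0
    block = onehot.T @ a1 @ onehot  # k x k sums of A1 over community pairs
    internal = np.diag(block).copy()
    external = block.sum(axis=1) - internal
    sizes = onehot.sum(axis=0)
    return sizes, internal, external


def modularity(net: BinaryNetwork, part: Partition) -> float:
    """Q = sum_k [ 2|B_k^int| / 2m - (m_k / 2m)^2 ], zero-diagonal adjacency.

    The edgeless network has no defined null model; Q is taken as 0 there
    (logged).
    """
    _check(net, part)
    m = net.n_edges
    if m == 0:
        logger.info("modularity of an edgeless network defined as 0")
        return 0.0
    adj = net.adjacency.astype(float)
    c = part.as_array() - 1
    k = part.n_communities
    onehot = np.zeros((net.n, k))
    onehot[np.arange(net.n), c] = 1.0
    internal2 = np.einsum("ik,ij,jk->k", onehot, adj, onehot)  # 2 * internal edges
    deg_sum = net.degrees() @ onehot
    return float(np.sum(internal2 / (2.0 * m) - (deg_sum / (2.0 * m)) ** 2))


def global_density(net: BinaryNetwork, part: Partition) -> float:
    """Q_GD = [Q_GD_int + 1 - Q_GD_ext] / 2 with pooled denominators."""
    _check(net, part)
    n = net.n
    sizes, internal, external = _community_sums(net, part)
    q_int = internal.sum() / np.sum(sizes**2)
    ext_denom = np.sum(sizes * (n - sizes))
    if ext_denom == 0:  # single community: no external pairs exist
        q_ext = 0.0
    else:
        q_ext = external.sum() / ext_denom
    return float(0.5 * (q_int + 1.0 - q_ext))


def local_density(net: BinaryNetwork, part: Partition) -> float:
    """Q_LD = sum_k |V_k|/(2|V|) * [q_int(V_k) + 1 - q_ext(V_k)]."""
    _check(net, part)
    n = net.n
    sizes, internal, external = _community_sums(net, part)
    q_int = internal / sizes**2
    with np.errstate(divide="ignore", invalid="ignore"):
        q_ext = np.where(sizes < n, external / (sizes * (n - sizes)), 0.0)
    return float(np.sum(sizes / (2.0 * n) * (q_int + 1.0 - q_ext)))


def distance_based(net: BinaryNetwork, part: Partition) -> float:
    """Q_DB = ||A_G - A_V||_1 / |V|^2; 0 for a perfect community structure.

    A_V is the ideal block matrix of the partition (1 for same-community
    pairs, diagonal included); A_G takes the diagonal as 1.
    """
    _check(net, part)
    n = net.n
    sizes, internal, external = _community_sums(net, part)
    # entries are 0/1, so the L1 distance counts disagreements:
    # same-community pairs lacking an edge, plus cross-community edges
    mismatches = np.sum(sizes**2 - internal) + external.sum()
    return float(mismatches / n**2)


def node_membership(net: BinaryNetwork, part: Partition) -> float:
    """Q_NM = (1/2|V|) sum_x [ mu(x, own community) + 1 - mu(x, rest) ]."""
    _check(net, part)
    n = net.n
    a1 = net.adjacency.astype(float)
    np.fill_diagonal(a1, 1.0)
    c = part.as_array() - 1
    sizes = np.bincount(c).astype(float)
    own_size = sizes[c]
    k = part.n_communities
    onehot = np.zeros((n, k))
    onehot[np.arange(n), c] = 1.0
    within = (a1 @ onehot)[np.arange(n), c]
    total = a1.sum(axis=1)
    mu_own = within / own_size
    rest = n - own_size
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_rest = np.where(rest > 0, (total - within) / np.where(rest > 0, rest, 1), 0.0)
    return float(np.sum(mu_own + 1.0 - mu_rest) / (2.0 * n))


def compute_all(
    net: BinaryNetwork,
    part: Partition,
    subject_id: str = "",
    threshold: float | None = None,
) -> MetricVector:
    """Evaluate the five metrics once and package them."""
    return MetricVector(
        modularity(net, part),
        global_density(net, part),
        local_density(net, part),
        distance_based(net, part),
        node_membership(net, part),
        net.threshold if threshold is None else threshold,
        subject_id,
    )


def _check(net: BinaryNetwork, part: Partition) -> None:
    if part.n != net.n:
        raise ValueError(f"partition over {part.n} nodes, network has {net.n}")
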