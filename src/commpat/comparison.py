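"""Rand-index partition similarity and the permutation tests built on it.

The Rand index counts node pairs on which two partitions agree (same
community in both, or different communities in both) out of all C(N,2)
pairs.  Two group-difference tests use it:

* a global test — the pooled mean within-group Rand index over all
  within-group subject pairs, compared with its distribution under random
  relabelings of subjects that preserve group sizes;
* a nodal test — for each node X, every subject's partition is reduced to a
  two-block labeling of the other N-1 nodes (same module as X or not), and
  the same within-group-similarity statistic is tested per node, localizing
  which nodes drive a global difference.

P-values follow the strict rule: the fraction of permutations whose
statistic strictly exceeds the observed one.  A non-strict ``>=`` variant
and an add-one smoothing option are available because the strict rule can
return p = 0 on degenerate data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .detection import Partition
from .group_stats import fdr_bh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    seed: int
    strict: bool
    per_group_means: dict = field(default_factory=dict)
    method: str = "sampled"  # "sampled" | "enumerated"

    def to_dict(self) -> dict:
        return {
            "observed_statistic": self.observed_statistic,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "strict": self.strict,
            "per_group_means": self.per_group_means,
            "method": self.method,
        }


@dataclass(frozen=True)
class NodalTestResult:
    per_node_p: np.ndarray
    per_node_q: np.ndarray
    observed: np.ndarray
    n_permutations: int
    seed: int


def rand_index(u: Partition, r: Partition) -> float:
    """Pair-counting agreement (a + d) / C(N, 2) between two partitions."""
    if u.n != r.n:
        raise ValueError(f"partitions over different node sets ({u.n} vs {r.n})")
    n = u.n
    if n < 2:
        raise ValueError("Rand index needs at least 2 nodes")
    cu = u.as_array()
    cr = r.as_array()
    return _rand_from_codes(cu, cr, n)


def _rand_from_codes(cu: np.ndarray, cr: np.ndarray, n: int) -> float:
    ku = cu.max() + 1
    kr = cr.max() + 1
    cont = np.bincount(cu * kr + cr, minlength=ku * kr).astype(float)
    same_both = np.sum(cont * (cont - 1)) / 2.0
    row = np.bincount(cu).astype(float)
    col = np.bincount(cr).astype(float)
    same_u = np.sum(row * (row - 1)) / 2.0
    same_r = np.sum(col * (col - 1)) / 2.0
    total = n * (n - 1) / 2.0
    # agreements = same_both + d; d = total - (same_u + same_r - same_both)
    return float(1.0 - (same_u + same_r - 2.0 * same_both) / total)


def pairwise_rand_matrix(partitions: list[Partition]) -> np.ndarray:
    """Symmetric matrix of Rand indices over all partition pairs (diag 1)."""
    s = len(partitions)
    r = np.eye(s)
    for i in range(s):
        for j in range(i + 1, s):
            r[i, j] = r[j, i] = rand_index(partitions[i], partitions[j])
    return r


def _group_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    values, codes = np.unique(labels, return_inverse=True)
    if len(values) != 2:
        raise ValueError(f"exactly two groups required, got {list(values)}")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 members")
    return codes


def within_group_mean_rand(
    partitions: list[Partition], labels
) -> tuple[dict[str, float], float]:
    """Mean Rand index over within-group pairs, per group and pooled.

    The pooled statistic averages all within-group pairs of both groups
    together (each pair weighted equally).
    """
    codes = _group_codes(labels)
    rmat = pairwise_rand_matrix(partitions)
    iu, ju = np.triu_indices(len(partitions), k=1)
    vals = rmat[iu, ju]
    names = np.unique(np.asarray(labels))
    per_group: dict[str, float] = {}
    within = codes[iu] == codes[ju]
    for g, name in enumerate(names):
        mask = within & (codes[iu] == g)
        per_group[str(name)] = float(vals[mask].mean())
    pooled = float(vals[within].mean())
    return per_group, pooled


def group_permutation_test(
    partitions: list[Partition],
    labels,
    n_permutations: int = 50_000,
    seed: int = 0,
    strict: bool = True,
    smoothing: bool = False,
    rand_matrix: np.ndarray | None = None,
) -> PermutationResult:
    """Permutation test of the pooled within-group mean Rand index.

    Group labels are shuffled preserving group sizes; the statistic is
    recomputed from the precomputed pairwise Rand matrix.  When the number
    of distinct group-preserving label arrangements is at most
    ``n_permutations`` the null is enumerated exactly instead of sampled.
    """
    codes = _group_codes(labels)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    s = len(partitions)
    rmat = pairwise_rand_matrix(partitions) if rand_matrix is None else rand_matrix
    iu, ju = np.triu_indices(s, k=1)
    vals = rmat[iu, ju]

    def stat(c: np.ndarray) -> float:
        within = c[iu] == c[ju]
        return float(vals[within].mean())

    observed = stat(codes)
    names = np.unique(np.asarray(labels))
    per_group = {
        str(name): float(vals[(codes[iu] == g) & (codes[ju] == g)].mean())
        for g, name in enumerate(names)
    }

    n_case = int(codes.sum())
    total_arrangements = comb(s, n_case)
    if total_arrangements <= n_permutations:
        null = np.empty(total_arrangements)
        for t, pos in enumerate(combinations(range(s), n_case)):
            c = np.zeros(s, dtype=int)
            c[list(pos)] = 1
            null[t] = stat(c)
        method = "enumerated"
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for t in range(n_permutations):
            null[t] = stat(rng.permutation(codes))
        method = "sampled"

    exceed = int(np.sum(null > observed)) if strict else int(np.sum(null >= observed))
    denom = len(null)
    p = (exceed + 1) / (denom + 1) if smoothing else exceed / denom
    return PermutationResult(
        observed, float(null.mean()), float(null.std(ddof=0)), float(p),
        denom, seed, strict, per_group, method,
    )


def node_community_labeling(part: Partition, x: int) -> np.ndarray:
    """Binary vector over the other N-1 nodes: 1 iff same community as x."""
    if not (0 <= x < part.n):
        raise ValueError(f"node index {x} out of range")
    a = part.as_array()
    same = (a == a[x]).astype(int)
    return np.delete(same, x)


def _nodal_rand_tensor(partitions: list[Partition]) -> np.ndarray:
    """Per-node pairwise Rand similarities, shape (n_nodes, n_subj, n_subj).

    For node x and subjects (s, t), entry is the Rand index between the
    two-block partitions of the other N-1 nodes induced by "same module
    as x" in each subject's partition.
    """
    n_subj = len(partitions)
    n = partitions[0].n
    same = np.stack([
        p.as_array()[:, None] == p.as_array()[None, :] for p in partitions
    ])  # (n_subj, n, n) boolean, diagonal True
    big_n = n - 1
    total_pairs = big_n * (big_n - 1) / 2.0
    out = np.ones((n, n_subj, n_subj))
    for s in range(n_subj):
        ss = same[s]
        n1s = ss.sum(axis=1) - 1  # "same as x" count among the other nodes
        for t in range(s + 1, n_subj):
            st = same[t]
            n11 = np.logical_and(ss, st).sum(axis=1) - 1
            n1t = st.sum(axis=1) - 1
            n10 = n1s - n11
            n01 = n1t - n11
            n00 = big_n - n11 - n10 - n01
            a = (n11 * (n11 - 1) + n10 * (n10 - 1)
                 + n01 * (n01 - 1) + n00 * (n00 - 1)) / 2.0
            same_u = (n1s * (n1s - 1) + (big_n - n1s) * (big_n - n1s - 1)) / 2.0
            same_r = (n1t * (n1t - 1) + (big_n - n1t) * (big_n - n1t - 1)) / 2.0
            ri = 1.0 - (same_u + same_r - 2.0 * a) / total_pairs
            out[:, s, t] = out[:, t, s] = ri
    return out


def nodal_permutation_test(
    partitions: list[Partition],
    labels,
    n_permutations: int = 10_000,
    seed: int = 0,
    strict: bool = True,
) -> NodalTestResult:
    """Per-node permutation test of within-group nodal Rand similarity.

    One shared stream of group-size-preserving label permutations is applied
    to all nodes jointly; per-node p-values get Benjamini-Hochberg adjusted
    companions.
    """
    codes = _group_codes(labels)
    n_subj = len(partitions)
    tensor = _nodal_rand_tensor(partitions)
    iu, ju = np.triu_indices(n_subj, k=1)
    pairvals = tensor[:, iu, ju]  # (n_nodes, n_pairs)
    within = codes[iu] == codes[ju]
    observed = pairvals[:, within].mean(axis=1)

    rng = np.random.default_rng(seed)
    n_nodes = pairvals.shape[0]
    exceed = np.zeros(n_nodes)
    chunk = 512
    done = 0
    n_within = int(within.sum())
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        masks = np.empty((b, len(iu)))
        for t in range(b):
            c = rng.permutation(codes)
            masks[t] = c[iu] == c[ju]
        null_stats = pairvals @ masks.T / n_within  # (n_nodes, b)
        if strict:
            exceed += (null_stats > observed[:, None]).sum(axis=1)
        else:
            exceed += (null_stats >= observed[:, None]).sum(axis=1)
        done += b
    p = exceed / n_permutations
    q = fdr_bh(p)
    return NodalTestResult(p, q, observed, n_permutations, seed)
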