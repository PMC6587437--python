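"""The five community-quality metrics on networks with known structure.

Evaluates modularity (Q), global density (QGD), local density (QLD), the
distance-based metric (QDB) and node membership (QNM) on a perfect
modular graph and on a degraded version of it.
"""

import numpy as np

from commpat import BinaryNetwork, Partition, compute_all, METRIC_NAMES

# perfect structure: two disjoint cliques of 5
adj = np.zeros((10, 10), dtype=int)
adj[:5, :5] = 1
adj[5:, 5:] = 1
np.fill_diagonal(adj, 0)
part = Partition((1,) * 5 + (2,) * 5)
perfect = compute_all(BinaryNetwork(adj, 0.5), part)
print("perfect  ", dict(zip(METRIC_NAMES, np.round(perfect.as_tuple(), 3))))

# degrade: remove half the internal edges, add cross-links
rng = np.random.default_rng(0)
noisy = adj.copy()
for i, j in [(0, 1), (1, 2), (2, 3), (5, 6), (7, 8)]:
    noisy[i, j] = noisy[j, i] = 0
for i, j in [(0, 5), (1, 6), (2, 7)]:
    noisy[i, j] = noisy[j, i] = 1
degraded = compute_all(BinaryNetwork(noisy, 0.5), part)
print("degraded ", dict(zip(METRIC_NAMES, np.round(degraded.as_tuple(), 3))))
# Perfect structure pins the boundary values (QGD = QLD = QNM = 1, QDB = 0);
# degradation pushes every metric toward chance, QDB rising because it
# counts disagreements with the ideal block matrix.
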