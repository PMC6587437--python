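"""Pearson connectivity matrices and their binarization into sparse graphs.

Per-subject functional connectivity is the ROI-by-ROI Pearson correlation of
the time courses; group networks are element-wise averages of subject
matrices.  Binarization keeps an edge where the signed correlation strictly
exceeds the sparsity threshold T in [0.1, 0.9]; negative correlations never
produce edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SubjectTimeSeries

logger = logging.getLogger(__name__)

THRESHOLD_RANGE = (0.1, 0.9)


@dataclass
class ConnectivityMatrix:
    """Symmetric correlation matrix with unit diagonal and entries in [-1, 1]."""

    values: np.ndarray
    roi_labels: list[str]
    provenance: str = "subject"  # "subject" | "group_average"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric within 1e-12")
        if np.abs(v).max() > 1 + 1e-12:
            raise ValueError("correlation entries must have |r| <= 1")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("diagonal must be exactly 1")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        self.values = v
        if len(self.roi_labels) != v.shape[0]:
            raise ValueError("roi_labels length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.roi_labels)


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at a recorded sparsity threshold."""

    adjacency: np.ndarray
    threshold: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.diag(a).any():
            raise ValueError("stored diagonal must be zero")
        self.adjacency = a.astype(np.int8)
        if not self.roi_labels:
            self.roi_labels = [f"n{i}" for i in range(a.shape[0])]
        if len(self.roi_labels) != a.shape[0]:
            raise ValueError("roi_labels length mismatch")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(float)


def pearson_connectivity(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """ROI-by-ROI Pearson correlation of one subject's time courses.

    A zero-variance column correlates 0 with every other column (diagonal
    stays 1); this degenerate case is logged rather than raised so batch
    runs survive pathological inputs.
    """
    x = ts.series
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = x.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if degenerate.size:
        logger.warning(
            "subject %s: zero-variance ROI column(s) %s; correlations set to 0",
            ts.subject_id, degenerate.tolist(),
        )
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(ts.roi_labels), "subject", ts.subject_id)


def group_average(
    mats: list[ConnectivityMatrix], fisher_z: bool = False
) -> ConnectivityMatrix:
    """Element-wise mean of subject matrices (the group-average network).

    ``fisher_z=True`` averages on the arctanh scale instead of the plain
    arithmetic mean; off by default.
    """
    if not mats:
        raise ValueError("group_average needs a non-empty list")
    labels = mats[0].roi_labels
    n = mats[0].n
    for m in mats[1:]:
        if m.n != n or m.roi_labels != labels:
            raise ValueError("all matrices must share dimensions and ROI labels")
    stack = np.stack([m.values for m in mats])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        avg = np.tanh(z.mean(axis=0))
    else:
        avg = stack.mean(axis=0)
    np.fill_diagonal(avg, 1.0)
    return ConnectivityMatrix(avg, list(labels), "group_average")


def binarize(
    c: ConnectivityMatrix, t: float, inclusive: bool = False
) -> BinaryNetwork:
    """Threshold a correlation matrix into an undirected binary graph.

    An edge (i, j), i != j, is present iff r_ij > t (strict, on the signed
    correlation — negative correlations never pass; ``inclusive=True``
    switches to r_ij >= t).
    """
    lo, hi = THRESHOLD_RANGE
    if not (lo <= t <= hi):
        raise ValueError(f"threshold must lie in [{lo}, {hi}], got {t}")
    r = c.values
    adj = (r >= t) if inclusive else (r > t)
    adj = adj.astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, float(t), list(c.roi_labels))


def write_matrix_csv(c: ConnectivityMatrix, path) -> None:
    c.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_network_csv(net: BinaryNetwork, path) -> None:
    pd.DataFrame(net.adjacency, columns=net.roi_labels).to_csv(path, index=False)


def write_edgelist_tsv(net: BinaryNetwork, path) -> None:
    i, j = np.nonzero(np.triu(net.adjacency, k=1))
    pd.DataFrame({
        "node_label_1": [net.roi_labels[a] for a in i],
        "node_label_2": [net.roi_labels[b] for b in j],
    }).to_csv(path, sep="\t", index=False)


def read_matrix_csv(path, provenance: str = "subject") -> ConnectivityMatrix:
    df = pd.read_csv(path)
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns), provenance)
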