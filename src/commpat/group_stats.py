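"""Distributional group comparisons of community-metric values.

Two-sample Kolmogorov-Smirnov tests per (metric, threshold) cell, a single
Benjamini-Hochberg FDR correction across the whole family of tests in a
run, and Gaussian kernel-density summaries of each group's metric
distribution (default bandwidth 0.02, the literal standard deviation of
the kernel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import METRIC_NAMES

DEFAULT_KDE_BANDWIDTH = 0.02


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic D = sup|ECDF_x - ECDF_y| and asymptotic p.

    Uses the asymptotic Kolmogorov distribution with the standard effective
    sample size n_x * n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def kde_density(values, grid, bandwidth: float = DEFAULT_KDE_BANDWIDTH) -> np.ndarray:
    """Gaussian-kernel density estimate on a grid.

    ``bandwidth`` is the kernel standard deviation h:
    f(g) = (1/n) sum_i N(g; x_i, h^2).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return dens


def metric_group_table(metrics: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-(metric, threshold) group comparison table with a shared BH family.

    ``metrics`` must hold columns subject_id, group, threshold and the five
    metric columns (Q, QGD, QLD, QDB, QNM).  Every (metric, threshold) cell
    yields group means/SDs and a KS test; BH correction is applied across
    all cells of the run jointly.
    """
    required = {"group", "threshold", *METRIC_NAMES}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    groups = sorted(metrics["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g0, g1 = groups
    rows = []
    for thr in sorted(metrics["threshold"].unique()):
        sub = metrics[metrics["threshold"] == thr]
        a = sub[sub["group"] == g0]
        b = sub[sub["group"] == g1]
        if a.empty or b.empty:
            raise ValueError(f"threshold {thr}: a group is missing")
        for name in METRIC_NAMES:
            d, p = ks_two_sample(a[name], b[name])
            rows.append({
                "metric": name,
                "threshold": thr,
                f"mean_{g0}": float(a[name].mean()),
                f"sd_{g0}": float(a[name].std(ddof=1)),
                f"mean_{g1}": float(b[name].mean()),
                f"sd_{g1}": float(b[name].std(ddof=1)),
                "ks_D": d,
                "p": p,
            })
    table = pd.DataFrame(rows)
    table["q"] = fdr_bh(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table


def kde_table(
    metrics: pd.DataFrame,
    bandwidth: float = DEFAULT_KDE_BANDWIDTH,
    grid_size: int = 201,
) -> pd.DataFrame:
    """Long-format KDE curves per (metric, threshold, group) for plotting."""
    rows = []
    for thr in sorted(metrics["threshold"].unique()):
        sub = metrics[metrics["threshold"] == thr]
        for name in METRIC_NAMES:
            lo = float(sub[name].min()) - 3 * bandwidth
            hi = float(sub[name].max()) + 3 * bandwidth
            grid = np.linspace(lo, hi, grid_size)
            for g in sorted(sub["group"].unique()):
                dens = kde_density(sub.loc[sub["group"] == g, name], grid, bandwidth)
                rows.append(pd.DataFrame({
                    "metric": name, "threshold": thr, "group": g,
                    "grid": grid, "density": dens,
                }))
    return pd.concat(rows, ignore_index=True)
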