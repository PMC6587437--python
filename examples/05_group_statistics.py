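"""KS/FDR group comparison of metric distributions, with KDE summaries.

Computes the five metrics for every subject at two thresholds, tests each
(metric, threshold) cell with a two-sample Kolmogorov-Smirnov test, and
corrects the whole family with Benjamini-Hochberg.
"""

import pandas as pd

from commpat import (
    SyntheticSpec, generate_cohort, pearson_connectivity, binarize,
    detect_communities, compute_all, metric_group_table, kde_density,
    METRIC_NAMES,
)

spec = SyntheticSpec(n_rois=60, block_sizes=(20, 20, 20), n_timepoints=150,
                     delta_rho_in=-0.1, n_per_group=15, seed=5)
cohort = generate_cohort(spec)

rows = []
for t in (0.3, 0.4):
    for s in cohort.subjects:
        net = binarize(pearson_connectivity(s), t)
        mv = compute_all(net, detect_communities(net), s.subject_id)
        rows.append({"subject_id": s.subject_id, "group": s.group, "threshold": t,
                     **dict(zip(METRIC_NAMES, mv.as_tuple()))})
metrics = pd.DataFrame(rows)

table = metric_group_table(metrics)
print(table[["metric", "threshold", "mean_case", "mean_control", "ks_D", "q"]]
      .round(4).to_string(index=False))
print(f"{int(table['significant'].sum())} of {len(table)} cells significant (q < 0.05)")
# The diffuse case-group effect shows up as FDR-significant shifts in the
# density-family metrics; group means tell the direction of the change.

sub = metrics[(metrics["threshold"] == 0.4) & (metrics["group"] == "case")]
dens = kde_density(sub["QGD"], grid=[0.6, 0.8, 1.0], bandwidth=0.02)
print("case QGD density at grid (0.6, 0.8, 1.0):", dens.round(2))
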