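"""Diagnostic classification from community metrics, with feature ranking.

Trains the linear discriminant (and KNN) on the five metric features at
one threshold, evaluates with leave-one-out cross-validation, and ranks
features by recursive feature elimination.
"""

import pandas as pd

from commpat import (
    SyntheticSpec, generate_cohort, pearson_connectivity, binarize,
    detect_communities, compute_all, FeatureTable, cross_validate, rfe_rank,
    METRIC_NAMES,
)

spec = SyntheticSpec(n_rois=90, block_sizes=(30, 30, 30), n_timepoints=150,
                     delta_rho_in=-0.15, n_per_group=20, seed=9)
cohort = generate_cohort(spec)

rows = []
for s in cohort.subjects:
    net = binarize(pearson_connectivity(s), 0.4)
    mv = compute_all(net, detect_communities(net), s.subject_id)
    rows.append({"subject_id": s.subject_id, "group": s.group, "threshold": 0.4,
                 **dict(zip(METRIC_NAMES, mv.as_tuple()))})
feats = FeatureTable.from_metrics(pd.DataFrame(rows), 0.4)

for clf in ("lda", "knn"):
    rep = cross_validate(feats, clf, "loo", seed=0)
    print(f"{clf.upper()} LOO: accuracy {rep.accuracy:.1f}%  "
          f"precision {rep.precision:.1f}%  recall {rep.recall:.1f}%")

ranking = rfe_rank(feats, "lda", seed=0)
for name, score in sorted(ranking.scores.items(), key=lambda kv: -kv[1]):
    print(f"RFE score {name}: {score:.2f}")
# With the planted effect the discriminant separates the groups almost
# perfectly; RFE scores near 1 mark the metrics that carry the signal.
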