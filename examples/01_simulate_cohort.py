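"""Generate a synthetic two-group cohort of ROI time series.

Builds a 60-ROI cohort with three correlation modules; the case group has
weaker within-module correlation (diffuse under-connectivity) and two
nodes reassigned to a neighbouring module (focal community change).
"""

import numpy as np

from commpat import SyntheticSpec, generate_cohort, pearson_connectivity

spec = SyntheticSpec(
    n_rois=60, block_sizes=(20, 20, 20), n_timepoints=150,
    rho_in_control=0.5, rho_out=0.1, delta_rho_in=-0.1,
    affected_nodes=frozenset({0, 1}), n_per_group=10, seed=7,
)
cohort = generate_cohort(spec)
print(f"{len(cohort.subjects)} subjects, "
      f"{sum(s.group == 'case' for s in cohort.subjects)} cases")

blocks = spec.block_assignment("control")
same = (blocks[:, None] == blocks[None, :]) & ~np.eye(60, dtype=bool)
for group in ("control", "case"):
    r = np.mean([
        pearson_connectivity(s).values[same].mean()
        for s in cohort.group_members(group)
    ])
    print(f"mean within-module correlation, {group}: {r:.3f}")
# The case group's mean sits ~0.1 below the control group's: the planted
# diffuse effect survives sampling noise at 150 timepoints.
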