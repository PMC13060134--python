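"""Time-course analysis: filters, normalization, synchronized groups.

Simulates a feeding-study-style feature table with two planted groups of
co-varying metabolites, applies the blank/RT filters and within-tissue
relative abundance, and detects synchronized groups (pairwise Pearson
r >= 0.95 over >= 3 shared timepoints, connected components).
"""

import numpy as np

from carnlib import relative_abundance, synchronized_groups
from carnlib.synthetic_data import simulate_timecourse

template = np.array([2.0, 6.0, 9.0, 5.0, 3.0, 7.0, 10.0, 4.0])
table, truth = simulate_timecourse(
    n_features=30,
    tissues=["liver", "serum"],
    timepoints=list(range(0, 24, 3)),  # every 3 h over a day
    planted_groups=[("liver", 4, template), ("serum", 3, template[::-1])],
    noise_sd=0.02,
    seed=5,
)
print(f"feature table: {table.matrix.shape[0]} features x {table.matrix.shape[1]} samples")

normalized = relative_abundance(table)  # per-feature max within each tissue -> 1.0

for tissue, planted in truth:
    groups = synchronized_groups(normalized, tissue)
    print(f"\n{tissue}: {len(groups)} synchronized group(s); planted members {sorted(planted)}")
    for g in groups:
        hit = "recovers the planted group" if g.members >= planted else "other co-variation"
        print(f"  members {sorted(g.members)}  min pairwise r = {g.pairwise_min_r:.3f}  ({hit})")
# at 2% noise the planted members stay above the r >= 0.95 gate; unrelated
# features only rarely correlate that strongly over 8 timepoints.
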