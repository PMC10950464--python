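"""Replicated sweep: how lineage counts respond to the cluster number k.

Compares the high-oscillation noisy regime with the low-oscillation regime
over a small k grid (desk-scale replication) and prints the distribution of
type-A counts plus the mean type-B count per cell — the stacked-bar and
heatmap quantities of the study design.
"""

import warnings

from cfrlineage import sweep

warnings.simplefilter("ignore", UserWarning)

tab = sweep([1.0, 1000.0], sigma=0.01, ks=[5, 15, 30], n_real=20, master_seed=1)

for alpha in tab.alphas:
    print(f"alpha = {alpha:g}, sigma = {tab.sigma}")
    for ki, k in enumerate(tab.ks):
        dist_a = {c: round(p, 2) for c, p in sorted(tab.dist_a[(alpha, k)].items())}
        mean_b = tab.mean_b[tab.alphas.index(alpha), ki]
        print(f"  k={k:>2}: P(nA) = {dist_a}, mean nB = {mean_b:.2f}")
print(
    "Three type-A lineages is the ground truth; note how extra lineages "
    "start to appear in the oscillatory (alpha=1000) row once k grows, while "
    "coarse clusterings recover exactly three everywhere."
)
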