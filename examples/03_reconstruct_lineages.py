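"""Full lineage reconstruction on one synthetic snapshot.

Clusters a high-oscillation snapshot, builds the cluster MST, extracts
root-to-leaf lineages and prints the per-lineage summary table (length,
elapsed time, terminal |c|^2, type) that separates genuine from spurious
lineages.
"""

from cfrlineage import (
    CFRParams,
    SimSettings,
    build_mst,
    classify_lineages,
    cluster_dataset,
    generate_dataset,
    identify_root,
    lineage_table,
)

ds = generate_dataset(
    CFRParams(alpha=1000.0), settings=SimSettings(sigma=0.01), seed=42
)
clustering = cluster_dataset(ds, k=25, seed=0)
tree = build_mst(clustering.centroids)
tree.root = identify_root(clustering, ds)
lineages = classify_lineages(lineage_table(tree, clustering, ds))

print(f"k = {clustering.k} clusters, root = cluster {tree.root}")
print(f"{'lineage':>8} {'length':>7} {'elapsed t':>10} {'|c|^2':>8} type")
for i, lin in enumerate(sorted(lineages, key=lambda l: -l.terminal_cnorm_sq), 1):
    print(
        f"{i:>8} {lin.length:>7} {lin.elapsed_time:>10.0f} "
        f"{lin.terminal_cnorm_sq:>8.1f} {lin.ltype:>4}"
    )
n_a = sum(l.ltype == "A" for l in lineages)
print(
    f"-> {n_a} type-A (genuine, far-terminating) and {len(lineages) - n_a} "
    "type-B (spurious, near-origin) lineages; the ground truth has exactly 3 fates."
)
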