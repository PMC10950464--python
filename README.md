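# cfrlineage

Oscillatory differentiation dynamics versus cluster/MST lineage
reconstruction: a simulation and analysis toolkit.

Single-cell pseudotime tools typically cluster a snapshot of cells, join
the clusters with a minimum spanning tree, and read lineages off the
root-to-leaf paths. `cfrlineage` asks what happens to that procedure when
the underlying differentiation is *oscillatory* — when a multi-potent cell
cycles through propensities for several fates before committing — and shows
that oscillation places a hard geometric limit on how finely the data may
be clustered before spurious lineages appear, independent of noise. It is
written for computational biologists and modellers who want a controlled,
fully seeded test bed where the ground truth (three fates) is known exactly.

## The model

Cell state is the level triple (x1, x2, x3) of three fate-determining
transcription factors coupled in a "cross-repressilator" — two directed
rings of mutual inhibition with strengths α and β:

    dxᵢ = [ b + g(t) / ((1 + α xⱼʰ)(1 + β xₖʰ)) − d xᵢ ] dt + σ xᵢ dWᵢ,

(i, j, k) cyclic, g(t) = 4t/(t + 2000) the differentiation-driving signal,
defaults b = 10⁻³, β = 0.1, d = 0.1, h = 3. As g rises the symmetric
multi-potent state loses stability through a Hopf bifurcation (the
circulant Jacobian's complex pair has imaginary part ∝ α − β), the
trajectory spirals out visiting all three fates, and finally one TF
dominates. α dials the amount of twisting without changing anything else.

Snapshots of 1200 simulated cells (400 per fate, fate-balanced by cyclic
permutation) are clustered with best-of-50 k-means, joined by a centroid
MST, rooted at the earliest cluster, and every root-to-leaf path is
classified by the squared norm |c|² of its terminal cluster's log-centroid:
**type A** (|c|² > 8, genuine, far-terminating) or **type B** (spurious,
terminating near the multi-potent region).

An exactly solvable planar model (dr/dt = a·r, dθ/dt = b/(1 + c·r))
explains the artifact: spiral arms stay one cluster diameter apart at every
radius iff the per-third-turn expansion ratio E = exp(2πa/(3b)) exceeds 3,
i.e. a/b ≥ (3 ln 3)/(2π) ≈ 0.52. Below that threshold some cluster number
k always manufactures type-B lineages; above it none can.

## Worked example

`examples/03_reconstruct_lineages.py` generates a strongly oscillatory
snapshot (α = 1000, σ = 0.01), clusters it at k = 25 and prints the
per-lineage summary:

```
k = 25 clusters, root = cluster 17
 lineage  length  elapsed t    |c|^2 type
       1       9       1747     37.7    A
       2       9       1732     37.6    A
       3       8       1731     36.6    A
       4       3        730     18.6    A
-> 4 type-A (genuine, far-terminating) and 0 type-B (spurious, near-origin)
   lineages; the ground truth has exactly 3 fates.
```

Three long lineages (8–9 clusters, elapsed time ≈ 1700, |c|² ≈ 37) are the
genuine fates; the fourth, short early-terminating lineage is a
reconstruction artifact of the oscillatory geometry — with more clusters,
or more noise, such extra lineages multiply. The other examples cover
trajectory simulation and stability analysis, snapshot generation and
CSV export, replicated (α, σ, k) sweeps, and the analytic separation
thresholds.

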