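# metpathcomp

Comparative phylogenetics and co-evolution analysis from metabolic
pathway alignments.

Organisms can be compared not only by their sequences but by what their
metabolism *does*. Given, for each organism, a set of pathway instances —
small directed graphs of enzymes labelled by EC numbers — `metpathcomp`
aligns every pair of organisms on every shared pathway, combines the
scores across pathways into a single dissimilarity matrix, and infers a
phylogeny. A second method compares pathways to each other across the
whole organism set to find pathways whose evolutionary histories are
correlated (co-evolution). The package is aimed at systems-biology and
molecular-evolution researchers who have per-organism pathway graphs
(e.g. exported from a pathway database) or precomputed alignment scores.

## Method

**Pages.** For a set of n organisms and m pathways, each pathway k gets a
*page*: an n × n matrix A<sub>·,·,k</sub> where A<sub>ijk</sub> is the
similarity score of aligning pathway k's instance in organism i against
its instance in organism j. Scores are ≤ 0, 0 meaning identical;
self-alignments score exactly 0. Where the pathway is missing, the entry
is the sentinel ONE_MISSING (exactly one organism lacks it) or
BOTH_MISSING (both lack it). The bundled aligner scores a partial
injective node mapping by EC-prefix agreement (−μ·(4 − k) for a common
prefix of k of the four EC fields), a deletion penalty d per unmatched
query node, and a penalty δ per query edge with no corresponding directed
path in the target, maximized exactly by branch-and-bound; precomputed
pages from an external alignment engine can be ingested instead.

**Threshold graphs and weights.** Each page is binarized at a threshold
t: organisms i, j are joined by an edge iff A<sub>ijk</sub> ≥ t, or if
the pathway is absent from both and the confidence parameter b is true
(joint absence read as similarity); a pathway present in exactly one of
the two never yields an edge. Each threshold graph (TG) receives an
entropy-style information weight

&nbsp;&nbsp;&nbsp;&nbsp;w = Σ<sub>v∈V</sub> h(deg(v)/|V|),&nbsp;&nbsp;
h(p) = −p log₂ p − (1 − p) log₂(1 − p),

which vanishes for the two uninformative extremes (no edges at all, or
every degree |V|) and is largest when a pathway splits the organisms into
groups. The page is replaced by the weighted TG adjacency (w on edges, 0
elsewhere), the stack is summed along the pathway axis into a similarity
matrix, every element is subtracted from the maximum to give
dissimilarities, and a neighbor-joining tree is built (in-package
Saitou–Nei with pinned deterministic tie-breaking).

**Co-evolution.** Every page entry falls into one of four appearance
categories: d1 both absent, d2 both present, d3 present in the first
organism only, d4 in the second only. The generalized Hamming distance
H(p₁, p₂) averages a lookup D(x, y) over entries (0 on identical
categories, 2 for d3 vs d4, 1 for one-sided vs shared patterns); the L1
component L(p₁, p₂) is the mean |score difference| where both pathways
are present in both organisms. The combined distance
(W<sub>p</sub>·H + L)/(W<sub>p</sub> + 1) with W<sub>p</sub> = 100 feeds
average-linkage clustering with silhouette-selected cluster count.

A simulator (`metpathcomp.evosim`) evolves pathway repertoires along a
known Yule tree — losses, gains, EC mutations, indels, edge rewires, and
group-coupled presence events — providing ground truth for tree- and
cluster-recovery experiments.

## Worked example

Simulate 8 organisms and 30 pathways diverging by EC mutation only, run
the pipeline, and compare against the generating tree:

```python
from metpathcomp.evosim import SimConfig, simulate, write_simulation
from metpathcomp.cli import run_pipeline
from metpathcomp.phylogeny import read_newick, robinson_foulds

table, truth = simulate(SimConfig.mutation_only(seed=2))
manifest = write_simulation(table, truth, "demo")
run_pipeline(manifest=manifest, t=-3.0, out_dir="demo_out")
tree = read_newick("demo_out/tree.nwk")
print(robinson_foulds(tree, truth.tree))
```

prints `0`: the inferred topology matches the generating tree exactly.
`demo_out/` also holds the dissimilarity matrix (PHYLIP square format),
the run log with every parameter, and the pathway weight ranking — the
pathways whose threshold graphs carry the most information about how the
organisms split into groups:

```
pathway_id      weight
p08     7.720146130309063
p23     7.629014136158993
p29     7.629014136158993
```

The same pipeline is available from the shell:

```
metpathcomp simulate --n 8 --m 30 --seed 2 --out demo
metpathcomp run --manifest demo/manifest.json --out demo_out
metpathcomp coevolve --manifest demo/manifest.json --out cm.tsv --clusters clusters.tsv
```

On a simulation with two planted co-evolving pathway groups
(`SimConfig.coevolving(seed=42)`, coupling ρ = 0.9), the co-evolution
matrix clusters into exactly `k = 2` groups that reproduce the planted
15 + 15 bipartition perfectly.

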