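# Methods

## Model and assumptions

The pipeline treats an organism's metabolism as a bag of pathway
instances: directed acyclic graphs whose nodes are enzymes labelled with
(possibly partial) EC numbers. Two assumptions drive everything
downstream:

1. *Analogous instances are comparable.* Instances of the same pathway in
   different organisms describe the same cellular process, so an
   alignment score between them measures evolutionary divergence of that
   process.
2. *Pathway presence is informative.* Absence of a pathway from an
   organism is itself a character — shared absence can count as
   similarity (parameter `b`), one-sided absence is deliberately treated
   as "no information" rather than dissimilarity, because database
   incompleteness and true loss are indistinguishable.

### Alignment objective

The bundled aligner is a deliberately simple stand-in for a full pathway
alignment engine, keeping exactly the properties the pipeline relies on:
scores ≤ 0, self-alignment = 0, higher = more similar, parameterized by a
deletion score. It maximizes, over partial injective node mappings M from
the query (the smaller instance) into the target,

    sum_{u in dom M} ec(u, M(u))  +  d·|query \ dom M|  +  delta·#broken edges,

where `ec(x, y) = −μ·(4 − k)` for a common EC prefix of k fields (a `-`
wildcard ends the prefix) and a query edge is *broken* when no directed
path connects the images of its endpoints in the target (reachability
rather than direct adjacency, tolerating inserted enzymes; a config
switch restricts to direct edges). Branch-and-bound over mappings is
exact up to `exact_search_cap` query nodes (default 12, far above the
instance sizes used anywhere here); beyond that a deterministic greedy
assignment is scored under the same objective. Query nodes and candidate
targets are always enumerated in lexicographic node-id order, so results
are reproducible to the byte.

### Threshold graphs and the information weight

Binarizing each page at threshold t discards score magnitude: every score
at or above t counts equally. The comparison is `>= t` (a strict `>` is
available as `strict=True`); equality at the threshold therefore produces
an edge. Present-pathway diagonals score 0 and always clear any t ≤ 0, so
self-loops are part of the graph — that is what makes "all degrees equal
|V|" attainable for a fully similar organism set.

The page weight is the sum over nodes of the binary entropy of the
normalized degree, in bits:

    w = sum_v h(deg(v)/|V|),   h(p) = −p·log2(p) − (1−p)·log2(1−p).

This is one concrete member of the family of "entropy-inspired"
degree-based weights: it is non-negative, decomposes per node, vanishes
exactly when every degree is 0 (nothing is similar — nothing to learn)
and when every degree is |V| (everything is similar — equally nothing to
learn), and peaks when degrees sit at |V|/2, i.e. when the pathway
bisects the organisms. Two consequences worth knowing: a graph mixing
degree-0 and degree-|V| nodes also gets w = 0, and the log base only
rescales all weights uniformly, so it can never change a tree topology or
a ranking. The weight function is a pluggable argument
(`graph_weight(tg, node_term=...)`) for anyone preferring a different
per-node term.

### From weighted pages to a tree

Weighted pages contain only {0, w} entries, so summation along the
pathway axis is well defined; the result is converted to dissimilarities
by subtracting every element from the **global maximum** of the matrix.
With b = true the maximum provably sits on the diagonal (every present
pathway contributes its weight to every diagonal cell, absent pathways
contribute via the b-edge); with b = false diagonal entries can differ
between organisms, the maximum need not be the first diagonal element,
and the subtracted diagonal need not vanish. Both situations are logged,
and the diagonal is forced to 0 because a distance-based tree method
requires zero self-distance.

Neighbor joining is implemented in-package rather than delegated so that
tie handling is pinned: among equal Q-criterion values the
lexicographically smallest index pair is joined. On additive input the
implementation is exact (topology and branch lengths); on the decidedly
non-additive matrices the thresholding produces, negative branch-length
estimates occur and are clamped to 0 with a warning, standard practice
for distance methods. An independent implementation (dendropy's
`nj_tree`) is used in the test suite as a cross-check oracle only.

### Co-evolution distance

The category table D is symmetric, zero on the diagonal, 2 for the
opposed one-sided patterns (d3, d4), and 1 for every one-sided-vs-shared
pattern. The (d1, d2) pairing — present in both vs absent in both — has
no printed value; it defaults to 2 by the same logic that makes
D(d3, d4) = 2: the two pathways disagree in *both* organisms of the pair,
while every 1-valued entry disagrees in exactly one. The completed table
is a metric on the four categories (verified exhaustively in the tests).
`CoevParams(d1_d2_distance=...)` overrides the completion.

H normalizes by the number of entries in a page, read literally as all n²
ordered entries including the diagonal; `CoevParams(triangle=True)`
restricts to the strict upper triangle with matching normalization. L is
normalized by the number of qualifying entries — without that, L would
scale with pathway ubiquity and the weighted combination across pairs
would be incoherent — and defined as 0 (with a warning) when no entry
qualifies. The combination is the weighted average
(W_p·H + L)/(W_p + 1); a pure weighted sum is available via
`CoevParams(combine="weighted_sum")`. W_p = 100 makes the coarse
presence/absence signal dominate and the score-based L a refinement.

Co-evolution operates on the **raw score pages**, not the weighted ones:
after thresholding, entries are {0, w} and an L1 distance between them
is meaningless.

Clustering is deterministic average-linkage agglomeration on the
distance matrix; when the cluster count is not forced it is chosen in
2..min(10, m−1) by maximal silhouette (ties toward fewer clusters). This
replaces a probabilistic graph-partitioning clusterer deliberately: the
claim under test is the existence of cluster structure in the distance
matrix, not the behaviour of any particular clustering algorithm.

## Parameters

| parameter | default | meaning |
|---|---|---|
| d (`deletion_score`) | −2 | per-node deletion penalty; score units |
| μ (`ec_mismatch_penalty`) | 1 | per-EC-field disagreement; score units |
| δ (`topology_gap_penalty`) | = d | per broken query edge |
| t (threshold) | −5 | minimum score counted as similarity |
| b | true | joint absence counts as similarity |
| W_p | 100 | weight of H vs L in the combined distance |

d = −2, t = −5, b = true are the pipeline defaults. The threshold is the
one genuinely data-dependent knob: it must sit inside the actual score
distribution, and analyses at other divergence scales (e.g. the
mutation-only simulation study below, which uses t = −3) should expect to
adjust it.

## What the simulator emulates — and what it does not

`evosim` generates: a Yule tree (per-lineage splitting at rate
1/`branch_length_mean`; waits are exponential; leaves are
contemporaneous, so the truth is ultrametric); a root repertoire of m
random DAG instances of 3–10 enzymes; and Poisson events along each
branch — pathway loss/gain (presence flips; a regained pathway is a fresh
random instance), per-node EC field mutation, node indels, and
acyclicity-preserving edge rewires. Planted co-evolution couples
loss/gain events within pathway groups: each event fired by a group
member applies, with probability ρ, to every member on that branch.
Effective group event rates therefore scale with group size
(≈ g·rate·ρ), which is why the co-evolving preset uses a small
per-pathway loss rate (0.025 per unit branch length).

Default rates: EC mutation 0.3 per node per unit branch length (chosen so
typical leaf pairs differ by a few EC fields per pathway — enough to
grade similarity, not enough to drive most scores to the deletion floor),
indel and rewire 0.1 per pathway, loss 0.05 / gain 0.02 per pathway. The
`mutation_only` and `coevolving` presets define the two recovery
experiments (n = 8, m = 30, 20 replicate seeds each) used in the
acceptance tests.

The simulator does **not** emulate: horizontal transfer (gain has no
donor), database curation artifacts (one-sided absence in simulation is
always true loss), realistic pathway size distributions beyond the
configurable 3–10 node range, or rate heterogeneity across lineages.
Passing recovery tests therefore show that the pipeline extracts the
signal its own assumptions describe — not that real database exports
satisfy those assumptions.

A known, measured limitation: with only m = 30 pathways of
Poisson-mutation signal, trees whose shortest internal edge is very small
(near-simultaneous splits, which a Yule process produces regularly at
n = 8) are not reliably resolved — the same limit holds for an oracle
given the raw alignment scores directly, so it is an information limit of
the data volume, not of the threshold/weight compression. The
tree-recovery acceptance test documents the achieved rate; perfect
topology recovery in ≥ 90% of replicates is beyond this data volume.

## Numerical choices

* Scores and weights are IEEE doubles; pages serialize scores with
  `repr`, the shortest round-tripping decimal, so write→read is
  bit-exact.
* All randomness flows from one `numpy` Generator per simulation, seeded
  explicitly; identical seeds give byte-identical output files.
* NJ tie-break: smallest (i, j) index pair; alignment tie-break:
  lexicographic node order, first optimum kept.
* Degenerate inputs: an all-absent pathway yields an all-BOTH_MISSING
  page (valid); an organism losing every pathway is a warning, not an
  error; an all-zero co-evolution matrix falls back to k = 2 with a
  trivial split rather than failing.
* Problem sizes in the test suite are kept at n ≤ 12 organisms and
  m ≤ 30 pathways, where exact branch-and-bound alignment and the O(n³)
  NJ are instantaneous and 20-replicate studies run in seconds.

## Known limitations

* The aligner is a stand-in: it scores node identity by EC prefix and
  topology by reachability, and will not reproduce the scores of a
  homeomorphism-based engine; pipelines consuming real engine output
  should ingest precomputed pages.
* The weight formula's zero set includes mixed 0/|V|-degree graphs, a
  case the per-node entropy form cannot distinguish from the uniform
  extremes.
* H treats all organisms exchangeably; phylogenetic correlation between
  organisms is not modelled in the co-evolution distance (two pathways
  lost once each on the same deep branch look as co-evolving as two lost
  repeatedly in parallel).
* Neighbor joining is the only tree method offered, and no bootstrap or
  other support values are computed.
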