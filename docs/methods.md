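# Methods

## Network model

A GRN state is an immutable triple (nodes, TF subset, true edges) over
opaque, case-sensitive gene identifiers. Two invariants are enforced at
construction: every edge source is a TF gene, and there are no
self-loops. Autoregulation is common in real interaction tables, so
self-loop rows are dropped (and counted) at load time rather than
rejected — the three nodes of a graphlet must be distinct genes, so a
self-loop can never enter any downstream computation anyway. TF status
defaults to "out-degree ≥ 1 in the loaded network" and can be overridden
with an explicit annotation; the default matches catalogues in which
every recorded edge originates from a known TF, while the override serves
catalogues that list TFs separately. The absence of an edge between any
ordered pair of distinct genes is an implicit *false* edge; false edges
are never materialized.

## Graphlet taxonomy

The induced adjacency pattern of an ordered node triple is packed into a
6-bit code over the fixed pair order (1→2, 1→3, 2→1, 2→3, 3→1, 3→2), and
canonicalized by minimizing over the six node permutations. Of the 64
patterns, exactly 13 classes satisfy the graphlet definition: at least
two true edges *and* no node untouched by a true edge. The second
condition is load-bearing — without it the mutual dyad plus an isolated
third gene would form a 14th class. The catalog is generated by this
enumeration at import time and validated by assertion (13 classes;
required-TF distribution 1:5:7; the complete triad last).

Type numbering is deterministic: classes are sorted by (required TF
count, true-edge count, canonical code) ascending. This pins type 1 to
the single-TF fan-out and type 13 to the complete triad and respects the
grouping 1 / 2–6 / 7–13 by required TFs. The internal order *within* the
two- and three-TF groups is this package's own convention; any analysis
that must match an external numbering should key on the canonical code
(`GraphletType.canonical_code`), which is convention-free.

## Enumeration

The TF-anchored sweep iterates, for each TF gene `s`, over each true
target `u` and each third node `w`, classifying the induced triple.
Every graphlet contains at least one true edge, and every true edge
leaves a TF, so every graphlet is reached; a set of sorted triples
deduplicates multiply-discovered instances. The cost is O(t·k·n) for t
TFs of mean out-degree k in an n-node network, versus O(n³) brute force.
Instances are stored sorted lexicographically by triple, with the triad
code recorded relative to that ordering, so serialized output is
reproducible. Genes in no graphlet (NOG) are reported as a set and
excluded from per-gene metrics.

## REC and RGD

REC of a triple is 1 − mismatches/6, where mismatches is the Hamming
distance between the two induced 6-bit patterns. A triple node absent
from the compared state has no edges there, which realizes the rule that
all interactions of an absent node count as false edges without any
special casing. REC therefore takes only the values {0, 1/6, …, 1}.

The triplet universe of a comparison is the graphlet instance set of the
**reference** state, and K in RGD is the reference graphlet degree.
This makes the comparison directional by design: rewiring visible only
around nodes newly appearing in the compared state is captured by
rerunning with the roles swapped, and reports are expected to be read in
pairs. Per-type mean REC is the unweighted arithmetic mean over the
reference instances of that type. The per-triple mismatch count itself is
symmetric in the two states; asymmetry enters only through the choice of
instance set.

Genes are split into TF and non-TF groups when reporting the fraction
with RGD < 1.0; a group with no graphlet-participating members is
reported as undefined rather than 0.

## Condition-specific networks

A condition state is carved from a gold standard by keeping exactly the
edges whose **source** TF is called present; target expression is not
required, following the rule that retention depends only on the edge's
origin. Presence is P ≤ α (inclusive, α = 0.05 by default) on the
detection P-value, or a boolean flag. When several probes map to one
gene the gene is present if any probe passes (`any`, the default,
permissive and information-preserving); `all` and `min` are exposed for
stricter protocols. Name reconciliation keeps gold-standard identifiers
as authoritative and reports unmatched experiment rows rather than
guessing at normalization.

## Reports

The lowest-RGD TF ranking sorts ascending by RGD, breaking ties by
descending graphlet degree (a gene rewired across more graphlets is the
stronger signal) and then lexicographically, making the order a total
order. Edge and node labels are TP (both states), FN (reference only),
FP (compared only); the merged subnetwork around selected genes is the
union of the triples of every reference graphlet containing a selected
gene, carrying all labelled edges of either state among those nodes, with
weakly connected components reported largest first.

Agreement with external per-node metrics (centralities computed in
Cytoscape or any graph tool and imported as a node attribute table) uses
the absolute between-state change Δ per node, restricted to nodes having
an RGD and a metric value in both states. A node is flagged by RGD iff
RGD < 1 and by the metric iff Δ > ε, with ε = 0 by default but exposed
because floating-point centralities rarely reproduce exactly. The
disagreement rate is d = (flagged by exactly one) / (all evaluable
nodes) and dc conditions on being flagged by at least one. Correlations
(Spearman ρ, Kendall τ with average-rank ties, Pearson r) come from
scipy and are reported as undefined below 3 nodes or for constant
vectors.

## Synthetic networks and baselines

`generate_random_grn(n, t, e, seed)` samples e distinct ordered pairs
uniformly without replacement from the t×(n−1) TF-sourced non-self
pairs; the first t node labels are the TFs, so only the edge draw is
random and a seed fully reproduces the network. The generator emulates
the size and sparsity regime of curated bacterial regulatory catalogues
(a small TF subset sourcing all edges, mean out-degree ~10) but none of
their degree heterogeneity, autoregulation, or modular structure —
passing tests demonstrate correctness of the metrics, not realism of the
topology, and absolute baseline values on real catalogues will differ.

The randomization baseline uses degree-preserving double-edge swaps
((a→b, c→d) → (a→d, c→b), rejecting self-loops and duplicates), the
standard null model for regulatory networks, via
`networkx.directed_edge_swap`; swaps keep every node's in- and
out-degree and the TF-source invariant. On small or dense networks the
swap chain can exhaust its attempt budget (200·n_swaps + 1000 tries)
before reaching the requested count; this stops early with a warning
rather than failing, since a partially randomized network is still a
valid (weaker) null. A uniform-resample mode that preserves only |E| is
exposed as an alternative. `perturb` removes a fraction of edges and
adds random TF-sourced ones for controlled sensitivity fixtures.

Mean RGD of a network against progressively more randomized copies of
itself decays from 1 toward a plateau; the test suite verifies the decay
on a 200-node, 30-TF, 400-edge fixture over 20 seeds and a swap ladder
of 0/25/100/400/1600, sizes chosen so the whole suite runs in well under
a minute on a laptop.

## Numerical and degenerate-input choices

- REC/RGD are exact rationals with denominator dividing 6K; they are
  stored as floats and all tests compare at machine precision.
- An empty present set yields an empty (nodeless) condition network; an
  edgeless network has an empty instance list and every gene NOG.
- Rewiring a network with fewer than two edges, or zero requested swaps,
  returns the input unchanged (the former with a warning).
- Unknown genes in degree lookups and subnetwork selections raise
  KeyError; a selected gene with graphlet degree 0 contributes nothing
  and warns.
- File carriers are plain TSV/SIF with `#` comments; duplicate rows
  collapse and the load report's (kept, duplicates, self-loops) always
  sum to the raw row count.

## Known limitations

- Only 3-node graphlets: larger graphlets make enumeration
  combinatorially hard and always contain a 3-node graphlet anyway.
- The comparison is pairwise; multi-state trajectories are left to the
  caller to aggregate.
- Centralities are consumed, never computed; ANOVA-style significance of
  RGD-change fractions is out of scope because the replicate grouping is
  protocol-specific.
- Type numbers within the two- and three-TF groups follow this package's
  canonical sort, not any particular figure's layout; use canonical
  codes for cross-tool comparisons.
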