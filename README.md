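# grnlets

Graphlet-based differential analysis of gene regulatory networks (GRNs).

## The problem

A GRN is a directed graph whose edges run from transcription-factor (TF)
encoding genes to the genes they regulate. The same organism realizes
different states of its GRN under different conditions — for *E. coli*,
growing in suspension versus forming a biofilm — and the interesting
question is not which genes change expression but **where the network was
rewired**: which regulators gained or lost their local circuitry. Global
network statistics wash out such local changes; per-gene expression tests
ignore structure entirely. `grnlets` fills that gap for anyone comparing
two states of a directed regulatory network: a gold-standard catalogue
against a condition-specific subnetwork, two conditions, or two time
points.

## The metrics

A **graphlet** is an induced subgraph on three distinct genes with at
least two *true* regulatory edges and no node untouched by a true edge.
Exactly 13 isomorphism classes of directed triads satisfy this
definition; the absence of an interaction (a *false* edge) counts as much
as its presence, so every class except the complete triad (type 13) also
requires specific absences. Type 1 needs one TF gene, types 2–6 need two,
types 7–13 need three.

Given a reference state *G* and a compared state *G′*, let *A* and *B* be
the 3×3 induced adjacency matrices of the same node triple in each state
(with *N* = 3 nodes and *N*(*N*−1) = 6 ordered pairs). The
**reconstruction rate** of one graphlet is

    REC = 1 − (1/6) · Σ_{i≠j} |a_ij − b_ij|

i.e. the classification accuracy over the six possible edges; REC = 1 is
a perfect match, 0 total disagreement, and a triple node absent from *G′*
contributes an all-zero row and column to *B*. The **REC graphlet
degree** of a gene is the mean REC over the *K* reference-state graphlets
it participates in:

    RGD = (1/K) · Σ_k REC_k

RGD < 1 flags local rewiring; sorting TFs by ascending RGD ranks the
regulators whose neighbourhood changed the most. The triplet universe
always comes from the reference state, so comparisons are directional —
run both directions to see both sides.

Graphlets are found with a TF-anchored sweep (for each TF, each of its
targets, each third node) at O(t·k·n) cost instead of the brute-force
O(n³), exploiting the fact that every edge leaves a TF gene.

## Worked example

```python
from grnlets import GRN, compare_networks

reference = GRN.from_edges([("a", "b"), ("a", "c"), ("a", "d")])  # a regulates b, c, d
compared  = GRN.from_edges([("a", "b"), ("a", "c")], nodes=["d"])  # a -> d lost

result = compare_networks(reference, compared)
for r in result.rec_records:
    print(r.triple, r.mismatches, round(r.rec, 4))
for g in result.rgd_records:
    print(g.gene, g.k, round(g.rgd, 4))
```

prints

```
('a', 'b', 'c') 0 1.0
('a', 'b', 'd') 1 0.8333
('a', 'c', 'd') 1 0.8333
a 3 0.8889
b 2 0.9167
c 2 0.9167
d 2 0.8333
```

The reference star contains three fan-out (type-1) graphlets. The triple
{a,b,c} is reconstructed perfectly (REC 1); the two triples containing
the lost edge a→d each miss one of six entries (REC 5/6). Gene `a` sits
in all three graphlets, so its RGD is (1 + 5/6 + 5/6)/3 = 8/9 ≈ 0.889 —
below 1, correctly flagging the hub whose regulation changed.

The same machinery is available from a shell:

```sh
grnlets simulate --nodes 200 --tfs 30 --edges 400 --seed 1 --out gold.tsv
grnlets condition --gold gold.tsv --calls calls.tsv --out state.tsv
grnlets compare --reference gold.tsv --compared state.tsv
grnlets report --reference gold.tsv --compared state.tsv --top-k 5
```

`compare` writes per-triplet REC, per-gene RGD and a JSON summary
(per-type mean REC, fractions of TF and non-TF genes with RGD < 1, NOG
counts); `report` writes the lowest-RGD TF ranking, a Cytoscape-loadable
merged subnetwork with TP/FN/FP edge and node labels, and — given a node
attribute table of externally computed centralities — agreement
statistics (Spearman ρ, Kendall τ, Pearson r, disagreement rates d and
dc) between RGD and each metric's between-state change.

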