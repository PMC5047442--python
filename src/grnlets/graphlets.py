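"""Directed 3-node graphlet taxonomy, classification and enumeration.

A *graphlet* here is an induced subgraph on three distinct genes with at
least two true regulatory edges and no node untouched by a true edge.
Exactly 13 isomorphism classes of directed triads satisfy that definition;
type 1 needs a single TF-encoding gene (the fan-out), types 2-6 need two,
types 7-13 need three, and type 13 is the complete triad in which all six
ordered gene pairs carry a regulatory interaction (every other type also
requires at least one *false* edge, i.e. an absent interaction).

The induced adjacency pattern of an ordered node triple is packed into a
6-bit *triad code*: bit ``i`` is set when the ordered pair ``PAIR_ORDER[i]``
carries a true edge, with ``PAIR_ORDER`` fixed as
(1->2, 1->3, 2->1, 2->3, 3->1, 3->2) on the triple's node ordering.
Classification canonicalizes the code by minimizing over the six node
permutations, so it is independent of node labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

from .grn import GRN

__all__ = [
    "PAIR_ORDER",
    "GraphletType",
    "GraphletInstance",
    "GraphletIndex",
    "GRAPHLET_TYPES",
    "CANONICAL_TO_TYPE",
    "triad_code",
    "canonical_code",
    "classify_triad",
    "enumerate_graphlets",
    "graphlet_degree",
]

# Ordered off-diagonal entries of the 3x3 induced adjacency matrix.
PAIR_ORDER: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1),
)
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_ORDER)}
_PERMS = tuple(permutations(range(3)))


@dataclass(frozen=True)
class GraphletType:
    """One of the 13 graphlet isomorphism classes."""

    type_id: int
    canonical_code: int
    required_tf_count: int  # nodes with out-degree >= 1 in the triad
    true_edge_count: int


@dataclass(frozen=True)
class GraphletInstance:
    """A concrete graphlet: an unordered gene triple plus its class.

    ``triple`` is stored lexicographically sorted and ``code`` is the triad
    code of the induced subgraph under that ordering (not canonicalized),
    so instances serialize reproducibly.
    """

    triple: tuple[str, str, str]
    type_id: int
    code: int


def _apply_perm(code: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for i, (a, b) in enumerate(PAIR_ORDER):
        if code >> i & 1:
            out |= 1 << _PAIR_INDEX[(perm[a], perm[b])]
    return out


def canonical_code(code: int) -> int:
    """Minimum triad code over the 6 node permutations (isomorphism key)."""
    if not 0 <= code < 64:
        raise ValueError(f"triad code must be in [0, 64), got {code}")
    return min(_apply_perm(code, p) for p in _PERMS)


def _is_graphlet_code(code: int) -> bool:
    edges = [PAIR_ORDER[i] for i in range(6) if code >> i & 1]
    if len(edges) < 2:
        return False
    touched = {x for e in edges for x in e}
    return len(touched) == 3


def _out_degree_nodes(code: int) -> int:
    return len({a for i, (a, b) in enumerate(PAIR_ORDER) if code >> i & 1})


def _build_catalog() -> tuple[GraphletType, ...]:
    """Enumerate all 64 triad codes and number the surviving classes.

    Classes are ordered by (required TF count, true-edge count, canonical
    code) ascending, which pins type 1 to the single-TF fan-out and type 13
    to the complete triad.
    """
    canon_codes = sorted(
        {canonical_code(c) for c in range(64) if _is_graphlet_code(c)}
    )
    keyed = sorted(
        canon_codes,
        key=lambda cc: (_out_degree_nodes(cc), bin(cc).count("1"), cc),
    )
    types = tuple(
        GraphletType(
            type_id=i,
            canonical_code=cc,
            required_tf_count=_out_degree_nodes(cc),
            true_edge_count=bin(cc).count("1"),
        )
        for i, cc in enumerate(keyed, start=1)
    )
    # Catalog sanity: the taxonomy the whole package rests on.
    assert len(types) == 13
    assert [t.required_tf_count for t in types].count(1) == 1
    assert [t.required_tf_count for t in types].count(2) == 5
    assert [t.required_tf_count for t in types].count(3) == 7
    assert types[0].required_tf_count == 1
    assert types[-1].true_edge_count == 6
    return types


GRAPHLET_TYPES: tuple[GraphletType, ...] = _build_catalog()
CANONICAL_TO_TYPE: dict[int, GraphletType] = {
    t.canonical_code: t for t in GRAPHLET_TYPES
}


def triad_code(triple: tuple[str, str, str], grn: GRN) -> int:
    """Triad code of the subgraph induced by ``triple`` under its given order."""
    code = 0
    for i, (a, b) in enumerate(PAIR_ORDER):
        if (triple[a], triple[b]) in grn.edges:
            code |= 1 << i
    return code


def classify_triad(code: int) -> GraphletType | None:
    """Map a triad code to its graphlet type, or None if not a graphlet.

    A pattern fails when it has fewer than two true edges or leaves a node
    untouched (e.g. a mutual dyad plus an isolated third gene).
    """
    if not _is_graphlet_code(code):
        return None
    return CANONICAL_TO_TYPE[canonical_code(code)]


@dataclass
class GraphletIndex:
    """All graphlet instances of one network state.

    ``node_index`` maps each gene to the (integer) ids of the instances it
    participates in; its length is the gene's graphlet degree K.  ``nog``
    is the set of genes forming no graphlet at all.
    """

    grn: GRN
    instances: list[GraphletInstance] = field(default_factory=list)
    node_index: dict[str, list[int]] = field(default_factory=dict)
    type_counts: dict[int, int] = field(default_factory=dict)
    nog: frozenset[str] = frozenset()

    def degree(self, gene: str) -> int:
        if gene not in self.grn.nodes:
            raise KeyError(f"gene {gene!r} is not a node of {self.grn.name!r}")
        return len(self.node_index.get(gene, ()))


def enumerate_graphlets(grn: GRN) -> GraphletIndex:
    """Enumerate every graphlet of ``grn`` with the TF-anchored sweep.

    For each TF gene ``s``, each of its true targets ``u`` and each third
    node ``w``, the induced triple {s, u, w} is formed, deduplicated and
    classified.  Because every graphlet contains at least two true edges
    and edges only leave TF genes, every graphlet is reached through one of
    its true edges; the result equals brute force over all C(n, 3) triples
    at O(t * k * n) cost.
    """
    adj = grn.out_adjacency
    nodes = sorted(grn.nodes)
    seen: set[tuple[str, str, str]] = set()
    instances: list[GraphletInstance] = []
    for s, targets in adj.items():
        for u in targets:
            for w in nodes:
                if w == s or w == u:
                    continue
                triple = tuple(sorted((s, u, w)))
                if triple in seen:
                    continue
                seen.add(triple)
                code = triad_code(triple, grn)
                gtype = classify_triad(code)
                if gtype is not None:
                    instances.append(
                        GraphletInstance(triple=triple, type_id=gtype.type_id, code=code)
                    )
    instances.sort(key=lambda inst: inst.triple)
    node_index: dict[str, list[int]] = {}
    type_counts: dict[int, int] = {}
    for idx, inst in enumerate(instances):
        type_counts[inst.type_id] = type_counts.get(inst.type_id, 0) + 1
        for g in inst.triple:
            node_index.setdefault(g, []).append(idx)
    nog = frozenset(grn.nodes - node_index.keys())
    return GraphletIndex(
        grn=grn,
        instances=instances,
        node_index=node_index,
        type_counts=type_counts,
        nog=nog,
    )


def graphlet_degree(index: GraphletIndex, gene: str) -> int:
    """Number of graphlet instances containing ``gene`` (K); 0 iff NOG."""
    return index.degree(gene)
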