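"""REC and RGD: graphlet-based rewiring metrics between two network states.

REC (reconstruction rate) scores one node triple.  Let A and B be the 3x3
adjacency matrices of the subgraph induced by the same triple in the
reference and the compared state (1 = true edge, 0 = false edge).  With
N = 3 nodes there are N(N-1) = 6 ordered pairs, and

    REC = 1 - (1/6) * sum_{i != j} |a_ij - b_ij|

i.e. the classification accuracy over the six possible edges, counting
both presences and absences.  REC is 1 for a perfect match and 0 for total
disagreement; a triple node absent from the compared state contributes
all-zero rows and columns to B (all its interactions are false edges
there).

RGD (REC graphlet degree) of a gene is the mean REC over the K reference
graphlets the gene participates in; RGD < 1 flags local rewiring around
that gene.  The triplet universe always comes from the *reference* state,
so the comparison is directional — swap the roles to see the other side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graphlets import (
    PAIR_ORDER,
    GraphletIndex,
    classify_triad,
    enumerate_graphlets,
    triad_code,
)
from .grn import GRN

__all__ = [
    "RECRecord",
    "RGDRecord",
    "ComparisonResult",
    "triplet_rec",
    "compare_networks",
    "rgd_all",
    "fraction_changed",
]

N_ORDERED_PAIRS = 6  # N(N-1) with N = 3


@dataclass(frozen=True)
class RECRecord:
    """Per-triple reconstruction rate."""

    triple: tuple[str, str, str]
    type_id: int
    mismatches: int  # sum over ordered pairs of |a_ij - b_ij|, in 0..6
    rec: float  # 1 - mismatches/6

    def __post_init__(self) -> None:
        if not 0 <= self.mismatches <= N_ORDERED_PAIRS:
            raise ValueError("mismatch count must lie in 0..6")


@dataclass(frozen=True)
class RGDRecord:
    """Per-gene mean REC over its K reference graphlets (K >= 1)."""

    gene: str
    k: int
    rgd: float


@dataclass
class ComparisonResult:
    """Full REC/RGD comparison of a compared state against a reference."""

    reference_name: str
    compared_name: str
    rec_records: list[RECRecord] = field(default_factory=list)
    rgd_records: list[RGDRecord] = field(default_factory=list)
    per_type_mean_rec: dict[int, float] = field(default_factory=dict)
    nodes_absent_in_compared: frozenset[str] = frozenset()
    nog: frozenset[str] = frozenset()
    reference_index: GraphletIndex | None = None


def _mismatch_count(
    triple: tuple[str, str, str], reference: GRN, compared: GRN
) -> int:
    """Hamming distance between the two induced adjacency patterns.

    Edge lookups against a node absent from ``compared`` are False, which
    realizes the all-zero row/column rule without special-casing.
    """
    a = triad_code(triple, reference)
    b = triad_code(triple, compared)
    return bin(a ^ b).count("1")


def triplet_rec(
    triple: tuple[str, str, str], reference: GRN, compared: GRN
) -> RECRecord:
    """REC of one triple; the triple must form a graphlet in the reference."""
    triple = tuple(sorted(triple))  # type: ignore[assignment]
    gtype = classify_triad(triad_code(triple, reference))
    if gtype is None:
        raise ValueError(
            f"triple {triple} does not form a graphlet in {reference.name!r}"
        )
    m = _mismatch_count(triple, reference, compared)
    return RECRecord(
        triple=triple,
        type_id=gtype.type_id,
        mismatches=m,
        rec=(N_ORDERED_PAIRS - m) / N_ORDERED_PAIRS,
    )


def compare_networks(
    reference: GRN,
    compared: GRN,
    *,
    reference_index: GraphletIndex | None = None,
) -> ComparisonResult:
    """Score every reference graphlet against the compared state.

    Evaluates REC on each graphlet instance of the reference, averages per
    graphlet type (unweighted arithmetic mean over instances of that type),
    and computes RGD for every reference gene with K >= 1.  Pass a
    pre-built ``reference_index`` to amortize enumeration across several
    compared states.
    """
    index = reference_index or enumerate_graphlets(reference)
    recs: list[RECRecord] = []
    type_sum: dict[int, float] = {}
    type_n: dict[int, int] = {}
    for inst in index.instances:
        m = _mismatch_count(inst.triple, reference, compared)
        rec = (N_ORDERED_PAIRS - m) / N_ORDERED_PAIRS
        recs.append(
            RECRecord(triple=inst.triple, type_id=inst.type_id, mismatches=m, rec=rec)
        )
        type_sum[inst.type_id] = type_sum.get(inst.type_id, 0.0) + rec
        type_n[inst.type_id] = type_n.get(inst.type_id, 0) + 1
    rgds = [
        RGDRecord(
            gene=gene,
            k=len(ids),
            rgd=sum(recs[i].rec for i in ids) / len(ids),
        )
        for gene, ids in sorted(index.node_index.items())
    ]
    indexed_nodes = set(index.node_index)
    return ComparisonResult(
        reference_name=reference.name,
        compared_name=compared.name,
        rec_records=recs,
        rgd_records=rgds,
        per_type_mean_rec={t: type_sum[t] / type_n[t] for t in sorted(type_sum)},
        nodes_absent_in_compared=frozenset(indexed_nodes - compared.nodes),
        nog=index.nog,
        reference_index=index,
    )


def rgd_all(result: ComparisonResult) -> list[RGDRecord]:
    """Per-gene RGD records of a comparison (reference genes with K >= 1).

    Genes in no reference graphlet (NOG) carry no RGD and are listed in
    ``result.nog`` instead.
    """
    return list(result.rgd_records)


def fraction_changed(
    rgds: list[RGDRecord], tfs: set[str]
) -> tuple[float | None, float | None]:
    """Fraction of genes with RGD < 1.0, split by TF status.

    Only genes participating in at least one reference graphlet enter the
    denominators (they are the only ones with an RGD).  A group with no
    members is reported as None (undefined).
    """
    tf_recs = [r for r in rgds if r.gene in tfs]
    ntf_recs = [r for r in rgds if r.gene not in tfs]

    def frac(group: list[RGDRecord]) -> float | None:
        if not group:
            return None
        return sum(1 for r in group if r.rgd < 1.0) / len(group)

    return frac(tf_recs), frac(ntf_recs)
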