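"""Core directed gene-regulatory-network (GRN) data model and file I/O.

A GRN is a directed graph whose nodes are gene identifiers and whose edges
run from a transcription-factor-encoding gene (the regulator) to a target
gene.  Only the *true* edges — experimentally supported regulatory
interactions — are stored; the absence of an edge between any ordered pair
of distinct genes is an implicit *false* edge, and both kinds count when
two network states are compared.

Supported carriers are a 2-column tab-separated edge list and Cytoscape's
SIF format, plus a long-format (gene, attribute, value) node table used for
TF flags and imported per-node metrics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

PathLike = Union[str, Path]

__all__ = [
    "GRN",
    "LoadReport",
    "GRNError",
    "ParseError",
    "ConsistencyError",
    "read_edge_list",
    "write_network",
    "set_tf_annotation",
    "read_node_attributes",
    "write_node_attributes",
]


class GRNError(ValueError):
    """Base class for network-model validation failures."""


class ParseError(GRNError):
    """A malformed row was encountered while reading a network file."""


class ConsistencyError(GRNError):
    """An operation would violate a GRN invariant (e.g. a non-TF edge source)."""


@dataclass(frozen=True)
class LoadReport:
    """Row accounting for a single edge-list read.

    ``kept + duplicates + self_loops == raw_rows`` always holds.
    """

    raw_rows: int = 0
    kept: int = 0
    duplicates: int = 0
    self_loops: int = 0

    def __post_init__(self) -> None:
        if self.kept + self.duplicates + self.self_loops != self.raw_rows:
            raise GRNError("load report counts do not sum to the raw row count")


@dataclass(frozen=True)
class GRN:
    """A state of a gene regulatory network.

    Parameters
    ----------
    name
        Free-text label for the state (e.g. a condition or time point).
    nodes
        All gene identifiers, including isolated genes.
    tf_nodes
        The subset of ``nodes`` that encode transcription factors.  Every
        edge source must belong to this set.
    edges
        Ordered (regulator, target) pairs.  Self-loops are forbidden: the
        three nodes of a graphlet must be distinct genes, so autoregulation
        is dropped upstream at load time.
    """

    name: str
    nodes: frozenset[str]
    tf_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.tf_nodes <= self.nodes:
            raise ConsistencyError("tf_nodes must be a subset of nodes")
        for s, t in self.edges:
            if s == t:
                raise ConsistencyError(f"self-loop on {s!r} is not allowed")
            if s not in self.tf_nodes:
                raise ConsistencyError(
                    f"edge ({s!r}, {t!r}) originates from a non-TF gene"
                )
            if t not in self.nodes:
                raise ConsistencyError(f"edge target {t!r} is not a node")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        *,
        name: str = "grn",
        nodes: Iterable[str] = (),
        tf_nodes: Iterable[str] | None = None,
    ) -> "GRN":
        """Build a GRN from an edge iterable.

        ``tf_nodes=None`` applies the default TF rule: every gene with
        out-degree >= 1 is flagged as TF-encoding.  Extra ``nodes`` may add
        isolated genes.
        """
        edge_set = frozenset((str(s), str(t)) for s, t in edges)
        node_set = frozenset(str(x) for x in nodes) | frozenset(
            x for e in edge_set for x in e
        )
        if tf_nodes is None:
            tfs = frozenset(s for s, _ in edge_set)
        else:
            tfs = frozenset(str(x) for x in tf_nodes)
            node_set |= tfs
        return cls(name=name, nodes=node_set, tf_nodes=tfs, edges=edge_set)

    @property
    def n(self) -> int:
        """Total number of genes (nodes)."""
        return len(self.nodes)

    @property
    def t(self) -> int:
        """Number of TF-encoding genes."""
        return len(self.tf_nodes)

    @property
    def out_adjacency(self) -> dict[str, list[str]]:
        """True-edge adjacency list keyed by TF gene, targets sorted.

        Only TF genes with at least one target appear; self-connections
        cannot occur by construction.
        """
        adj: dict[str, list[str]] = {}
        for s, t in self.edges:
            adj.setdefault(s, []).append(t)
        for targets in adj.values():
            targets.sort()
        return adj

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.edges

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GRN(name={self.name!r}, n={self.n}, t={self.t}, "
            f"edges={len(self.edges)})"
        )


def _iter_rows(path: PathLike) -> Iterable[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_edge_list(
    path: PathLike, dialect: str = "tsv", *, name: str | None = None
) -> tuple[GRN, LoadReport]:
    """Read a network from a 2-column TSV edge list or a SIF file.

    TSV rows are ``regulator<TAB>target``; SIF rows are
    ``source relation target`` with the relation token ignored.  Comment
    lines starting with ``#`` and blank lines are skipped.  Duplicate rows
    collapse to one edge and self-loop rows are dropped; both are counted
    in the returned :class:`LoadReport`.  TF status defaults to out-degree
    >= 1 (override afterwards with :func:`set_tf_annotation`).
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = kept = dups = loops = 0
    edges: set[tuple[str, str]] = set()
    for lineno, tokens in _iter_rows(path):
        raw += 1
        if dialect == "sif":
            if len(tokens) < 3:
                raise ParseError(
                    f"{path}:{lineno}: SIF row needs source, relation, target"
                )
            s, t = tokens[0], tokens[2]
        else:
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}:{lineno}: edge row needs a source and a target"
                )
            s, t = tokens[0], tokens[1]
        if s == t:
            loops += 1
            continue
        if (s, t) in edges:
            dups += 1
            continue
        edges.add((s, t))
        kept += 1
    grn = GRN.from_edges(edges, name=name or Path(path).stem)
    return grn, LoadReport(raw_rows=raw, kept=kept, duplicates=dups, self_loops=loops)


def write_network(
    grn: GRN, path: PathLike, dialect: str = "tsv", *, node_table: PathLike | None = None
) -> None:
    """Write ``grn`` as an edge list (TSV or SIF).

    Isolated nodes cannot be carried by an edge list; when ``node_table``
    is given they are emitted there as ``(gene, isolated, 1)`` rows so the
    full node set survives a round trip.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        for s, t in sorted(grn.edges):
            if dialect == "sif":
                fh.write(f"{s}\tregulates\t{t}\n")
            else:
                fh.write(f"{s}\t{t}\n")
    if node_table is not None:
        touched = {x for e in grn.edges for x in e}
        isolated = sorted(grn.nodes - touched)
        with open(node_table, "wt", encoding="utf-8") as fh:
            for g in isolated:
                fh.write(f"{g}\tisolated\t1\n")


def set_tf_annotation(grn: GRN, tf_list: Iterable[str]) -> GRN:
    """Replace the TF flag set with an explicit annotation.

    Genes in ``tf_list`` missing from the network are added as isolated
    nodes.  Raises :class:`ConsistencyError`, naming the offending edge,
    if any existing edge would originate from a non-TF gene under the new
    annotation.
    """
    tfs = frozenset(str(x) for x in tf_list)
    for s, t in grn.edges:
        if s not in tfs:
            raise ConsistencyError(
                f"edge ({s!r}, {t!r}) originates from {s!r}, "
                "which is not in the TF annotation"
            )
    return GRN(
        name=grn.name,
        nodes=grn.nodes | tfs,
        tf_nodes=tfs,
        edges=grn.edges,
    )


def read_node_attributes(path: PathLike) -> dict[str, dict[str, str]]:
    """Read a long-format node attribute table.

    Rows are ``gene<TAB>attribute<TAB>value``; the last row wins for a
    repeated (gene, attribute) pair.  Returns ``{gene: {attribute: value}}``.
    """
    out: dict[str, dict[str, str]] = {}
    for lineno, tokens in _iter_rows(path):
        if len(tokens) < 3:
            raise ParseError(f"{path}:{lineno}: node row needs gene, attribute, value")
        gene, attr, value = tokens[0], tokens[1], tokens[2]
        if not gene:
            raise ParseError(f"{path}:{lineno}: empty gene id")
        out.setdefault(gene, {})[attr] = value
    return out


def write_node_attributes(
    rows: Mapping[str, Mapping[str, object]], path: PathLike
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted(rows):
            for attr in sorted(rows[gene]):
                fh.write(f"{gene}\t{attr}\t{rows[gene][attr]}\n")
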