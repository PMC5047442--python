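"""Condition-specific network construction from expression presence calls.

A condition-specific state of a gold-standard GRN keeps an edge only when
its source TF gene is called *present* (expressed) in that condition.  A
gene is present when any of its detection P-values passes the threshold
(default alpha = 0.05, inclusive), or when its presence flag is set.
Target-gene expression is deliberately not required: edge retention depends
only on the regulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .grn import GRN, ParseError

PathLike = Union[str, Path]

__all__ = [
    "ExpressionCall",
    "ExpressionCallTable",
    "ConditionNetwork",
    "read_call_table",
    "call_presence",
    "reconcile_names",
    "build_condition_network",
]


@dataclass(frozen=True)
class ExpressionCall:
    """One probe-level detection call: P-value in [0, 1] or a boolean flag."""

    gene: str
    p_value: float | None = None
    present: bool | None = None

    def __post_init__(self) -> None:
        if (self.p_value is None) == (self.present is None):
            raise ValueError(f"{self.gene!r}: provide exactly one of p_value/present")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(
                f"gene {self.gene!r}: P-value {self.p_value} outside [0, 1]"
            )


@dataclass
class ExpressionCallTable:
    """Detection calls for one condition; multiple rows per gene allowed
    (e.g. several probesets mapping to the same gene)."""

    name: str
    calls: list[ExpressionCall] = field(default_factory=list)

    def genes(self) -> set[str]:
        return {c.gene for c in self.calls}


@dataclass(frozen=True)
class ConditionNetwork:
    """A gold-standard GRN filtered by one condition's presence calls."""

    grn: GRN
    gold_name: str
    call_table_name: str
    alpha: float
    tfs_retained: int
    tfs_dropped: int


def read_call_table(path: PathLike, *, name: str | None = None) -> ExpressionCallTable:
    """Read a tab-separated call table.

    Column 2 is either a detection P-value or a 0/1 presence flag; the two
    may be mixed.  ``#`` comments and blank lines are skipped.
    """
    calls: list[ExpressionCall] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: call row needs gene and value")
            gene, raw = tokens[0], tokens[1]
            if raw in ("0", "1"):
                calls.append(ExpressionCall(gene=gene, present=raw == "1"))
            else:
                calls.append(ExpressionCall(gene=gene, p_value=float(raw)))
    return ExpressionCallTable(name=name or Path(path).stem, calls=calls)


def call_presence(
    table: ExpressionCallTable,
    alpha: float = 0.05,
    probe_rule: str = "any",
) -> set[str]:
    """Genes called present at the given detection threshold.

    A probe passes when its P-value <= ``alpha`` (inclusive; the
    conventional reading of a significance cut-off) or its flag is true.
    ``probe_rule`` aggregates multiple probes per gene: ``any`` (default,
    permissive), ``all``, or ``min`` (the smallest P wins, equivalent to
    ``any`` for pure P-value tables but stated separately for clarity).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if probe_rule not in ("any", "all", "min"):
        raise ValueError(f"unknown probe rule {probe_rule!r}")
    passes: dict[str, list[bool]] = {}
    for c in table.calls:
        ok = c.present if c.present is not None else c.p_value <= alpha
        passes.setdefault(c.gene, []).append(ok)
    if probe_rule == "all":
        return {g for g, v in passes.items() if all(v)}
    return {g for g, v in passes.items() if any(v)}


def reconcile_names(
    gold: GRN, table: ExpressionCallTable
) -> tuple[ExpressionCallTable, list[str]]:
    """Keep only call rows whose gene id matches a gold-standard node.

    Gold names are authoritative; unmatched experiment genes are returned
    (sorted) for reporting and excluded from the filtered table.
    """
    matched = [c for c in table.calls if c.gene in gold.nodes]
    unmatched = sorted(table.genes() - gold.nodes)
    return ExpressionCallTable(name=table.name, calls=matched), unmatched


def build_condition_network(
    gold: GRN,
    present: Iterable[str],
    *,
    name: str | None = None,
    call_table_name: str = "",
    alpha: float = 0.05,
) -> ConditionNetwork:
    """Filter a gold standard down to edges sourced from present TFs.

    Retained edges are exactly those whose source is present; nodes are the
    present TFs plus every endpoint of a retained edge; the TF flag set is
    the gold one restricted to surviving nodes.  An empty present set
    yields an empty network.
    """
    present = set(present)
    present_tfs = gold.tf_nodes & present
    edges = frozenset(e for e in gold.edges if e[0] in present)
    nodes = present_tfs | {x for e in edges for x in e}
    grn = GRN(
        name=name or f"{gold.name}|{call_table_name or 'condition'}",
        nodes=frozenset(nodes),
        tf_nodes=gold.tf_nodes & nodes,
        edges=edges,
    )
    return ConditionNetwork(
        grn=grn,
        gold_name=gold.name,
        call_table_name=call_table_name,
        alpha=alpha,
        tfs_retained=len(present_tfs),
        tfs_dropped=len(gold.tf_nodes - present),
    )
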