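"""Differential-rewiring reports built on top of the REC/RGD comparison.

Covers the three downstream products of a two-state comparison: the ranked
list of TF genes with the lowest RGD (the strongest local rewiring), the
merged subnetwork around selected genes with true-positive / false-negative
/ false-positive edge and node labels, and agreement statistics between RGD
and externally computed per-node metrics (centralities are consumed from a
node attribute table, never computed here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
from scipy import stats

from .graphlets import GraphletIndex
from .grn import GRN
from .metrics import RGDRecord

__all__ = [
    "EdgeLabel",
    "NodeLabel",
    "LabelledSubnetwork",
    "AgreementStats",
    "lowest_rgd_tfs",
    "label_edges_and_nodes",
    "extract_graphlet_neighborhood",
    "metric_agreement",
]


@dataclass(frozen=True)
class EdgeLabel:
    """TP: edge in both states; FN: reference only; FP: compared only."""

    edge: tuple[str, str]
    label: str


@dataclass(frozen=True)
class NodeLabel:
    """TP: node in both states; FN: reference only; FP: compared only."""

    gene: str
    label: str


@dataclass
class LabelledSubnetwork:
    """Merged neighborhood of the selected genes with state labels."""

    selected: frozenset[str]
    nodes: list[NodeLabel]
    edges: list[EdgeLabel]
    components: list[frozenset[str]]  # weakly connected, largest first


@dataclass(frozen=True)
class AgreementStats:
    """Agreement between RGD and the change in one external metric.

    ``d`` is the overall disagreement rate (nodes flagged by exactly one of
    the two approaches over all evaluable nodes); ``dc`` conditions on a
    node being flagged by at least one.  Correlations relate RGD to the
    absolute metric change and are None when fewer than 3 nodes or a
    constant vector make them undefined.
    """

    spearman_rho: float | None
    kendall_tau: float | None
    pearson_r: float | None
    d: float | None
    dc: float | None
    n_both: int
    n_rgd_only: int
    n_metric_only: int
    n_total: int


def lowest_rgd_tfs(
    rgds: Sequence[RGDRecord], tfs: set[str], top_k: int = 5
) -> list[tuple[str, int, float]]:
    """TF genes ranked by ascending RGD (strongest rewiring first).

    Ties break by descending graphlet degree K, then lexicographic gene id,
    making the ranking a deterministic total order.  Only TFs in at least
    one reference graphlet are eligible; returns at most ``top_k`` rows of
    (gene, K, RGD).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    eligible = [r for r in rgds if r.gene in tfs and r.k >= 1]
    eligible.sort(key=lambda r: (r.rgd, -r.k, r.gene))
    return [(r.gene, r.k, r.rgd) for r in eligible[:top_k]]


def label_edges_and_nodes(
    reference: GRN, compared: GRN
) -> tuple[list[EdgeLabel], list[NodeLabel]]:
    """Label every edge and node of the two-state union exactly once."""

    def lab(in_ref: bool, in_cmp: bool) -> str:
        return "TP" if in_ref and in_cmp else ("FN" if in_ref else "FP")

    edges = [
        EdgeLabel(edge=e, label=lab(e in reference.edges, e in compared.edges))
        for e in sorted(reference.edges | compared.edges)
    ]
    nodes = [
        NodeLabel(gene=g, label=lab(g in reference.nodes, g in compared.nodes))
        for g in sorted(reference.nodes | compared.nodes)
    ]
    return edges, nodes


def extract_graphlet_neighborhood(
    selected: set[str],
    index: GraphletIndex,
    reference: GRN,
    compared: GRN,
) -> LabelledSubnetwork:
    """Merged subnetwork of all graphlets containing any selected gene.

    Nodes are the union of the triples of every reference graphlet instance
    touching a selected gene; edges are all true edges of either state
    among those nodes, each carrying its TP/FN/FP label.  A selected gene
    with graphlet degree 0 contributes nothing (warned).  Weakly connected
    components are reported largest-first over the subnetwork's labelled
    edges plus its isolated members.
    """
    missing = {g for g in selected if g not in index.grn.nodes}
    if missing:
        raise KeyError(f"selected genes not in the indexed network: {sorted(missing)}")
    sub_nodes: set[str] = set()
    for g in sorted(selected):
        ids = index.node_index.get(g, [])
        if not ids:
            warnings.warn(
                f"selected gene {g!r} participates in no graphlet", stacklevel=2
            )
            continue
        for i in ids:
            sub_nodes.update(index.instances[i].triple)
    all_edge_labels, all_node_labels = label_edges_and_nodes(reference, compared)
    edges = [
        el for el in all_edge_labels
        if el.edge[0] in sub_nodes and el.edge[1] in sub_nodes
    ]
    nodes = [nl for nl in all_node_labels if nl.gene in sub_nodes]
    g = nx.DiGraph()
    g.add_nodes_from(sub_nodes)
    g.add_edges_from(el.edge for el in edges)
    components = sorted(
        (frozenset(c) for c in nx.weakly_connected_components(g)),
        key=lambda c: (-len(c), sorted(c)),
    )
    return LabelledSubnetwork(
        selected=frozenset(selected),
        nodes=nodes,
        edges=edges,
        components=components,
    )


def metric_agreement(
    rgds: Sequence[RGDRecord],
    metric_ref: Mapping[str, float],
    metric_cmp: Mapping[str, float],
    change_epsilon: float = 0.0,
) -> AgreementStats:
    """Compare what RGD flags against what an external metric flags.

    Evaluated over nodes with an RGD and a metric value in both states.  A
    node is identified by RGD iff RGD < 1.0, and by the metric iff the
    absolute between-state change exceeds ``change_epsilon`` (strict; the
    default 0 means any change counts).  Reports Spearman, Kendall and
    Pearson correlations between RGD and |delta|, the disagreement rates d
    and dc, and the contingency counts.
    """
    if change_epsilon < 0:
        raise ValueError("change_epsilon must be non-negative")
    common = [
        (r.gene, r.rgd, abs(metric_ref[r.gene] - metric_cmp[r.gene]))
        for r in rgds
        if r.gene in metric_ref and r.gene in metric_cmp
    ]
    n_total = len(common)
    n_both = n_rgd = n_met = 0
    for _, rgd, delta in common:
        by_rgd = rgd < 1.0
        by_met = delta > change_epsilon
        if by_rgd and by_met:
            n_both += 1
        elif by_rgd:
            n_rgd += 1
        elif by_met:
            n_met += 1
    d = (n_rgd + n_met) / n_total if n_total else None
    denom = n_both + n_rgd + n_met
    dc = (n_rgd + n_met) / denom if denom else None

    rho = tau = r_ = None
    if n_total >= 3:
        rgd_v = [x[1] for x in common]
        delta_v = [x[2] for x in common]
        if len(set(rgd_v)) > 1 and len(set(delta_v)) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = float(stats.spearmanr(rgd_v, delta_v).statistic)
                tau = float(stats.kendalltau(rgd_v, delta_v).statistic)
                r_ = float(stats.pearsonr(rgd_v, delta_v).statistic)
    return AgreementStats(
        spearman_rho=rho,
        kendall_tau=tau,
        pearson_r=r_,
        d=d,
        dc=dc,
        n_both=n_both,
        n_rgd_only=n_rgd,
        n_metric_only=n_met,
        n_total=n_total,
    )
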