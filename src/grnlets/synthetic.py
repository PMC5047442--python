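"""Synthetic GRN factory: random networks, randomization baselines, and
controlled perturbations.

These generators stand in for downloadable regulatory catalogues so every
other module is testable offline, and they provide the null baselines for
the comparison metrics: a reference compared against progressively more
randomized copies of itself traces how REC/RGD decay toward their chance
level.  Edges always run from a designated TF subset to arbitrary other
genes, never as self-loops, matching the GRN invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .grn import GRN

__all__ = ["RandomGRNSpec", "generate_random_grn", "rewire", "perturb"]


@dataclass(frozen=True)
class RandomGRNSpec:
    """Size parameters of a random GRN draw.

    Capacity is ``n_tfs * (n_nodes - 1)``: each TF may regulate every other
    gene (self-loops excluded).  The first ``n_tfs`` node labels are the
    TFs, so the TF set is deterministic and only the edge draw is random.
    """

    n_nodes: int
    n_tfs: int
    n_edges: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_nodes < 0 or self.n_tfs < 0 or self.n_edges < 0:
            raise ValueError("sizes must be non-negative")
        if self.n_tfs > self.n_nodes:
            raise ValueError("n_tfs cannot exceed n_nodes")
        if self.n_edges > self.capacity:
            raise ValueError(
                f"n_edges={self.n_edges} exceeds capacity {self.capacity} "
                f"for {self.n_tfs} TFs over {self.n_nodes} nodes"
            )

    @property
    def capacity(self) -> int:
        return self.n_tfs * max(self.n_nodes - 1, 0)


def _node_labels(n: int) -> list[str]:
    width = len(str(max(n - 1, 0)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_random_grn(spec: RandomGRNSpec, *, name: str | None = None) -> GRN:
    """Draw ``n_edges`` distinct TF-sourced ordered pairs uniformly.

    Sampling is without replacement over the full {TF} x {other genes}
    capacity, so the same spec and seed always reproduce the same network.
    """
    labels = _node_labels(spec.n_nodes)
    tfs = labels[: spec.n_tfs]
    rng = np.random.default_rng(spec.seed)
    picks = rng.choice(spec.capacity, size=spec.n_edges, replace=False) if spec.n_edges else []
    edges = []
    for p in picks:
        ti, rest = divmod(int(p), spec.n_nodes - 1)
        # skip the TF's own slot to exclude self-loops
        tj = rest if rest < ti else rest + 1
        edges.append((labels[ti], labels[tj]))
    return GRN(
        name=name or f"random-n{spec.n_nodes}-t{spec.n_tfs}-e{spec.n_edges}-s{spec.seed}",
        nodes=frozenset(labels),
        tf_nodes=frozenset(tfs),
        edges=frozenset(edges),
    )


def rewire(
    grn: GRN, n_swaps: int, seed: int, *, mode: str = "swap"
) -> GRN:
    """Randomize a network while keeping its size.

    ``mode="swap"`` (default) performs ``n_swaps`` accepted double-edge
    swaps (a->b, c->d) => (a->d, c->b), rejecting any swap that would
    create a self-loop or a duplicate edge; every node's in- and out-degree
    is preserved exactly, which is the standard null model for regulatory
    networks.  ``mode="resample"`` instead redraws the same number of edges
    uniformly from the same TF set, preserving only |E|.  ``n_swaps = 0``
    returns the network unchanged; so does a network with fewer than two
    edges (with a warning).
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    if mode not in ("swap", "resample"):
        raise ValueError(f"unknown rewire mode {mode!r}")
    if n_swaps == 0:
        return grn
    if len(grn.edges) < 2:
        warnings.warn("network has < 2 edges; rewiring is a no-op", stacklevel=2)
        return grn
    if mode == "resample":
        labels = sorted(grn.nodes)
        tfs = sorted(grn.tf_nodes)
        rng = np.random.default_rng(seed)
        pairs = [(s, t) for s in tfs for t in labels if t != s]
        picks = rng.choice(len(pairs), size=len(grn.edges), replace=False)
        return GRN(
            name=f"{grn.name}|resampled-s{seed}",
            nodes=grn.nodes,
            tf_nodes=grn.tf_nodes,
            edges=frozenset(pairs[int(p)] for p in picks),
        )
    g = nx.DiGraph()
    g.add_nodes_from(sorted(grn.nodes))
    g.add_edges_from(sorted(grn.edges))
    try:
        nx.directed_edge_swap(
            g, nswap=n_swaps, max_tries=200 * n_swaps + 1000, seed=seed
        )
    except nx.NetworkXException as exc:  # too few swappable configurations
        warnings.warn(f"rewiring stopped early: {exc}", stacklevel=2)
    return GRN(
        name=f"{grn.name}|rewired-{n_swaps}-s{seed}",
        nodes=grn.nodes,
        tf_nodes=grn.tf_nodes,
        edges=frozenset(g.edges()),
    )


def perturb(
    grn: GRN, remove_fraction: float, add_fraction: float, seed: int
) -> GRN:
    """Remove a random fraction of edges and add random new TF-sourced ones.

    Removes ``round(remove_fraction * |E|)`` uniformly chosen edges, then
    adds ``round(add_fraction * |E|)`` edges drawn uniformly from the
    unused TF-sourced pairs (fewer if capacity runs out).  Node and TF sets
    are unchanged; reproducible by seed.
    """
    if not 0.0 <= remove_fraction <= 1.0 or not 0.0 <= add_fraction <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(grn.edges)
    n_remove = round(remove_fraction * len(edges))
    n_add = round(add_fraction * len(edges))
    keep = set(edges)
    if n_remove:
        drop = rng.choice(len(edges), size=n_remove, replace=False)
        keep -= {edges[int(i)] for i in drop}
    if n_add:
        labels = sorted(grn.nodes)
        candidates = [
            (s, t)
            for s in sorted(grn.tf_nodes)
            for t in labels
            if t != s and (s, t) not in grn.edges
        ]
        n_add = min(n_add, len(candidates))
        if n_add:
            picks = rng.choice(len(candidates), size=n_add, replace=False)
            keep |= {candidates[int(i)] for i in picks}
    return GRN(
        name=f"{grn.name}|perturbed-s{seed}",
        nodes=grn.nodes,
        tf_nodes=grn.tf_nodes,
        edges=frozenset(keep),
    )
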