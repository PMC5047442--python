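"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's enumeration and scoring paths:
they loop over all C(n, 3) node triples, build the induced 3x3 adjacency
matrices entry by entry, and decide graphlet membership from first
principles (>= 2 true edges, no untouched node), so they can certify the
optimized implementation.
"""

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import settings

from grnlets import GRN, RandomGRNSpec, generate_random_grn

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def induced_matrix(triple, grn):
    """3x3 0/1 adjacency of the induced subgraph, rows/cols in triple order.

    A gene absent from the network simply has no edges, which realizes the
    absent-node rule (all-zero row and column) with no special casing.
    """
    a = np.zeros((3, 3), dtype=int)
    for i in range(3):
        for j in range(3):
            if i != j and (triple[i], triple[j]) in grn.edges:
                a[i, j] = 1
    return a


def is_graphlet_matrix(a):
    if a.sum() < 2:
        return False
    touched = (a.sum(axis=0) + a.sum(axis=1)) > 0
    return bool(touched.all())


def oracle_triples(grn):
    """All graphlet triples by exhaustive O(n^3) enumeration."""
    return [
        t
        for t in combinations(sorted(grn.nodes), 3)
        if is_graphlet_matrix(induced_matrix(t, grn))
    ]


def oracle_rec(triple, reference, compared):
    a = induced_matrix(triple, reference)
    b = induced_matrix(triple, compared)
    return 1.0 - np.abs(a - b).sum() / 6.0


def oracle_rgd(reference, compared):
    """Per-gene mean REC over its reference graphlets, from scratch."""
    per_gene = {}
    for t in oracle_triples(reference):
        rec = oracle_rec(t, reference, compared)
        for g in t:
            per_gene.setdefault(g, []).append(rec)
    return {g: sum(v) / len(v) for g, v in per_gene.items()}


def matrices_isomorphic(a, b):
    """Triad isomorphism by trying all 6 node permutations."""
    for p in permutations(range(3)):
        if np.array_equal(a[np.ix_(p, p)], b):
            return True
    return False


@pytest.fixture
def star():
    """a regulates b, c, d: three type-1 (fan-out) graphlets."""
    return GRN.from_edges([("a", "b"), ("a", "c"), ("a", "d")], name="star")


@pytest.fixture
def chain():
    """Cascade a -> b -> c: a single two-TF graphlet."""
    return GRN.from_edges([("a", "b"), ("b", "c")], name="chain")


@pytest.fixture
def ffl():
    """Feed-forward loop a -> b -> c with a -> c."""
    return GRN.from_edges([("a", "b"), ("a", "c"), ("b", "c")], name="ffl")


@pytest.fixture
def random_grn():
    def make(n=30, t=6, e=45, seed=0):
        return generate_random_grn(
            RandomGRNSpec(n_nodes=n, n_tfs=t, n_edges=e, seed=seed)
        )

    return make
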