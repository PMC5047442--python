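"""Triad taxonomy, canonicalization, classification and enumeration."""

from itertools import combinations, permutations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from grnlets import (
    GRAPHLET_TYPES,
    GRN,
    RandomGRNSpec,
    canonical_code,
    classify_triad,
    enumerate_graphlets,
    generate_random_grn,
    graphlet_degree,
    triad_code,
)
from grnlets.graphlets import PAIR_ORDER, _apply_perm

from conftest import induced_matrix, is_graphlet_matrix, matrices_isomorphic, oracle_triples


class TestTaxonomy:
    def test_exactly_13_types(self):
        assert len(GRAPHLET_TYPES) == 13
        assert len({t.canonical_code for t in GRAPHLET_TYPES}) == 13

    def test_required_tf_distribution(self):
        """One single-TF class, five two-TF classes, seven three-TF classes."""
        by_tfs = {}
        for t in GRAPHLET_TYPES:
            by_tfs.setdefault(t.required_tf_count, []).append(t.type_id)
        assert sorted(by_tfs[1]) == [1]
        assert sorted(by_tfs[2]) == [2, 3, 4, 5, 6]
        assert sorted(by_tfs[3]) == [7, 8, 9, 10, 11, 12, 13]

    def test_type_13_is_complete_triad(self):
        t13 = GRAPHLET_TYPES[-1]
        assert t13.type_id == 13 and t13.true_edge_count == 6
        assert t13.canonical_code == 63
        # every other type leaves at least one ordered pair as a false edge
        assert all(t.true_edge_count < 6 for t in GRAPHLET_TYPES[:-1])

    def test_classes_partition_the_valid_codes(self):
        """Each of the 64 patterns either fails the definition or lands in
        exactly one class, and every class is hit."""
        hit = set()
        for code in range(64):
            g = classify_triad(code)
            edges = sum(code >> i & 1 for i in range(6))
            touched = {x for i, p in enumerate(PAIR_ORDER) if code >> i & 1 for x in p}
            if edges >= 2 and len(touched) == 3:
                assert g is not None
                hit.add(g.type_id)
            else:
                assert g is None
        assert hit == set(range(1, 14))


class TestCanonicalCode:
    @given(code=st.integers(0, 63))
    def test_permutation_invariance(self, code):
        for p in permutations(range(3)):
            assert canonical_code(_apply_perm(code, p)) == canonical_code(code)

    def test_isomorphic_single_edges_agree(self):
        assert canonical_code(0b000001) == canonical_code(0b001000)  # 1->2 vs 2->3

    def test_fixed_points(self):
        assert canonical_code(0) == 0
        assert canonical_code(63) == 63

    @given(a=st.integers(0, 63), b=st.integers(0, 63))
    def test_canonical_equality_iff_isomorphic(self, a, b):
        """The canonical code is a perfect isomorphism key."""
        nodes = ("x", "y", "z")
        ga = GRN.from_edges(
            [(nodes[i], nodes[j]) for k, (i, j) in enumerate(PAIR_ORDER) if a >> k & 1],
            nodes=nodes, tf_nodes=nodes,
        )
        gb = GRN.from_edges(
            [(nodes[i], nodes[j]) for k, (i, j) in enumerate(PAIR_ORDER) if b >> k & 1],
            nodes=nodes, tf_nodes=nodes,
        )
        iso = matrices_isomorphic(induced_matrix(nodes, ga), induced_matrix(nodes, gb))
        assert (canonical_code(a) == canonical_code(b)) == iso


class TestClassifyTriad:
    def test_fan_out_is_type_1(self):
        g = GRN.from_edges([("a", "b"), ("a", "c")])
        assert classify_triad(triad_code(("a", "b", "c"), g)).type_id == 1

    def test_complete_triad_is_type_13(self):
        edges = [(x, y) for x in "abc" for y in "abc" if x != y]
        g = GRN.from_edges(edges)
        assert classify_triad(triad_code(("a", "b", "c"), g)).type_id == 13

    def test_mutual_dyad_with_untouched_node_is_not_a_graphlet(self):
        g = GRN.from_edges([("a", "b"), ("b", "a")], nodes=["c"])
        assert classify_triad(triad_code(("a", "b", "c"), g)) is None

    def test_single_edge_is_not_a_graphlet(self):
        g = GRN.from_edges([("a", "b")], nodes=["c"])
        assert classify_triad(triad_code(("a", "b", "c"), g)) is None


class TestEnumerate:
    def test_star_gives_three_type1_instances(self, star):
        idx = enumerate_graphlets(star)
        assert [i.type_id for i in idx.instances] == [1, 1, 1]
        assert graphlet_degree(idx, "a") == 3
        assert all(graphlet_degree(idx, g) == 2 for g in "bcd")
        assert idx.nog == frozenset()

    def test_chain_gives_one_two_tf_instance(self, chain):
        idx = enumerate_graphlets(chain)
        assert len(idx.instances) == 1
        gtype = GRAPHLET_TYPES[idx.instances[0].type_id - 1]
        assert gtype.required_tf_count == 2
        assert graphlet_degree(idx, "b") == 1

    def test_edgeless_network_all_nog(self):
        g = GRN.from_edges([], nodes=["a", "b", "c"])
        idx = enumerate_graphlets(g)
        assert idx.instances == [] and idx.nog == {"a", "b", "c"}

    def test_unknown_gene_degree_raises(self, star):
        idx = enumerate_graphlets(star)
        with pytest.raises(KeyError):
            graphlet_degree(idx, "zzz")

    def test_node_index_consistent_with_instances(self, random_grn):
        idx = enumerate_graphlets(random_grn(n=40, t=8, e=70, seed=3))
        for gene, ids in idx.node_index.items():
            assert all(gene in idx.instances[i].triple for i in ids)
        assert sum(idx.type_counts.values()) == len(idx.instances)
        assert idx.nog | set(idx.node_index) == idx.grn.nodes

    def test_triples_unique(self, random_grn):
        idx = enumerate_graphlets(random_grn(n=40, t=8, e=70, seed=4))
        triples = [i.triple for i in idx.instances]
        assert len(triples) == len(set(triples))

    def test_every_instance_contains_a_tf(self, random_grn):
        g = random_grn(n=40, t=8, e=70, seed=5)
        idx = enumerate_graphlets(g)
        for inst in idx.instances:
            n_tfs_in_triple = sum(x in g.tf_nodes for x in inst.triple)
            required = GRAPHLET_TYPES[inst.type_id - 1].required_tf_count
            assert 1 <= required <= n_tfs_in_triple

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, random_grn, seed):
        """TF-anchored sweep equals exhaustive O(n^3) triple enumeration."""
        g = random_grn(n=35, t=7, e=60, seed=seed)
        idx = enumerate_graphlets(g)
        assert [i.triple for i in idx.instances] == oracle_triples(g)

    @pytest.mark.parametrize("seed", range(3))
    def test_instance_classes_match_matrix_isomorphism(self, random_grn, seed):
        """Two instances share a type id iff their induced matrices are
        isomorphic (checked by explicit permutation of the matrices)."""
        g = random_grn(n=20, t=5, e=35, seed=seed)
        idx = enumerate_graphlets(g)
        mats = [induced_matrix(i.triple, g) for i in idx.instances]
        for (ia, ma), (ib, mb) in combinations(zip(idx.instances, mats), 2):
            assert (ia.type_id == ib.type_id) == matrices_isomorphic(ma, mb)
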