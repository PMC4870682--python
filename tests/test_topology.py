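"""Tree metrics: classification, DB, Wiener index, canonical form.

Independent oracles: networkx all-pairs shortest paths for the Wiener
index, and a brute-force permutation-matching recursion for rooted
unordered tree isomorphism.
"""

import itertools

import networkx as nx
import pytest

from conftest import random_tree_parents
from hyperbranch.errors import StructureError
from hyperbranch.fixtures import dendrimer_topology, path_topology, star_topology
from hyperbranch.topology import CGTopology, filter_unique


def nx_wiener(topo):
    g = nx.Graph(topo.edges())
    g.add_nodes_from(range(len(topo)))
    return sum(
        d for _, row in nx.all_pairs_shortest_path_length(g) for d in row.values()
    ) // 2


def brute_force_rooted_iso(t1, r1, t2, r2):
    """Rooted unordered isomorphism by trying all child bijections."""
    c1 = t1.nodes[r1].children
    c2 = t2.nodes[r2].children
    if len(c1) != len(c2):
        return False
    if not c1:
        return True
    for perm in itertools.permutations(c2):
        if all(brute_force_rooted_iso(t1, a, t2, b) for a, b in zip(c1, perm)):
            return True
    return False


def all_rooted_trees(n):
    """Every labeled rooted tree with parents preceding children."""
    for parents in itertools.product(*[range(i) for i in range(1, n)]):
        yield CGTopology.from_parents([None, *parents])


class TestConstruction:
    def test_from_parents_rejects_forward_reference(self):
        with pytest.raises(StructureError):
            CGTopology.from_parents([None, 2, 1])

    def test_from_parents_rejects_second_root(self):
        with pytest.raises(StructureError):
            CGTopology.from_parents([None, None, 0])

    def test_edge_count_is_nodes_minus_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 40))
            topo = CGTopology.from_parents(random_tree_parents(n, rng))
            assert len(topo.edges()) == n - 1


class TestClassification:
    def test_path_of_six(self):
        # root + 5: interior root of a 6-chain -> 3 linear, 2 terminal
        topo = path_topology(6)
        assert topo.classify() == (0, 3, 2)

    def test_small_branched_tree(self):
        # root with 3 children, one child with 2 children of its own
        topo = star_topology(3)
        topo.add_child(1)
        topo.add_child(1)
        assert topo.classify() == (1, 0, 4)

    def test_two_layer_dendrimer(self):
        topo = dendrimer_topology(3, 2)  # 1 + 3 + 6 units
        assert len(topo) == 10
        assert topo.classify() == (3, 0, 6)

    def test_dlt_plus_root_equals_dp(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 60))
            topo = CGTopology.from_parents(random_tree_parents(n, rng))
            try:
                d, l, t = topo.classify()
            except StructureError:
                continue  # random tree exceeded AB2 valence; not a core
            assert d + l + t + 1 == topo.dp

    def test_overbranched_core_rejected(self):
        topo = star_topology(2)
        for _ in range(3):
            topo.add_child(1)
        with pytest.raises(StructureError, match="at most 2"):
            topo.classify()


class TestDegreeOfBranching:
    @pytest.mark.parametrize("n", [4, 10, 25])
    def test_linear_chain_scores_zero(self, n):
        assert path_topology(n).degree_of_branching() == 0.0

    def test_perfect_dendrimer_scores_one(self):
        assert dendrimer_topology(3, 3).degree_of_branching() == 1.0

    def test_holter_formula_hand_value(self):
        # D=1, L=1: root -> a -> (b, c), b -> d  gives D=1 L=1 T=2
        topo = CGTopology.from_parents([None, 0, 1, 1, 2])
        assert topo.classify() == (1, 1, 2)
        assert topo.degree_of_branching() == pytest.approx(2 / 3)

    def test_frechet_convention_differs_on_chains(self):
        topo = path_topology(10)
        assert topo.degree_of_branching("holter") == 0.0
        assert topo.degree_of_branching("frechet") == pytest.approx(2 / 9)


class TestWienerIndex:
    def test_two_bonded_units(self):
        assert CGTopology.from_parents([None, 0]).wiener_index() == 1

    def test_path_of_five_closed_form(self):
        # n(n^2-1)/6 = 20
        assert path_topology(5).wiener_index() == 20

    def test_star_of_four_leaves(self):
        assert star_topology(4).wiener_index() == 16

    def test_bond_split_sizes_sum_to_n(self, rng):
        topo = CGTopology.from_parents(random_tree_parents(15, rng))
        for _, vl, vr in topo.bond_splits():
            assert vl + vr == 15

    def test_matches_bfs_distance_sum_on_random_trees(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 61))
            topo = CGTopology.from_parents(random_tree_parents(n, rng))
            assert topo.wiener_index() == nx_wiener(topo)

    def test_low_wi_is_more_compact_than_high_wi(self, rng):
        # among trees of one size, the min-WI tree has eccentricity (root
        # height here) no larger than the max-WI tree
        from hyperbranch.growth import grow_core

        batch = [grow_core(40, 3, 0.4, rng) for _ in range(60)]
        by_wi = sorted(batch, key=lambda t: t.wiener_index())

        def height(t):
            return max(n.generation for n in t.nodes)

        assert height(by_wi[0]) <= height(by_wi[-1])


class TestCanonicalCode:
    def test_child_order_does_not_matter(self):
        a = CGTopology.from_parents([None, 0, 0, 1])  # child with leaf first
        b = CGTopology.from_parents([None, 0, 0, 2])  # same shape, other child
        assert a.canonical_code() == b.canonical_code()

    def test_path_and_star_differ(self):
        assert (
            CGTopology.from_parents([None, 0, 1, 2]).canonical_code()
            != CGTopology.from_parents([None, 0, 0, 0]).canonical_code()
        )

    @pytest.mark.parametrize(
        "n,n_classes", [(1, 1), (2, 1), (3, 2), (4, 4), (5, 9), (6, 20), (7, 48)]
    )
    def test_code_equality_is_isomorphism_exhaustively(self, n, n_classes):
        """AHU code equality coincides with brute-force isomorphism for all
        rooted trees up to 7 nodes; class counts are 1,1,2,4,9,20,48."""
        reps = []  # (topology, code)
        for topo in all_rooted_trees(n):
            code = topo.canonical_code()
            matched = None
            for rt, rc in reps:
                if brute_force_rooted_iso(topo, 0, rt, 0):
                    matched = rc
                    break
            if matched is None:
                reps.append((topo, code))
                assert all(code != rc for _, rc in reps[:-1])
            else:
                assert code == matched
        assert len(reps) == n_classes


class TestFilterUnique:
    def test_exact_copy_discarded(self):
        t = path_topology(6)
        kept, discarded = filter_unique([t, t.copy()])
        assert kept == [t] and discarded == 1

    def test_relabelings_collapse_to_one(self, rng):
        base = CGTopology.from_parents([None, 0, 0, 1, 1, 2])
        variants = [base]
        # permute the order in which children were attached
        variants.append(CGTopology.from_parents([None, 0, 0, 2, 2, 1]))
        for _ in range(8):
            variants.append(base.copy())
        kept, discarded = filter_unique(variants)
        assert len(kept) == 1 and discarded == 9

    def test_genuinely_different_trees_both_kept(self):
        a = CGTopology.from_parents([None, 0, 0, 1])
        b = CGTopology.from_parents([None, 0, 1, 2])
        assert not brute_force_rooted_iso(a, 0, b, 0)
        kept, discarded = filter_unique([a, b])
        assert len(kept) == 2 and discarded == 0
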