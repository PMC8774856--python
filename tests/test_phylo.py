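import math

import numpy as np
import pytest

from mitoprofile.errors import AlignmentError, MitoprofileError
from mitoprofile.phylo import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    overall_mean_distance,
    tn93_distance,
)
from mitoprofile.seq_io import MultipleAlignment


def aln_of(rows, ids=None):
    ids = ids or [f"t{i}" for i in range(len(rows))]
    return MultipleAlignment(ids=ids, rows=rows, reference_id=ids[0])


def random_additive_tree(n, rng):
    """Random binary tree; returns (leaf names, additive distance matrix,
    true non-trivial bipartitions). Independent of the NJ implementation."""
    import networkx as nx

    names = [f"t{i}" for i in range(n)]
    G = nx.Graph()
    G.add_edge("t0", "t1", weight=rng.uniform(0.1, 1.0))
    internal = 0
    for i in range(2, n):
        a, b = sorted(G.edges())[rng.integers(G.number_of_edges())]
        w = G[a][b]["weight"]
        x = f"x{internal}"
        internal += 1
        f = rng.uniform(0.2, 0.8)
        G.remove_edge(a, b)
        G.add_edge(a, x, weight=w * f)
        G.add_edge(x, b, weight=w * (1 - f))
        G.add_edge(x, f"t{i}", weight=rng.uniform(0.1, 1.0))
    D = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(G, f"t{i}")
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = lengths[f"t{j}"]
    leaves, anchor = set(names), min(names)
    parts = set()
    for a, b in list(G.edges()):
        H = G.copy()
        H.remove_edge(a, b)
        comp = {x for x in __import__("networkx").node_connected_component(H, a) if x in leaves}
        if 1 < len(comp) < n - 1:
            parts.add(frozenset(comp if anchor not in comp else leaves - comp))
    return names, D, parts


class TestDistances:
    def test_single_mismatch_p_distance(self):
        dm = distance_matrix(aln_of(["ACGT", "ACGA"]), model="p")
        assert dm.get("t0", "t1") == pytest.approx(0.25)

    def test_identical_rows_zero_for_both_models(self):
        for model in ("p", "TN93"):
            dm = distance_matrix(aln_of(["ACGTACGT", "ACGTACGT"]), model=model)
            assert dm.get("t0", "t1") == 0.0

    def test_tn93_matches_hand_evaluated_closed_form(self):
        # 20 sites: one A<->G transition, one C<->T transition, one A<->C
        # transversion; evaluated by explicit arithmetic below
        r1 = "AACCGGTTAACCGGTTAACC"
        r2 = "GACCGGTTAATCGGTTCACC"
        dm = distance_matrix(aln_of([r1, r2]), model="TN93")
        n = 20
        pooled = r1 + r2
        pA, pC, pG, pT = (pooled.count(x) / 40 for x in "ACGT")
        pR, pY = pA + pG, pC + pT
        P1, P2, Q = 1 / n, 1 / n, 1 / n
        expected = (
            -2 * pA * pG / pR * math.log(1 - pR * P1 / (2 * pA * pG) - Q / (2 * pR))
            - 2 * pT * pC / pY * math.log(1 - pY * P2 / (2 * pT * pC) - Q / (2 * pY))
            - 2 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY)
            * math.log(1 - Q / (2 * pR * pY))
        )
        assert dm.get("t0", "t1") == pytest.approx(expected, rel=1e-12)

    def test_tn93_dominates_p_distance(self, synthetic_alignment):
        aln, _ = synthetic_alignment
        p = distance_matrix(aln, model="p")
        t = distance_matrix(aln, model="TN93")
        assert (t.values >= p.values - 1e-12).all()

    def test_tn93_converges_to_p_at_low_divergence(self):
        rows = ["A" * 400 + "C" * 300 + "G" * 150 + "T" * 150]
        mutant = list(rows[0])
        mutant[10] = "G"
        mutant[500] = "T"
        rows.append("".join(mutant))
        p = distance_matrix(aln_of(rows), model="p").get("t0", "t1")
        t = distance_matrix(aln_of(rows), model="TN93").get("t0", "t1")
        assert p <= 0.01
        assert t == pytest.approx(p, rel=0.02)

    def test_saturated_pair_flagged_undefined(self):
        dm = distance_matrix(aln_of(["AGAGAGAG", "GAGAGAGA"]), model="TN93")
        assert ("t0", "t1") in dm.undefined_pairs
        assert math.isnan(dm.get("t0", "t1"))

    def test_pairwise_deletion_ignores_gaps_per_pair(self):
        dm = distance_matrix(aln_of(["ACGT-CGT", "ACGAACGT", "ACGTACGT"]), model="p")
        assert dm.get("t0", "t1") == pytest.approx(1 / 7)
        assert dm.get("t1", "t2") == pytest.approx(1 / 8)

    def test_zero_considered_sites_is_an_error(self):
        with pytest.raises(AlignmentError):
            distance_matrix(aln_of(["AC--", "--GT"]), model="p")


class TestOverallMean:
    def test_two_taxa(self):
        m = DistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.5], [0.5, 0]]), model="p")
        assert overall_mean_distance(m) == pytest.approx(0.5)

    def test_equals_direct_average(self):
        rng = np.random.default_rng(4)
        n = 6
        v = rng.uniform(0, 1, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = DistanceMatrix(ids=[f"t{i}" for i in range(n)], values=v, model="p")
        direct = np.mean([v[i, j] for i in range(n) for j in range(i + 1, n)])
        assert overall_mean_distance(m) == pytest.approx(direct)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        v = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(ids=["a", "b", "c"], values=v, model="p"))
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_recovers_known_five_taxon_additive_tree(self):
        rng = np.random.default_rng(0)
        names, D, parts = random_additive_tree(5, rng)
        tree = nj_tree(DistanceMatrix(ids=names, values=D, model="p"))
        assert tree.bipartitions() == parts
        # additivity: leaf-to-leaf path lengths reproduce the input distances
        def path_lengths(node, acc, out):
            if node.is_leaf:
                out[node.name] = acc + node.length
                return
            for ch in node.children:
                path_lengths(ch, acc + node.length, out)

        # verify pairwise distances through the tree for a few pairs
        import networkx as nx

        G = nx.Graph()

        def build(node, parent):
            me = id(node) if not node.is_leaf else node.name
            if parent is not None:
                G.add_edge(parent, me, weight=node.length)
            for ch in node.children:
                build(ch, me)

        build(tree.root, None)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = nx.shortest_path_length(G, a, b, weight="weight")
                assert d == pytest.approx(D[names.index(a), names.index(b)], abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_additive_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        names, D, parts = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(ids=names, values=D, model="p"))
        assert tree.bipartitions() == parts

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        names, D, _ = random_additive_tree(7, rng)
        ours = nj_tree(DistanceMatrix(ids=names, values=D, model="p"))
        theirs = skbio_nj(SkbioDM(D, ids=names))
        their_parts = set()
        leaves = set(names)
        anchor = min(leaves)
        for node in theirs.non_tips(include_self=False):
            sub = {t.name for t in node.tips()}
            if 1 < len(sub) < len(leaves) - 1:
                their_parts.add(frozenset(sub if anchor not in sub else leaves - sub))
        assert ours.bipartitions() == their_parts

    def test_requires_three_taxa(self):
        m = DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2)), model="p")
        with pytest.raises(MitoprofileError):
            nj_tree(m)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MitoprofileError):
            DistanceMatrix(
                ids=["a", "b"], values=np.array([[0.0, 0.1], [0.2, 0.0]]), model="p"
            )


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self):
        rng = np.random.default_rng(8)
        names, D, _ = random_additive_tree(6, rng)
        tree = nj_tree(DistanceMatrix(ids=names, values=D, model="p"))
        back = PhyloTree.from_newick(tree.to_newick())
        assert back.leaf_names() == tree.leaf_names()
        assert back.bipartitions() == tree.bipartitions()
        assert back.to_newick() == tree.to_newick()

    def test_parses_external_newick(self):
        t = PhyloTree.from_newick("((a:1,b:2)90:0.5,c:3,d:4);")
        assert t.leaf_names() == ["a", "b", "c", "d"]
        assert t.root.children[0].support == 90


class TestBootstrap:
    def test_clean_signal_gets_full_support(self):
        # four taxa, one internal edge separating {t0,t1} from {t2,t3};
        # every informative column supports the same split (no homoplasy)
        rows = [
            "A" * 50 + "C" * 10,
            "A" * 50 + "G" * 10,
            "T" * 50 + "C" * 10,
            "T" * 50 + "G" * 10,
        ]
        aln = aln_of(rows)
        tree = bootstrap_support(aln, model="p", B=100, seed=1)
        supports = [
            ch.support
            for ch in tree.root.children
            if not ch.is_leaf and ch.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_given_seed(self, synthetic_alignment):
        aln, _ = synthetic_alignment
        t1 = bootstrap_support(aln, B=25, seed=42)
        t2 = bootstrap_support(aln, B=25, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_invariant_to_row_order(self):
        rows = [
            "AAAAACCCCCGGGGGAC",
            "AAAAACCCCCGGGTGAC",
            "TTTTTCCCCCGGGGGAC",
            "TTTTTCCCCCGGGTTAC",
            "TTTTACCCCCGGGTTAC",
        ]
        ids = [f"t{i}" for i in range(5)]
        a1 = MultipleAlignment(ids=ids, rows=rows, reference_id="t0")
        order = [3, 1, 4, 0, 2]
        a2 = MultipleAlignment(
            ids=[ids[i] for i in order], rows=[rows[i] for i in order],
            reference_id="t3",
        )
        t1 = bootstrap_support(a1, model="p", B=50, seed=9)
        t2 = bootstrap_support(a2, model="p", B=50, seed=9)
        assert t1.to_newick() == t2.to_newick()
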