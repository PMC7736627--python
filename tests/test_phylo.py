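"""Supermatrix construction, TN93, neighbor joining, bootstrap, constraints."""

import math

import numpy as np
import pytest

from mitocomp.divergence import p_distance
from mitocomp.phylo import (DistanceMatrix, PhyloTree, bootstrap_support,
                            build_supermatrix, check_constraints,
                            distance_matrix, neighbor_joining, tn93_distance)


def random_tree_distances(rng, n_taxa):
    """A random additive matrix plus the generating topology's bipartitions.

    Builds a random binary tree by sequential attachment with positive branch
    lengths, then returns exact leaf-to-leaf path lengths (the independent
    oracle for NJ consistency)."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); leaves are taxa strings
    next_id = [0]

    def new_internal():
        next_id[0] += 1
        return f"__n{next_id[0]}"

    adj: dict[str, list[tuple[str, float]]] = {}

    def connect(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def bl():
        return float(rng.uniform(0.5, 3.0))

    center = new_internal()
    for t in taxa[:3]:
        connect(center, t, bl())
    edges = [(center, t) for t in taxa[:3]]
    for t in taxa[3:]:
        u, v = edges[rng.integers(len(edges))]
        w_uv = next(w for x, w in adj[u] if x == v)
        mid = new_internal()
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]
        split = float(rng.uniform(0.25, 0.75)) * w_uv
        connect(u, mid, split)
        connect(mid, v, w_uv - split)
        connect(mid, t, bl())
        edges = [(a, b) for a in adj for b, _ in adj[a] if a < b]

    def path_length(src, dst):
        stack = [(src, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == dst:
                return dist
            for nxt, w in adj.get(node, []):
                if nxt != prev:
                    stack.append((nxt, node, dist + w))
        raise AssertionError("disconnected")

    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = path_length(taxa[i], taxa[j])

    def leafset(node, prev):
        if not node.startswith("__"):
            return frozenset([node])
        out = frozenset()
        for nxt, _ in adj[node]:
            if nxt != prev:
                out |= leafset(nxt, node)
        return out

    ref = sorted(taxa)[0]
    all_taxa = frozenset(taxa)
    bips = set()
    for a in adj:
        for b, _ in adj[a]:
            if a < b:
                side = leafset(a, b)
                if 1 < len(side) < n:
                    bips.add(side if ref not in side else all_taxa - side)
    return DistanceMatrix(taxa=taxa, matrix=mat), bips


class TestSupermatrix:
    def test_width_and_boundaries(self, quartet):
        leaves, _ = quartet
        sm = build_supermatrix(leaves)
        assert sorted(sm.taxa) == ["OUT", "SA", "SM", "ST"]
        widths = [hi - lo for lo, hi in sm.gene_boundaries.values()]
        assert sum(widths) == sm.n_sites
        assert all(len(s) == sm.n_sites for s in sm.alignment.values())
        assert all(w % 3 == 0 for w in widths)

    def test_missing_gene_named_in_error(self, quartet):
        from mitocomp.genome_model import GeneTable, Mitogenome
        leaves, _ = quartet
        st = leaves["ST"]
        pruned = Mitogenome(st.sequence,
                            GeneTable([f for f in st.table if f.name != "ND6"],
                                      genome_length=st.table.genome_length),
                            species=st.species)
        bad = dict(leaves, ST=pruned)
        with pytest.raises(ValueError, match="ND6"):
            build_supermatrix(bad)

    def test_single_taxon(self, quartet):
        leaves, _ = quartet
        sm = build_supermatrix({"ST": leaves["ST"]})
        assert sm.taxa == ["ST"] and sm.n_sites > 11000


class TestTn93:
    def test_identical(self):
        assert tn93_distance("ACGTACGT" * 10, "ACGTACGT" * 10) == (0.0, False)

    def test_correction_inflates_p(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 2000))
        b = list(a)
        for i in rng.choice(2000, 100, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        b = "".join(b)
        d, sat = tn93_distance(a, b)
        p, _ = p_distance(a, b)
        assert not sat and d >= p

    def test_matches_independent_formula(self):
        """Closed form re-derived independently from pair counts."""
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), 1000, p=[0.35, 0.15, 0.15, 0.35]))
        b = list(a)
        for i in rng.choice(1000, 120, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        b = "".join(b)

        n = len(a)
        freq = {x: (a.count(x) + b.count(x)) / (2 * n) for x in "ACGT"}
        P1 = sum(1 for x, y in zip(a, b) if {x, y} == {"A", "G"}) / n
        P2 = sum(1 for x, y in zip(a, b) if {x, y} == {"C", "T"}) / n
        Q = sum(1 for x, y in zip(a, b)
                if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
        gR, gY = freq["A"] + freq["G"], freq["C"] + freq["T"]
        k1 = 2 * freq["A"] * freq["G"] / gR
        k2 = 2 * freq["T"] * freq["C"] / gY
        k3 = 2 * (gR * gY - freq["A"] * freq["G"] * gY / gR
                  - freq["T"] * freq["C"] * gR / gY)
        expected = (-k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
                    - k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
                    - k3 * math.log(1 - Q / (2 * gR * gY)))
        d, sat = tn93_distance(a, b)
        assert not sat
        assert d == pytest.approx(expected, abs=1e-12)

    def test_saturation_falls_back_to_p(self):
        d, sat = tn93_distance("AAAAAAAAAA", "GGGGGGGGGG")
        assert sat and 0 < d <= 1

    def test_strict_mode_raises_on_saturation(self):
        with pytest.raises(ValueError, match="undefined"):
            tn93_distance("AAAAAAAAAA", "GGGGGGGGGG", strict=True)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float))
        tree = neighbor_joining(dm)
        nwk = tree.to_newick(3)
        # pendant lengths (dAB+dAC-dBC)/2 = 1, 3, 5
        assert "A:1.000" in nwk and "B:3.000" in nwk and "C:5.000" in nwk

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> path-length matrix
        mat = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                        [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], mat))
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_equal_distance_star_is_deterministic(self):
        mat = np.ones((5, 5)) - np.eye(5)
        taxa = list("ABCDE")
        t1 = neighbor_joining(DistanceMatrix(taxa, mat.copy()))
        t2 = neighbor_joining(DistanceMatrix(taxa, mat.copy()))
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_consistency_on_random_additive_matrices(self, n_taxa):
        """NJ is consistent on additive matrices: the generating topology is
        recovered exactly (20 seeded cases per size here)."""
        for seed in range(20):
            rng = np.random.default_rng(1000 * n_taxa + seed)
            dm, true_bips = random_tree_distances(rng, n_taxa)
            tree = neighbor_joining(dm)
            assert tree.bipartitions() == true_bips, f"n={n_taxa} seed={seed}"

    def test_agrees_with_scikit_bio_on_additive_matrix(self):
        """Independent implementation cross-check on one seeded case."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        dm, true_bips = random_tree_distances(rng, 6)
        ours = neighbor_joining(dm).bipartitions()
        sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.taxa)
        sk_tree = PhyloTree.from_newick(str(skbio.tree.nj(sk_dm)))
        assert ours == sk_tree.bipartitions() == true_bips


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        nwk = "((A:0.1,B:0.2)95:0.05,(C:0.3,D:0.4)80:0.07,E:0.5);"
        tree = PhyloTree.from_newick(nwk)
        back = PhyloTree.from_newick(tree.to_newick())
        assert back.bipartitions() == tree.bipartitions()
        # bipartitions canonicalized as the side not containing taxon "A"
        assert tree.edge_supports() == {frozenset({"C", "D"}): 80.0,
                                        frozenset({"C", "D", "E"}): 95.0}
        assert back.edge_supports() == tree.edge_supports()


class TestBootstrap:
    def test_single_rep_supports_are_zero_or_hundred(self, quartet):
        leaves, _ = quartet
        sm = build_supermatrix(leaves)
        tree = bootstrap_support(sm, reps=1, seed=5)
        sup = [v for v in tree.edge_supports().values() if v is not None]
        assert sup and set(sup) <= {0.0, 100.0}

    def test_same_seed_same_supports(self, quartet):
        leaves, _ = quartet
        sm = build_supermatrix(leaves)
        t1 = bootstrap_support(sm, reps=25, seed=9)
        t2 = bootstrap_support(sm, reps=25, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_well_separated_clades_get_high_support(self, quartet):
        leaves, _ = quartet
        sm = build_supermatrix(leaves)
        tree = bootstrap_support(sm, reps=50, seed=2)
        # sole internal edge: {ST,SA} vs {SM,OUT}, canonicalized away from OUT
        support = tree.edge_supports()[frozenset({"SA", "ST"})]
        assert support >= 90.0


class TestConstraints:
    def test_sister_and_nonsister(self):
        tree = PhyloTree.from_newick("((ST:1,SA:1):1,SM:1,OUT:2);")
        assert check_constraints(tree, [{"ST", "SA"}]) == [True]
        assert check_constraints(tree, [{"ST", "SM"}]) == [False]
        assert check_constraints(tree, [{"ST", "SA", "SM"}]) == [True]

    def test_unknown_taxon(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError, match="unknown"):
            check_constraints(tree, [{"A", "Z"}])

    def test_simulated_topology_recovered(self, quartet):
        leaves, ledger = quartet
        sm = build_supermatrix(leaves)
        tree = neighbor_joining(distance_matrix(sm))
        assert check_constraints(tree, [{"ST", "SA"}, {"ST", "SA", "SM"}]) == \
            [True, True]
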