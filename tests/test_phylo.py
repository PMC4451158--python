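import numpy as np
import pytest

from its2barcode import (
    BootstrapConfig,
    DistanceMatrix,
    MultipleAlignment,
    ValidationError,
    bootstrap_support,
    is_monophyletic,
    neighbor_joining,
    read_newick,
    species_clade_supports,
)

from _oracles import random_additive_case


def _dm(ids, d):
    return DistanceMatrix(tuple(ids), np.asarray(d, dtype=float))


class TestNeighborJoining:
    def test_three_taxon_lengths_from_three_point_formulas(self):
        dm = _dm("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        rng = np.random.default_rng(5)
        ids, D, bip_lengths, leaf_lengths = random_additive_case(rng, 4)
        tree = neighbor_joining(_dm(ids, D))
        got_bips = {bip: node.length for bip, node in tree.bipartitions().items()}
        assert set(got_bips) == set(bip_lengths)
        for bip, ln in bip_lengths.items():
            assert got_bips[bip] == pytest.approx(ln, abs=1e-9)
        for leaf in tree.leaves():
            assert leaf.length == pytest.approx(leaf_lengths[leaf.name], abs=1e-9)

    def test_path_lengths_reproduce_additive_input(self):
        rng = np.random.default_rng(9)
        ids, D, _, _ = random_additive_case(rng, 6)
        tree = neighbor_joining(_dm(ids, D))
        # accumulate leaf-to-root-path lengths, then pairwise distances
        depths = {}

        def walk(node, acc):
            acc = acc + (node.length or 0.0)
            if node.is_leaf:
                depths[node.name] = (acc, node)
            for c in node.children:
                walk(c, acc)

        # use the bipartition structure instead: distances via recursion
        paths = _tree_path_lengths(tree)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert paths[frozenset((a, b))] == pytest.approx(
                    D[ids.index(a), ids.index(b)], abs=1e-9
                )

    def test_degenerate_near_star_matrix_does_not_crash(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.3
        tree = neighbor_joining(_dm(["a", "b", "c", "d"], d))
        assert sorted(tree.leaf_names()) == ["a", "b", "c", "d"]

    def test_too_few_or_nonfinite_inputs_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(_dm("AB", [[0, 1], [1, 0]]))
        bad = np.zeros((3, 3))
        bad[0, 1] = bad[1, 0] = np.inf
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(("a", "b", "c"), bad))

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        n = 7
        ids = [f"t{k}" for k in range(n)]
        m = rng.uniform(0.05, 0.5, size=(n, n))
        d = np.triu(m, 1)
        d = d + d.T
        mine = neighbor_joining(_dm(ids, d))
        theirs = read_newick(str(skbio_nj(SkbioDM(d, ids))))
        assert set(mine.bipartitions()) == set(theirs.bipartitions())


def _tree_path_lengths(tree):
    """Pairwise leaf path lengths via postorder accumulation."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: node.length or 0.0}
        below = []
        for c in node.children:
            below.append(walk(c))
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        out[frozenset((a, b))] = da + db
        merged = {}
        for sub in below:
            for a, da in sub.items():
                merged[a] = da + (node.length or 0.0)
        return merged

    walk(tree.root)
    return out


class TestBootstrap:
    def _strong_signal_msa(self):
        # two pairs separated by 30 transition sites (P=0.25, well inside
        # the K2P correction range)
        left = "A" * 30 + "C" * 90
        right = "G" * 30 + "C" * 90
        rows = {
            "L1": left, "L2": left,
            "R1": right, "R2": right,
        }
        labels = {"L1": "Sp_l", "L2": "Sp_l", "R1": "Sp_r", "R2": "Sp_r"}
        return MultipleAlignment(rows, labels)

    def test_strong_central_split_gets_full_support(self):
        msa = self._strong_signal_msa()
        tree = bootstrap_support(msa, BootstrapConfig(replicates=100, seed=0))
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(s >= 99.0 for s in supports)

    def test_identical_seed_identical_supports(self, default_msa):
        cfg = BootstrapConfig(replicates=30, seed=123)
        t1 = bootstrap_support(default_msa, cfg)
        t2 = bootstrap_support(default_msa, cfg)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_bounded(self, default_msa):
        tree = bootstrap_support(default_msa, BootstrapConfig(replicates=25, seed=2))
        for node in tree.bipartitions().values():
            assert 0.0 <= node.support <= 100.0

    def test_structureless_alignment_gets_weak_supports(self):
        # star-like data: every row mutates the same base sequence at its
        # own independent sites, so no split has shared character support
        rng = np.random.default_rng(17)
        bases = list("ACGT")
        base = rng.choice(bases, size=120)
        rows = {}
        for k in range(8):
            arr = base.copy()
            for site in rng.choice(120, size=8, replace=False):
                arr[site] = bases[(bases.index(arr[site]) + 1 + rng.integers(0, 3)) % 4]
            rows[f"s{k}"] = "".join(arr)
        labels = {k: "Sp_x" for k in rows}
        msa = MultipleAlignment(rows, labels)
        tree = bootstrap_support(msa, BootstrapConfig(replicates=50, seed=17))
        supports = [n.support for n in tree.bipartitions().values()]
        assert np.median(supports) < 50.0


class TestMonophyly:
    def _tree(self, newick):
        return read_newick(newick)

    def test_clean_split_is_monophyletic(self):
        t = self._tree("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        labels = {"A1": "Sp_a", "A2": "Sp_a", "B1": "Sp_b", "B2": "Sp_b"}
        assert is_monophyletic(t, labels, "Sp_a")
        assert is_monophyletic(t, labels, "Sp_b")

    def test_interleaved_species_is_not(self):
        t = self._tree("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        labels = {"A1": "Sp_a", "A2": "Sp_a", "B1": "Sp_b", "B2": "Sp_b"}
        assert not is_monophyletic(t, labels, "Sp_a")

    def test_singleton_species_is_trivially_monophyletic(self):
        t = self._tree("((A1:1,A2:1):1,(B1:1,C1:1):1);")
        labels = {"A1": "Sp_a", "A2": "Sp_a", "B1": "Sp_b", "C1": "Sp_c"}
        assert is_monophyletic(t, labels, "Sp_b")

    def test_unknown_species_rejected(self):
        t = self._tree("(A:1,B:1,C:1);")
        with pytest.raises(ValidationError):
            is_monophyletic(t, {"A": "x", "B": "x", "C": "x"}, "Sp_missing")

    def test_all_simulated_species_monophyletic(self, default_dataset, default_msa):
        from its2barcode import distance_matrix

        tree = neighbor_joining(distance_matrix(default_msa))
        for sp in sorted(set(default_msa.labels.values())):
            assert is_monophyletic(tree, default_msa.labels, sp)


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        rng = np.random.default_rng(21)
        ids, D, _, _ = random_additive_case(rng, 6)
        tree = neighbor_joining(_dm(ids, D))
        for node in tree.bipartitions().values():
            node.support = 87.0
        back = read_newick(tree.to_newick())
        assert set(back.bipartitions()) == set(tree.bipartitions())
        for bip, node in back.bipartitions().items():
            assert node.length == pytest.approx(tree.bipartitions()[bip].length, abs=1e-6)
            assert node.support == 87.0

    def test_fixed_string_with_support_label(self):
        t = read_newick("(A:0.1,B:0.2,(C:0.3,D:0.4)95:0.05);")
        [(bip, node)] = list(t.bipartitions().items())
        assert bip == frozenset({"C", "D"})
        assert node.support == 95.0
        assert node.length == pytest.approx(0.05)

    def test_unbalanced_parenthesis_is_a_parse_error(self):
        with pytest.raises(ValidationError):
            read_newick("((A:1,B:2;")


class TestSpeciesSupports:
    def test_supports_reported_per_species(self, default_msa):
        tree = bootstrap_support(default_msa, BootstrapConfig(replicates=25, seed=4))
        sup = species_clade_supports(tree, default_msa.labels)
        assert set(sup) == set(default_msa.labels.values())
        for v in sup.values():
            assert v is None or 0.0 <= v <= 100.0
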