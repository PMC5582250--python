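import itertools

import dendropy
import numpy as np
import pytest

from mirhunt.io_formats import SequenceRecord, ValidationError
from mirhunt.phylo import (
    DistanceMatrix,
    identity_distance,
    neighbor_joining,
    pairwise_align,
)

from conftest import random_rna


def brute_force_global_score(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive global alignment score by recursion (tiny inputs only)."""
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -10**9
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best
    return rec(0, 0)


class TestPairwiseAlign:
    def test_identical_sequences(self, rng):
        s = random_rna(rng, 50)
        aln = pairwise_align(s, s)
        assert aln.identity == 1.0
        assert aln.score == 50

    def test_single_substitution_identity(self):
        aln = pairwise_align("ACGU", "ACGA")
        assert aln.identity == pytest.approx(0.75)

    def test_score_matches_exhaustive_oracle(self, rng):
        for _ in range(15):
            a = random_rna(rng, int(rng.integers(3, 9)))
            b = random_rna(rng, int(rng.integers(3, 9)))
            assert pairwise_align(a, b).score == brute_force_global_score(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_align("", "ACGU")


class TestIdentityDistance:
    def test_duplicates_have_zero_distance(self, rng):
        s = random_rna(rng, 60)
        recs = [SequenceRecord(f"r{i}", "", s) for i in range(3)]
        dm = identity_distance(recs)
        assert np.allclose(dm.d, 0.0)

    def test_engineered_identities(self, rng):
        # scattered single substitutions keep the optimal alignment gapless,
        # so distance equals the substitution fraction exactly
        base = random_rna(rng, 100)
        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[out[p]]
            return "".join(out)
        recs = [
            SequenceRecord("a", "", base),
            SequenceRecord("b", "", mutate(base, range(0, 100, 10))),   # 10 subs
            SequenceRecord("c", "", mutate(base, range(0, 100, 5))),    # 20 subs
        ]
        dm = identity_distance(recs)
        assert dm.d[0, 1] == pytest.approx(0.10, abs=1e-9)
        assert dm.d[0, 2] == pytest.approx(0.20, abs=1e-9)

    def test_symmetry_random_inputs(self, rng):
        recs = [SequenceRecord(f"r{i}", "", random_rna(rng, int(rng.integers(30, 80))))
                for i in range(6)]
        dm = identity_distance(recs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)


class TestNeighborJoining:
    def _tree_distances(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        return {
            tuple(sorted((a.label, b.label))): pdm.distance(a, b)
            for a, b in itertools.combinations(t.taxon_namespace, 2)
        }

    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.4, 0.6, 0.8
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]))
        tree = neighbor_joining(dm)
        lengths = {c.name: ln for c, ln in tree.root.children}
        assert lengths["a"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["b"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["c"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:0.1,b:0.2):0.15,c:0.3,d:0.4) -> additive distances
        D = {
            ("a", "b"): 0.3,
            ("a", "c"): 0.1 + 0.15 + 0.3,
            ("a", "d"): 0.1 + 0.15 + 0.4,
            ("b", "c"): 0.2 + 0.15 + 0.3,
            ("b", "d"): 0.2 + 0.15 + 0.4,
            ("c", "d"): 0.7,
        }
        taxa = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for (x, y), v in D.items():
            i, j = taxa.index(x), taxa.index(y)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(taxa, mat))
        got = tree.path_lengths()
        for pair, v in D.items():
            assert got[pair] == pytest.approx(v, abs=1e-9)
        # topology: a and b must be sisters
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        ab = dt.mrca(taxon_labels=["a", "b"])
        assert {leaf.taxon.label for leaf in ab.leaf_iter()} == {"a", "b"}

    def test_matches_independent_nj_on_random_additive_input(self, rng):
        # build additive matrices from random trees via dendropy, run our NJ,
        # and verify path-length additivity is reproduced exactly
        for _ in range(5):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            ns = dendropy.TaxonNamespace(taxa)
            import random as pyrandom
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=ns,
                num_extant_tips=n, rng=pyrandom.Random(int(rng.integers(1000))))
            for e in t.edges():
                if e.length is None or e.length <= 0:
                    e.length = 0.1
            pdm = t.phylogenetic_distance_matrix()
            mat = np.zeros((n, n))
            for a, b in itertools.combinations(range(n), 2):
                d = pdm.distance(ns[a], ns[b])
                mat[a, b] = mat[b, a] = d
            tree = neighbor_joining(DistanceMatrix(taxa, mat))
            got = tree.path_lengths()
            for a, b in itertools.combinations(range(n), 2):
                key = tuple(sorted((taxa[a], taxa[b])))
                assert got[key] == pytest.approx(mat[a, b], abs=1e-9)

    def test_taxon_permutation_gives_isomorphic_tree(self, rng):
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        base = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            base[i, j] = base[j, i] = float(rng.uniform(0.2, 1.5))
        tree1 = neighbor_joining(DistanceMatrix(taxa, base))
        perm = list(rng.permutation(n))
        taxa2 = [taxa[p] for p in perm]
        mat2 = base[np.ix_(perm, perm)]
        tree2 = neighbor_joining(DistanceMatrix(taxa2, mat2))
        ns = dendropy.TaxonNamespace(taxa)
        d1 = dendropy.Tree.get(data=tree1.newick(), schema="newick",
                               taxon_namespace=ns)
        d2 = dendropy.Tree.get(data=tree2.newick(), schema="newick",
                               taxon_namespace=ns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
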