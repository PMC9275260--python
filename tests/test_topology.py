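import numpy as np
import pytest

from divsel.errors import ParameterError, PruningError, SizeError
from divsel.io import NucAlignment
from divsel.likelihood import SiteLnLMatrix
from divsel.topology import (
    all_topologies,
    au_test,
    bonferroni,
    fitch_score,
    parsimony_candidates,
    prune_to_shared_taxa,
    rell_bootstrap,
    sh_test,
)
from divsel.trees import PhyloTree


def splits_data(tree: PhyloTree) -> NucAlignment:
    """Homoplasy-free binary characters: one site per non-trivial split."""
    tips = tree.tip_names
    cols = []
    for split in tree.splits():
        cols.append(["A" if t in split else "C" for t in tips])
    # pad with a couple of constant columns
    cols.append(["A"] * len(tips))
    arr = np.array(cols).T
    return NucAlignment.from_pairs(
        [(t, "".join(arr[i])) for i, t in enumerate(tips)]
    )


class TestFitch:
    def test_pattern_costs_on_alternative_topologies(self):
        aln = NucAlignment.from_pairs(
            [("t1", "AA"), ("t2", "AA"), ("t3", "CA"), ("t4", "CA")]
        )
        grouped = PhyloTree.from_newick("((t1,t2),(t3,t4));")
        split = PhyloTree.from_newick("((t1,t3),(t2,t4));")
        assert fitch_score(grouped, aln) == 1  # informative site + constant
        assert fitch_score(split, aln) == 2

    def test_constant_column_costs_nothing(self):
        aln = NucAlignment.from_pairs([("a", "G"), ("b", "G"), ("c", "G")])
        tree = PhyloTree.from_newick("((a,b),c);")
        assert fitch_score(tree, aln) == 0

    def test_gaps_treated_as_missing(self):
        aln = NucAlignment.from_pairs(
            [("a", "A"), ("b", "-"), ("c", "N"), ("d", "A")]
        )
        tree = PhyloTree.from_newick("((a,b),(c,d));")
        assert fitch_score(tree, aln) == 0

    def test_invariance_to_rerooting_and_taxon_order(self):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice(list("ACGT"), 30)) for _ in taxa]
        aln = NucAlignment.from_pairs(list(zip(taxa, rows)))
        t1 = PhyloTree.from_newick("(((t0,t1),(t2,t3)),(t4,t5));")
        t2 = PhyloTree.from_newick("(t4,(t5,((t0,t1),(t2,t3))));")  # rerooted
        assert t1.splits() == t2.splits()
        assert fitch_score(t1, aln) == fitch_score(t2, aln)
        shuffled = NucAlignment.from_pairs(
            [(t, r) for t, r in sorted(zip(taxa, rows), reverse=True)]
        )
        assert fitch_score(t1, shuffled) == fitch_score(t1, aln)

    def test_exhaustive_minimum_matches_nni_search(self):
        # 7 taxa: NNI search from random starts must reach the global optimum
        rng = np.random.default_rng(11)
        taxa = [f"t{i}" for i in range(7)]
        aln = NucAlignment.from_pairs(
            [(t, "".join(rng.choice(list("ACGT"), 40))) for t in taxa]
        )
        topologies = all_topologies(taxa)
        assert len(topologies) == 945
        exhaustive_best = min(fitch_score(t, aln) for t in topologies)
        _, search_best = parsimony_candidates(aln, n_starts=8, seed=0)
        assert search_best == exhaustive_best


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_unrooted_topology_counts(self, n, count):
        trees = all_topologies([f"t{i}" for i in range(n)])
        assert len(trees) == count
        assert len({t.splits() for t in trees}) == count


class TestParsimonyCandidates:
    def test_perfect_data_yields_generating_topology(self):
        tree = PhyloTree.from_newick("(((a,b),(c,d)),((e,f),g));")
        aln = splits_data(tree)
        candidates, score = parsimony_candidates(aln, n_starts=10, seed=1)
        assert len(candidates) == 1
        assert candidates[0].splits() == tree.splits()
        assert score == len(tree.splits())

    def test_four_taxa_explored_exhaustively(self):
        aln = NucAlignment.from_pairs(
            [("a", "AAC"), ("b", "AAG"), ("c", "CAC"), ("d", "CAG")]
        )
        candidates, score = parsimony_candidates(aln, n_starts=6, seed=0)
        exhaustive = [
            (t, fitch_score(t, aln)) for t in all_topologies(["a", "b", "c", "d"])
        ]
        best = min(s for _, s in exhaustive)
        assert score == best
        expected = {t.splits() for t, s in exhaustive if s == best}
        assert {c.splits() for c in candidates} == expected

    def test_same_seed_same_candidates(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(6)]
        aln = NucAlignment.from_pairs(
            [(t, "".join(rng.choice(list("ACGT"), 20))) for t in taxa]
        )
        c1, s1 = parsimony_candidates(aln, n_starts=5, seed=3)
        c2, s2 = parsimony_candidates(aln, n_starts=5, seed=3)
        assert s1 == s2
        assert {t.splits() for t in c1} == {t.splits() for t in c2}

    def test_too_few_taxa(self):
        aln = NucAlignment.from_pairs([("a", "A"), ("b", "C"), ("c", "G")])
        with pytest.raises(SizeError):
            parsimony_candidates(aln)


class TestPruneToSharedTaxa:
    def test_identity_up_to_unifurcation_suppression(self):
        tree = PhyloTree.from_newick("((a:1,b:2):1,(c:3,d:4):2);")
        pruned = prune_to_shared_taxa(tree, ["a", "b", "c", "d"])
        assert pruned.splits() == tree.splits()
        assert pruned.total_length() == pytest.approx(tree.total_length())

    def test_hand_computed_lengths_after_pruning(self):
        tree = PhyloTree.from_newick("((a:1,b:2):1,(c:3,d:4):2);")
        pruned = prune_to_shared_taxa(tree, ["a", "c", "d"])
        assert sorted(pruned.tip_names) == ["a", "c", "d"]
        # b's removal merges a's edge with the internal edge: a sits at 1+1=2
        tip_a = next(t for t in pruned.tips() if t.name == "a")
        assert tip_a.length == pytest.approx(2.0)

    def test_polytomy_preserved(self):
        tree = PhyloTree.from_newick("(a:1,b:1,c:1,d:1);")
        pruned = prune_to_shared_taxa(tree, ["a", "b", "c"])
        assert len(pruned.root.children) == 3

    def test_too_few_shared_taxa(self):
        tree = PhyloTree.from_newick("((a:1,b:2):1,c:3);")
        with pytest.raises(PruningError):
            prune_to_shared_taxa(tree, ["a", "b"])


@pytest.fixture
def separated_matrix():
    rng = np.random.default_rng(0)
    base = rng.normal(-5.0, 1.0, size=200)
    worse = base - 0.1  # tree 2 loses a little at every site
    return SiteLnLMatrix(np.vstack([base, worse]), ("best", "worse"))


class TestRell:
    def test_single_site_replicates_are_constant(self):
        m = SiteLnLMatrix(np.array([[-3.0]]), ("t1",))
        boot = rell_bootstrap(m, B=50, seed=0)
        assert np.allclose(boot, -3.0)

    def test_replicate_means_near_totals(self, separated_matrix):
        boot = rell_bootstrap(separated_matrix, B=10_000, seed=1)
        totals = separated_matrix.total_lnls()
        site_sd = separated_matrix.values.std(axis=1) * np.sqrt(
            separated_matrix.n_sites
        )
        for i in range(2):
            se = site_sd[i] / np.sqrt(10_000)
            assert abs(boot[i].mean() - totals[i]) < 3 * site_sd[i]

    def test_determinism(self, separated_matrix):
        b1 = rell_bootstrap(separated_matrix, B=100, seed=7)
        b2 = rell_bootstrap(separated_matrix, B=100, seed=7)
        assert np.array_equal(b1, b2)

    def test_b_validation(self, separated_matrix):
        with pytest.raises(ParameterError):
            rell_bootstrap(separated_matrix, B=0)


class TestShTest:
    def test_identical_vectors_give_p_one(self):
        rng = np.random.default_rng(3)
        v = rng.normal(-4, 1, 150)
        m = SiteLnLMatrix(np.vstack([v, v]), ("t1", "t2"))
        p = sh_test(m, B=2000, seed=0)
        assert np.all(p > 0.9)

    def test_dominated_tree_rejected(self):
        rng = np.random.default_rng(4)
        base = rng.normal(-5, 0.5, 100)
        m = SiteLnLMatrix(np.vstack([base, base - 10.0]), ("good", "bad"))
        p = sh_test(m, B=10_000, seed=0)
        assert p[1] < 1e-3

    def test_best_tree_p_at_least_half(self, separated_matrix):
        p = sh_test(separated_matrix, B=10_000, seed=2)
        best = separated_matrix.total_lnls().argmax()
        assert p[best] >= 0.5 - 0.02


class TestAuTest:
    def test_statistically_identical_trees_not_rejected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(-4, 1, 300)
        b = a + rng.normal(0, 0.05, 300)  # same expected fit
        m = SiteLnLMatrix(np.vstack([a, b]), ("t1", "t2"))
        p = au_test(m, B_per_scale=2000, seed=0)
        assert np.all(p > 0.05)
        assert np.all(np.abs(p - 0.5) < 0.45)

    def test_separated_trees_decided(self):
        rng = np.random.default_rng(6)
        base = rng.normal(-5, 0.5, 100)
        m = SiteLnLMatrix(np.vstack([base, base - 1.0]), ("good", "bad"))
        p = au_test(m, B_per_scale=2000, seed=1)
        assert p[0] > 0.95
        assert p[1] < 0.05

    def test_needs_at_least_two_trees(self):
        m = SiteLnLMatrix(np.zeros((1, 10)), ("t1",))
        with pytest.raises(SizeError):
            au_test(m)


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni(0.05, 1) == 0.05
        assert bonferroni(0.05, 6) == pytest.approx(0.05 / 6)

    def test_never_more_liberal(self):
        for m in range(1, 10):
            assert bonferroni(0.05, m) <= 0.05

    def test_m_validation(self):
        with pytest.raises(ParameterError):
            bonferroni(0.05, 0)
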