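import numpy as np
import pytest
from scipy import stats

from divsel.errors import ParameterError
from divsel.likelihood import ReversibleModel, encode_codons
from divsel.models import (
    CodonModelParams,
    SiteClassDistribution,
    equal_codon_frequencies,
    get_code,
    gy94_rate_matrix,
)
from divsel.simulate import (
    CladeSpec,
    SupportRegime,
    simulate_codon_alignment,
    simulate_labeled_tree,
    simulate_locus_table,
    simulate_support_annotations,
)
from divsel.treestats import support_summary
from divsel.trees import PhyloTree

SPEC = [
    CladeSpec("SO1", "O1", (("F1", 4), ("F2", 4))),
    CladeSpec("SO2", "O2", (("F3", 8),)),
]


def tip_depths(tree: PhyloTree) -> dict[str, float]:
    out = {}

    def walk(node, d):
        if node.is_leaf:
            out[node.name] = d
        for c in node.children:
            walk(c, d + (c.length or 0.0))

    walk(tree.root, 0.0)
    return out


class TestLabeledTree:
    def test_ultrametric_before_multipliers(self):
        tree, tax = simulate_labeled_tree(3, seed=0)
        depths = tip_depths(tree)
        assert np.ptp(list(depths.values())) < 1e-9

    def test_same_seed_reproduces_newick(self):
        t1, _ = simulate_labeled_tree(10, clade_spec=None, seed=7)
        t2, _ = simulate_labeled_tree(10, clade_spec=None, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_clade_multiplier_doubles_crown_paths(self):
        base, tax = simulate_labeled_tree(16, clade_spec=SPEC, seed=3)
        doubled, _ = simulate_labeled_tree(
            16, clade_spec=SPEC, rate_multipliers={"SO1": 2.0}, seed=3
        )
        so1_tips = [t for t in tax if tax[t].superorder == "SO1"]
        mrca_b = base.mrca(so1_tips)
        mrca_d = doubled.mrca(so1_tips)

        def path(tree, mrca, tip):
            node = next(n for n in tree.tips() if n.name == tip)
            total = 0.0
            while node is not mrca:
                total += node.length
                node = node.parent
            return total

        for tip in so1_tips:
            assert path(doubled, mrca_d, tip) == pytest.approx(
                2.0 * path(base, mrca_b, tip)
            )

    def test_taxonomy_covers_all_tips_and_is_monophyletic(self):
        tree, tax = simulate_labeled_tree(16, clade_spec=SPEC, seed=1)
        assert set(tree.tip_names) == set(iter(tax))
        so1 = [t for t in tax if tax[t].superorder == "SO1"]
        assert tree.descendant_tip_names(tree.mrca(so1)) == set(so1)

    def test_infeasible_clade_spec(self):
        with pytest.raises(ParameterError):
            simulate_labeled_tree(10, clade_spec=SPEC, seed=0)  # sums to 16

    def test_minimum_tips(self):
        with pytest.raises(ParameterError):
            simulate_labeled_tree(2, seed=0)


class TestCodonSimulation:
    def test_zero_time_limit_identical_rows(self, codon_params):
        tree, _ = simulate_labeled_tree(4, seed=0, tree_height=1e-9)
        classes = SiteClassDistribution.m0(1.0)
        aln, _ = simulate_codon_alignment(tree, classes, codon_params, 50, seed=1)
        assert len(set(aln.rows)) == 1

    def test_m8_with_p1_zero_has_no_positive_class_sites(self, codon_params):
        tree, _ = simulate_labeled_tree(4, seed=0)
        classes = SiteClassDistribution.m8(0.5, 1.5, p0=1.0, omega_s=5.0, K=10)
        _, truth = simulate_codon_alignment(tree, classes, codon_params, 200, seed=2)
        assert truth.site_classes.max() < 10

    def test_determinism(self, codon_params):
        tree, _ = simulate_labeled_tree(6, seed=0)
        classes = SiteClassDistribution.m7(0.5, 1.5)
        a1, t1 = simulate_codon_alignment(tree, classes, codon_params, 100, seed=9)
        a2, t2 = simulate_codon_alignment(tree, classes, codon_params, 100, seed=9)
        assert a1 == a2
        assert np.array_equal(t1.site_classes, t2.site_classes)

    def test_long_branch_stationarity(self, codon_params):
        # single long edge: tip states should reach the stationary law
        root = PhyloTree.from_newick("(a:60.0,b:60.0);")
        classes = SiteClassDistribution.m0(1.0)
        aln, _ = simulate_codon_alignment(root, classes, codon_params, 20_000,
                                          seed=5)
        states = encode_codons(aln)[0]
        counts = np.bincount(states, minlength=61)
        expected = codon_params.pi * 20_000
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=60)
        assert p > 0.01

    def test_m0_two_tip_substitution_process_goodness_of_fit(self, codon_params):
        # joint (start, end) codon counts on a 2-tip tree against pi_i P_ij(t)
        t_total = 0.6
        tree = PhyloTree.from_newick("(a:0.3,b:0.3);")
        classes = SiteClassDistribution.m0(0.7)
        n = 10_000
        aln, _ = simulate_codon_alignment(tree, classes, codon_params, n, seed=8)
        states = encode_codons(aln)
        model = ReversibleModel(gy94_rate_matrix(codon_params, 0.7),
                                codon_params.pi)
        P = model.transition(t_total)
        probs = codon_params.pi[:, None] * P  # joint law of (tip a, tip b)
        observed = np.zeros((61, 61))
        np.add.at(observed, (states[0], states[1]), 1.0)
        expected = probs.ravel() * n
        obs = observed.ravel()
        big = expected >= 5.0
        obs_b = np.append(obs[big], obs[~big].sum())
        exp_b = np.append(expected[big], expected[~big].sum())
        chi2 = ((obs_b - exp_b) ** 2 / exp_b).sum()
        p = stats.chi2.sf(chi2, df=len(obs_b) - 1)
        assert p > 0.01


class TestSupportAnnotations:
    def test_resolved_point_mass_gives_full_support(self):
        tree, tax = simulate_labeled_tree(16, clade_spec=SPEC, seed=2)
        annotated = simulate_support_annotations(
            tree, SupportRegime(point_mass=1.0), seed=0, taxonomy=tax
        )
        assert support_summary(annotated).supported_pct == 100.0

    def test_unresolved_point_mass_gives_zero_support(self):
        tree, tax = simulate_labeled_tree(16, clade_spec=SPEC, seed=2)
        annotated = simulate_support_annotations(
            tree, SupportRegime(point_mass=0.5), seed=0, taxonomy=tax
        )
        assert support_summary(annotated, threshold=0.95).supported_pct == 0.0

    def test_resolved_beta_mean_support(self):
        tree, _ = simulate_labeled_tree(100, clade_spec=None, seed=4)
        annotated = simulate_support_annotations(
            tree, SupportRegime(a=50.0, b=1.0), seed=1
        )
        sup = [n.support for n in annotated.internal_nodes(exclude_root=True)]
        # Beta(50,1) mean is 50/51 ~ 0.980; check within sampling error
        assert np.mean(sup) > 0.95

    def test_deep_penalty_requires_taxonomy(self):
        tree, _ = simulate_labeled_tree(8, seed=0)
        with pytest.raises(ParameterError):
            simulate_support_annotations(
                tree, SupportRegime(a=10, b=1, deep_a=1, deep_b=1), seed=0
            )


class TestLocusScenarios:
    def test_deleted_scenario_has_30kb_gap(self):
        from divsel.synteny import flank_gap

        table, arch = simulate_locus_table("zan_deleted", seed=0)
        gap, inside = flank_gap(table)
        assert gap == 30_000
        assert inside == ()
        assert arch is None
        assert len(table) == 11

    def test_intact_candidate_exceeds_100kb(self):
        table, arch = simulate_locus_table("zan_intact", seed=0)
        assert table["Zan"].length > 100_000
        assert len(table) == 12

    def test_intact_table_round_trips_with_order(self, tmp_path):
        from divsel.io import read_locus_table, write_locus_table

        table, _ = simulate_locus_table("zan_intact", seed=0)
        p = tmp_path / "locus.tsv"
        write_locus_table(table, p)
        back = read_locus_table(p)
        assert len(back) == 12
        assert back.genes()[0] == "AchE" and back.genes()[-1] == "Tfr2"
        assert back.genes() == table.genes()

    def test_shuffled_order_depends_on_seed(self):
        t1, _ = simulate_locus_table("shuffled_order", seed=1)
        t2, _ = simulate_locus_table("shuffled_order", seed=2)
        assert t1.genes() != t2.genes()
        assert sorted(t1.genes()) == sorted(t2.genes())

    def test_pure_function_of_seed(self):
        t1, _ = simulate_locus_table("shuffled_order", seed=3)
        t2, _ = simulate_locus_table("shuffled_order", seed=3)
        assert [(r.gene, r.start, r.strand) for r in t1] == [
            (r.gene, r.start, r.strand) for r in t2
        ]

    def test_unknown_scenario(self):
        with pytest.raises(ParameterError):
            simulate_locus_table("nope", seed=0)
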