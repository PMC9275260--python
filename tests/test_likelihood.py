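import numpy as np
import pytest

from divsel.errors import MappingError, ValidationError
from divsel.io import CodonAlignment, NucAlignment
from divsel.likelihood import (
    ReversibleModel,
    SiteLnLMatrix,
    codon_omega_loglik,
    encode_codons,
    encode_nucleotides,
    fit_gtr_tree,
    gtr_gamma_site_loglik,
    mixture_loglik,
    pruning_loglik,
    site_class_loglik,
)
from divsel.models import (
    CodonModelParams,
    GtrGammaParams,
    SiteClassDistribution,
    get_code,
    gtr_rate_matrix,
    gy94_rate_matrix,
)
from divsel.trees import PhyloTree

GTR = GtrGammaParams(
    np.array([1.0, 2.0, 1.5, 0.8, 2.5, 1.0]),
    np.array([0.3, 0.2, 0.2, 0.3]),
    alpha=1.0,
    n_categories=1,
)


def brute_force_four_tip(tree_lengths, P_of_t, pi, states):
    """Exhaustive sum over interior-state assignments of the rooted tree
    ((a,b)x,(c,d)y)root. ``states`` = (sa, sb, sc, sd); independent of the
    pruning implementation."""
    tx, ta, tb, ty, tc, td = tree_lengths
    Px, Pa, Pb, Py, Pc, Pd = (P_of_t(t) for t in (tx, ta, tb, ty, tc, td))
    sa, sb, sc, sd = states
    n = len(pi)
    total = 0.0
    for r in range(n):
        for x in range(n):
            t1 = pi[r] * Px[r, x] * Pa[x, sa] * Pb[x, sb]
            if t1 == 0.0:
                continue
            for y in range(n):
                total += t1 * Py[r, y] * Pc[y, sc] * Pd[y, sd]
    return total


class TestPruningOracle:
    def test_zero_time_limit_gives_stationary_frequency(self):
        tree = PhyloTree.from_newick("(a:0,b:0);")
        aln = NucAlignment.from_pairs([("a", "C"), ("b", "C")])
        model = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        ll = pruning_loglik(tree, aln, model)
        assert ll[0] == pytest.approx(np.log(GTR.freqs[1]), abs=1e-12)

    def test_all_missing_column_has_loglik_zero(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2);")
        aln = NucAlignment.from_pairs([("a", "N-"), ("b", "NA")])
        model = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        ll = pruning_loglik(tree, aln, model)
        assert ll[0] == pytest.approx(0.0, abs=1e-12)

    def test_nucleotide_matches_exhaustive_enumeration(
        self, four_tip_tree, small_nuc_aln
    ):
        model = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        ll = pruning_loglik(four_tip_tree, small_nuc_aln, model)
        states = encode_nucleotides(small_nuc_aln)
        lengths = (0.15, 0.1, 0.2, 0.1, 0.3, 0.05)  # x, a, b, y, c, d
        for h in range(small_nuc_aln.n_sites):
            brute = brute_force_four_tip(
                lengths, model.transition, GTR.freqs, states[:, h]
            )
            assert ll[h] == pytest.approx(np.log(brute), abs=1e-10)

    def test_codon_matches_exhaustive_enumeration(
        self, four_tip_tree, small_codon_aln, codon_params
    ):
        model = ReversibleModel(
            gy94_rate_matrix(codon_params, 0.5), codon_params.pi
        )
        ll = pruning_loglik(four_tip_tree, small_codon_aln, model)
        states = encode_codons(small_codon_aln)
        lengths = (0.15, 0.1, 0.2, 0.1, 0.3, 0.05)
        h = 1  # one codon column is enough: 61^3 interior assignments
        brute = brute_force_four_tip(
            lengths, model.transition, codon_params.pi, states[:, h]
        )
        assert ll[h] == pytest.approx(np.log(brute), abs=1e-10)

    def test_missing_tip_raises_mapping_error(self, four_tip_tree):
        aln = NucAlignment.from_pairs([("a", "A"), ("b", "C"), ("c", "G")])
        model = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        with pytest.raises(MappingError):
            pruning_loglik(four_tip_tree, aln, model)


class TestReversibilityInvariants:
    def test_pulley_principle(self, small_nuc_aln):
        model = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        t1 = PhyloTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.05):0.20);")
        t2 = PhyloTree.from_newick("((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.10);")
        l1 = pruning_loglik(t1, small_nuc_aln, model).sum()
        l2 = pruning_loglik(t2, small_nuc_aln, model).sum()
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_rerooting_invariance(self, small_nuc_aln):
        model = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        rooted_mid = PhyloTree.from_newick(
            "((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.1);"
        )
        rooted_on_a = PhyloTree.from_newick(
            "(a:0.04,(b:0.2,(c:0.3,d:0.05):0.25):0.06);"
        )
        l1 = pruning_loglik(rooted_mid, small_nuc_aln, model).sum()
        l2 = pruning_loglik(rooted_on_a, small_nuc_aln, model).sum()
        assert l1 == pytest.approx(l2, abs=1e-9)


class TestSiteClassLoglik:
    def test_single_class_equals_m0(self, four_tip_tree, small_codon_aln,
                                    codon_params):
        classes = SiteClassDistribution.m0(0.4)
        per_class = site_class_loglik(
            four_tip_tree, small_codon_aln, codon_params, classes
        )
        model = ReversibleModel(gy94_rate_matrix(codon_params, 0.4),
                                codon_params.pi)
        direct = pruning_loglik(four_tip_tree, small_codon_aln, model)
        mix = mixture_loglik(per_class, classes.weights)
        assert np.allclose(per_class[:, 0], direct, atol=1e-12)
        assert np.allclose(mix, direct, atol=1e-12)

    def test_identical_classes_mixture_invariance(
        self, four_tip_tree, small_codon_aln, codon_params
    ):
        two = SiteClassDistribution(
            np.array([0.4, 0.4]), np.array([0.3, 0.7])
        )
        one = SiteClassDistribution.m0(0.4)
        m2 = mixture_loglik(
            site_class_loglik(four_tip_tree, small_codon_aln, codon_params, two),
            two.weights,
        )
        m1 = mixture_loglik(
            site_class_loglik(four_tip_tree, small_codon_aln, codon_params, one),
            one.weights,
        )
        assert np.allclose(m1, m2, atol=1e-10)

    def test_two_class_mixture_matches_brute_force(
        self, four_tip_tree, small_codon_aln, codon_params
    ):
        omegas, weights = np.array([0.2, 3.0]), np.array([0.6, 0.4])
        classes = SiteClassDistribution(omegas, weights)
        mix = mixture_loglik(
            site_class_loglik(four_tip_tree, small_codon_aln, codon_params,
                              classes),
            weights,
        )
        states = encode_codons(small_codon_aln)
        lengths = (0.15, 0.1, 0.2, 0.1, 0.3, 0.05)
        h = 0
        brute = 0.0
        for om, w in zip(omegas, weights):
            model = ReversibleModel(gy94_rate_matrix(codon_params, om),
                                    codon_params.pi)
            brute += w * brute_force_four_tip(
                lengths, model.transition, codon_params.pi, states[:, h]
            )
        assert mix[h] == pytest.approx(np.log(brute), abs=1e-10)


class TestGtrGamma:
    def test_huge_alpha_matches_single_rate(self, four_tip_tree, small_nuc_aln):
        gamma = GtrGammaParams(GTR.exchangeabilities, GTR.freqs,
                               alpha=1e6, n_categories=4)
        single = ReversibleModel(gtr_rate_matrix(GTR), GTR.freqs)
        l_gamma = gtr_gamma_site_loglik(four_tip_tree, small_nuc_aln, gamma)
        l_single = pruning_loglik(four_tip_tree, small_nuc_aln, single)
        assert np.allclose(l_gamma, l_single, atol=1e-6)

    def test_invariant_class_dominates_constant_column(self, four_tip_tree):
        aln = NucAlignment.from_pairs(
            [("a", "G"), ("b", "G"), ("c", "G"), ("d", "G")]
        )
        p_inv = 1.0 - 1e-6
        params = GtrGammaParams(GTR.exchangeabilities, GTR.freqs,
                                alpha=1.0, p_inv=p_inv)
        ll = gtr_gamma_site_loglik(four_tip_tree, aln, params)
        # two-term hand computation: p_inv * pi_G plus a tiny variable-class term
        assert ll[0] == pytest.approx(np.log(p_inv * GTR.freqs[2]), abs=1e-4)

    def test_fit_reports_lnl_consistent_with_row_sums(
        self, four_tip_tree, small_nuc_aln
    ):
        fitted, params, lnl = fit_gtr_tree(four_tip_tree, small_nuc_aln,
                                           fit_exchangeabilities=False)
        recomputed = gtr_gamma_site_loglik(fitted, small_nuc_aln, params).sum()
        assert recomputed == pytest.approx(lnl, abs=1e-8)


class TestSiteLnLMatrix:
    def test_row_sums_and_labels(self):
        vals = np.array([[1.0, -2.0], [0.5, -1.0]])
        m = SiteLnLMatrix(vals, ("t1", "t2"))
        assert np.allclose(m.total_lnls(), vals.sum(axis=1))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            SiteLnLMatrix(np.array([[np.inf, 0.0]]), ("t1",))

    def test_label_count_enforced(self):
        with pytest.raises(ValidationError):
            SiteLnLMatrix(np.zeros((2, 3)), ("t1",))


def test_batched_omega_loglik_matches_sequential(
    four_tip_tree, small_codon_aln, codon_params
):
    omegas = np.array([0.1, 0.5, 1.0, 3.0, 8.0])
    batched = codon_omega_loglik(four_tip_tree, small_codon_aln, codon_params,
                                 omegas, chunk=2)
    for k, om in enumerate(omegas):
        model = ReversibleModel(gy94_rate_matrix(codon_params, om),
                                codon_params.pi)
        direct = pruning_loglik(four_tip_tree, small_codon_aln, model)
        assert np.allclose(batched[:, k], direct, atol=1e-10)
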