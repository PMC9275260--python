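import numpy as np
import pytest

from divsel.errors import MonophylyError, SizeError, ValidationError
from divsel.io import TaxonomyMap, TaxonRanks
from divsel.simulate import (
    CladeSpec,
    SupportRegime,
    simulate_labeled_tree,
    simulate_support_annotations,
)
from divsel.studies import rate_recovery_experiment
from divsel.treestats import (
    RateRecord,
    SupportSummary,
    games_howell,
    normalize_rates,
    rank_rate_breakpoint,
    rate_comparison,
    split_deep_terminal,
    support_summary,
    tip_divergence_rates,
    welch_anova,
)
from divsel.trees import PhyloTree

# count -> percentage pairs as printed in the study's figure captions/results:
# (n_unsupported, n_total, printed unsupported %, half-unit of printed digit)
PRINTED_PAIRS = [
    (5, 112, 4.5, 0.05),    # focal gene: 107/112 supported = 95.5%
    (10, 109, 9.2, 0.05),
    (13, 131, 9.9, 0.05),
    (27, 115, 23.0, 0.5),
    (47, 118, 39.8, 0.05),
    (29, 66, 44.0, 0.5),
]


class TestSupportSummary:
    @pytest.mark.parametrize("n_unsup,n_tot,printed,tol", PRINTED_PAIRS)
    def test_count_pairs_reproduce_printed_percentages(
        self, n_unsup, n_tot, printed, tol
    ):
        s = SupportSummary.from_counts(n_tot - n_unsup, n_tot)
        assert abs(s.unsupported_pct - printed) <= tol + 1e-9
        assert s.supported_pct + s.unsupported_pct == pytest.approx(100.0)

    def test_focal_gene_support_percentage(self):
        s = SupportSummary.from_counts(107, 112)
        assert round(s.supported_pct, 1) == 95.5

    def test_threshold_is_inclusive(self):
        tree = PhyloTree.from_newick("((a:1,b:1)0.95:1,(c:1,d:1)0.95:1);")
        s = support_summary(tree, threshold=0.95)
        assert s.supported_pct == 100.0

    def test_denominator_conventions(self):
        tree = PhyloTree.from_newick("((a:1,b:1)0.99:1,(c:1,d:1):1);")
        annotated = support_summary(tree, denominator="annotated")
        assert annotated.n_internal == 1 and annotated.n_supported == 1
        internal = support_summary(tree, denominator="internal")
        assert internal.n_internal == 3  # root and both cherries
        minus_root = support_summary(tree, denominator="internal_minus_root")
        assert minus_root.n_internal == 2

    def test_empty_convention_raises(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(SizeError):
            support_summary(tree, denominator="annotated")

    def test_counts_validation(self):
        with pytest.raises(ValidationError):
            SupportSummary(5, 6)


class TestSplitDeepTerminal:
    def _taxonomy(self, fam_of):
        return TaxonomyMap(
            {t: TaxonRanks("SO", "O", f, t) for t, f in fam_of.items()}
        )

    def test_cherries_are_terminal_rest_deep(self):
        tree = PhyloTree.from_newick(
            "(((a:1,b:1)0.99:1,(c:1,d:1)0.5:1)0.4:1,(e:1,f:1)0.98:1);"
        )
        tax = self._taxonomy(
            {"a": "F1", "b": "F1", "c": "F2", "d": "F2", "e": "F3", "f": "F3"}
        )
        deep, term = split_deep_terminal(tree, tax, level="family")
        assert term.n_internal == 3 and term.n_supported == 2
        assert deep.n_internal == 1 and deep.n_supported == 0

    def test_single_family_has_no_deep_nodes(self):
        tree = PhyloTree.from_newick("((a:1,b:1)0.9:1,c:1);")
        tax = self._taxonomy({"a": "F", "b": "F", "c": "F"})
        deep, term = split_deep_terminal(tree, tax)
        assert deep is None
        assert term is not None

    def test_simulated_regime_separates_deep_and_terminal(self):
        spec = [
            CladeSpec("SO1", "O1", (("F1", 4), ("F2", 4))),
            CladeSpec("SO2", "O2", (("F3", 4), ("F4", 4))),
        ]
        tree, tax = simulate_labeled_tree(16, clade_spec=spec, seed=9)
        annotated = simulate_support_annotations(
            tree,
            SupportRegime(point_mass=1.0, deep_a=1.0, deep_b=1.0,
                          deep_point_mass=0.5),
            seed=0, taxonomy=tax,
        )
        deep, term = split_deep_terminal(tree=annotated, taxonomy=tax)
        assert term.supported_pct == 100.0
        assert deep.supported_pct == 0.0


class TestDivergenceRates:
    def _tree_and_tax(self):
        tree = PhyloTree.from_newick("((A:1,B:2):1,C:5);")
        tax = TaxonomyMap(
            {
                "A": TaxonRanks("SOab", "O1", "F1", "A"),
                "B": TaxonRanks("SOab", "O1", "F1", "B"),
                "C": TaxonRanks("SOc", "O2", "F2", "C"),
            }
        )
        return tree, tax

    def test_crown_rates_by_hand(self):
        tree, tax = self._tree_and_tax()
        recs = {r.tip: r for r in tip_divergence_rates(tree, tax, "crown")}
        assert recs["A"].raw_rate == 1.0
        assert recs["B"].raw_rate == 2.0
        assert recs["C"].raw_rate == 0.0 and not recs["C"].valid

    def test_stem_rates_by_hand(self):
        tree, tax = self._tree_and_tax()
        recs = {r.tip: r for r in tip_divergence_rates(tree, tax, "stem")}
        assert recs["A"].raw_rate == 2.0
        assert recs["B"].raw_rate == 3.0
        assert recs["C"].raw_rate == 5.0

    def test_additivity_in_edge_lengths(self):
        tree, tax = self._tree_and_tax()
        before = {r.tip: r.raw_rate for r in tip_divergence_rates(tree, tax, "crown")}
        tip_a = next(t for t in tree.tips() if t.name == "A")
        tip_a.length += 0.25
        after = {r.tip: r.raw_rate for r in tip_divergence_rates(tree, tax, "crown")}
        assert after["A"] == pytest.approx(before["A"] + 0.25)
        assert after["B"] == before["B"]

    def test_non_monophyletic_superorder_rejected(self):
        tree = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        tax = TaxonomyMap(
            {
                "A": TaxonRanks("SO1", "", "", ""),
                "B": TaxonRanks("SO1", "", "", ""),
                "C": TaxonRanks("SO2", "", "", ""),
                "D": TaxonRanks("SO2", "", "", ""),
            }
        )
        with pytest.raises(MonophylyError):
            tip_divergence_rates(tree, tax)


class TestNormalizeRates:
    def _records(self, raws, gene="g"):
        return [
            RateRecord(f"t{i}", "SO", "O", raw, gene=gene)
            for i, raw in enumerate(raws)
        ]

    def test_normalization_and_dynamic_range(self):
        normalized, ranges = normalize_rates(self._records([1.0, 2.0, 3.6]))
        assert [r.normalized_rate for r in normalized] == pytest.approx(
            [1.0, 2.0, 3.6]
        )
        assert ranges["g"] == pytest.approx(3.6)

    def test_equal_rates(self):
        normalized, ranges = normalize_rates(self._records([2.0, 2.0, 2.0]))
        assert all(r.normalized_rate == 1.0 for r in normalized)
        assert ranges["g"] == 1.0

    def test_scale_invariance(self):
        n1, _ = normalize_rates(self._records([1.0, 2.0, 5.0]))
        n2, _ = normalize_rates(self._records([7.0, 14.0, 35.0]))
        assert [r.normalized_rate for r in n1] == pytest.approx(
            [r.normalized_rate for r in n2]
        )

    def test_zero_minimum_rejected(self):
        with pytest.raises(ValidationError):
            normalize_rates(self._records([0.0, 1.0, 2.0]))


class TestRankRateBreakpoint:
    def _records(self, values):
        return [
            RateRecord(f"t{i}", "SO", "O", v, normalized_rate=v)
            for i, v in enumerate(values)
        ]

    def test_exact_two_line_input(self):
        x = np.arange(1, 21, dtype=float)
        y = np.where(x <= 10, 1.0 + 0.1 * x, -3.0 + 0.5 * x)
        fit = rank_rate_breakpoint(self._records(list(y)))
        assert fit.breakpoint == 10

    def test_single_line_declares_no_inflection(self):
        y = 1.0 + 0.05 * np.arange(1, 25)
        fit = rank_rate_breakpoint(self._records(list(y)))
        assert fit.breakpoint is None

    def test_size_validation(self):
        with pytest.raises(SizeError):
            rank_rate_breakpoint(self._records([1.0, 2.0, 3.0]))

    def test_simulated_91_21_regime(self):
        result = rate_recovery_experiment(seed=5)
        assert abs(result["breakpoint"] - 91) <= 2
        assert abs(result["clade_ratio"] - 3.0) / 3.0 <= 0.10


class TestRateComparison:
    def test_identical_groups_not_distinguished(self):
        g = [1.1, 2.0, 2.9, 4.2, 5.0]
        res = rate_comparison({"a": g, "b": g})
        assert res.omnibus_p > 0.9
        assert not res.posthoc["significant"].any()

    def test_games_howell_two_groups_matches_welch_t(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1.5, 3, 15)
        gh = games_howell({"a": a, "b": b})
        t_p = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert gh["p_value"].iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_games_howell_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        groups = {g: rng.normal(mu, sd, 14)
                  for g, mu, sd in [("a", 0, 1), ("b", 1, 2), ("c", 2.5, 0.5)]}
        ours = games_howell(groups).set_index(["group_a", "group_b"])
        df = pd.DataFrame(
            {"val": np.concatenate(list(groups.values())),
             "grp": np.repeat(list(groups), [14, 14, 14])}
        )
        ref = pg.pairwise_gameshowell(dv="val", between="grp", data=df)
        for _, row in ref.iterrows():
            key = (row["A"], row["B"])
            key = key if key in ours.index else (row["B"], row["A"])
            assert ours.loc[key, "p_value"] == pytest.approx(row["pval"], abs=1e-6)

    def test_welch_anova_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        groups = [rng.normal(m, s, 12) for m, s in [(0, 1), (0.5, 2), (1, 0.7)]]
        f, df2, p = welch_anova(groups)
        df = pd.DataFrame(
            {"val": np.concatenate(groups),
             "grp": np.repeat(["a", "b", "c"], 12)}
        )
        ref = pg.welch_anova(dv="val", between="grp", data=df)
        assert f == pytest.approx(ref["F"].iloc[0], rel=1e-6)
        assert p == pytest.approx(ref["p_unc"].iloc[0], rel=1e-6)

    def test_power_with_separated_groups(self):
        rejections = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            groups = {
                "a": np.abs(rng.normal(1.0, 0.4, 15)) + 0.1,
                "b": np.abs(rng.normal(3.0, 1.2, 15)) + 0.1,
            }
            res = rate_comparison(groups)
            rejections += res.omnibus_p < 0.05
        assert rejections >= 95

    def test_small_group_rejected(self):
        with pytest.raises(SizeError):
            rate_comparison({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})

    def test_decision_path_reported(self):
        rng = np.random.default_rng(11)
        groups = {"a": np.exp(rng.normal(0, 1, 20)),
                  "b": np.exp(rng.normal(2, 1, 20))}
        res = rate_comparison(groups)
        assert "Kruskal" in res.omnibus_test or "Welch" in res.omnibus_test \
            or "ANOVA" in res.omnibus_test
        assert res.path
        assert res.posthoc_test in ("Games-Howell", "RyanQ")
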