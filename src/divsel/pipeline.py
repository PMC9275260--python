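"""Orchestration: per-gene analysis and cross-gene comparison reports.

A gene analysis ties together the three per-gene stages — site-model
selection (M0/M7/M8 fits, M7-vs-M8 LRT, empirical-Bayes sites, ω×f), node
support accounting, and divergence rates. The comparison report assembles
the cross-gene support-vs-intensity table, tests each gene's candidate
topologies against the pruned species supertree (SH/AU, Bonferroni-adjusted
within each gene's candidate set), and runs the divergence-rate comparison.

Every run can emit TSV outputs plus the resolved configuration, and logs
each stage with the SHA-256 of its file inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .errors import PruningError, SizeError, ValidationError
from .likelihood import SiteLnLMatrix, fit_gtr_tree, gtr_gamma_site_loglik
from .models import GtrGammaParams
from .selection import (
    FitOptions,
    SiteModelAnalysis,
    empirical_bayes_sites,
    likelihood_ratio_test,
    selection_intensity,
    support_vs_selection_table,
)
from .topology import (
    bonferroni,
    parsimony_candidates,
    prune_to_shared_taxa,
    topology_test_suite,
)
from .treestats import (
    normalize_rates,
    rate_comparison,
    split_deep_terminal,
    support_summary,
    tip_divergence_rates,
)
from .trees import Node, PhyloTree

log = logging.getLogger("divsel")

__all__ = ["RunConfig", "GeneReport", "ComparisonReport",
           "analyze_gene", "run_gene_analysis", "run_comparison_report",
           "resolve_polytomies_ml"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; fully serializable."""

    gene: str = "gene"
    alignment_path: Optional[str] = None
    tree_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    out_dir: Optional[str] = None
    models: tuple[str, ...] = ("M0", "M7", "M8")
    pi_mode: str = "F3x4"
    K: int = 10
    n_restarts: int = 5
    support_threshold: float = 0.95
    support_denominator: str = "annotated"
    alpha: float = 0.05
    eb_method: str = "NEB"
    eb_threshold: float = 0.95
    anchor: str = "crown"
    rell_B: int = 10_000
    parsimony_starts: int = 8
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class GeneReport:
    gene: str
    fits: dict
    lrt: object
    detection: object
    intensity: object
    support: object
    support_deep: object
    support_terminal: object
    rate_records: list
    dynamic_range: Optional[float]
    config: RunConfig
    input_hashes: dict = field(default_factory=dict)

    def selection_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            rows.append(
                {
                    "gene": self.gene,
                    "model": name,
                    "lnL": fit.lnl,
                    "kappa": fit.kappa,
                    "tree_scale": fit.tree_scale,
                    "params": ";".join(f"{k}={v:.6g}" for k, v in fit.params.items()),
                    "n_free_params": fit.n_free_params,
                    "converged": fit.converged,
                }
            )
        df = pd.DataFrame(rows)
        if self.lrt is not None:
            df["lrt_stat_m7_m8"] = self.lrt.statistic
            df["lrt_df"] = self.lrt.df
            df["lrt_p"] = self.lrt.p_value
        return df

    def sites_frame(self) -> pd.DataFrame:
        if self.detection is None:
            return pd.DataFrame(columns=["gene", "site", "posterior"])
        return pd.DataFrame(
            {
                "gene": self.gene,
                "site": list(self.detection.selected_sites),
                "posterior": [
                    self.detection.posterior[i] for i in self.detection.selected_sites
                ],
            }
        )

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene or self.gene,
                    "tip": r.tip,
                    "superorder": r.superorder,
                    "order": r.order,
                    "raw_rate": r.raw_rate,
                    "normalized_rate": r.normalized_rate,
                }
                for r in self.rate_records
            ]
        )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.selection_frame().to_csv(out / f"{self.gene}.selection.tsv",
                                      sep="\t", index=False)
        self.sites_frame().to_csv(out / f"{self.gene}.sites.tsv",
                                  sep="\t", index=False)
        self.rates_frame().to_csv(out / f"{self.gene}.rates.tsv",
                                  sep="\t", index=False)
        self.config.to_yaml(out / f"{self.gene}.config.yaml")


def analyze_gene(
    gene: str,
    codon_aln: dio.CodonAlignment,
    tree: PhyloTree,
    taxonomy: Optional[dio.TaxonomyMap] = None,
    config: RunConfig = RunConfig(),
) -> GeneReport:
    """In-memory per-gene analysis (file-path orchestration wraps this)."""
    opts = FitOptions(K=config.K, pi_mode=config.pi_mode,
                      n_restarts=config.n_restarts)
    analysis = SiteModelAnalysis(codon_aln, tree, opts)
    fits = {}
    for model in config.models:
        log.info("[%s] fitting %s", gene, model)
        fits[model] = analysis.fit(model)
        log.info("[%s] %s lnL=%.4f params=%s", gene, model,
                 fits[model].lnl, fits[model].params)

    lrt = detection = intensity = None
    if "M7" in fits and "M8" in fits:
        lrt = likelihood_ratio_test(fits["M7"], fits["M8"], df=2)
        log.info("[%s] LRT M7 vs M8: stat=%.4f p=%.4g", gene,
                 lrt.statistic, lrt.p_value)
        detection = empirical_bayes_sites(
            fits["M8"], codon_aln, tree,
            threshold=config.eb_threshold, method=config.eb_method, options=opts,
        )
        omega_s = fits["M8"].classes.omega_s or 0.0
        # purifying/neutral path: no significant positive selection -> ω×f = 0
        if lrt.p_value < config.alpha and detection.selected_sites:
            intensity = selection_intensity(omega_s, detection.f_percent)
        else:
            intensity = selection_intensity(0.0, 0.0)
        log.info("[%s] intensity omega_s=%.3f f=%.2f%% -> %.2f", gene,
                 intensity.omega_s, intensity.f_percent, intensity.intensity)

    support = support_deep = support_terminal = None
    try:
        support = support_summary(tree, config.support_threshold,
                                  config.support_denominator)
    except SizeError:
        log.warning("[%s] no support annotations on tree", gene)
    rate_records, dyn_range = [], None
    if taxonomy is not None:
        if support is not None:
            support_deep, support_terminal = split_deep_terminal(
                tree, taxonomy, threshold=config.support_threshold,
                denominator=config.support_denominator,
            )
        records = tip_divergence_rates(tree, taxonomy, anchor=config.anchor,
                                       gene=gene)
        rate_records, ranges = normalize_rates(records)
        dyn_range = ranges.get(gene)
    return GeneReport(
        gene=gene, fits=fits, lrt=lrt, detection=detection,
        intensity=intensity, support=support, support_deep=support_deep,
        support_terminal=support_terminal, rate_records=rate_records,
        dynamic_range=dyn_range, config=config,
    )


def run_gene_analysis(config: RunConfig) -> GeneReport:
    """Load the configured inputs, run the per-gene analysis, write outputs."""
    if config.alignment_path is None or config.tree_path is None:
        raise ValueError("config must provide alignment_path and tree_path")
    hashes = {"alignment": _sha256(config.alignment_path),
              "tree": _sha256(config.tree_path)}
    aln = dio.read_alignment(config.alignment_path)
    codon_aln = dio.as_codon_alignment(aln, strict=False)
    tree = dio.read_tree(config.tree_path)
    taxonomy = None
    if config.taxonomy_path:
        taxonomy = dio.read_taxonomy(config.taxonomy_path)
        hashes["taxonomy"] = _sha256(config.taxonomy_path)
    log.info("[%s] inputs: %s", config.gene, hashes)
    report = analyze_gene(config.gene, codon_aln, tree, taxonomy, config)
    report.input_hashes.update(hashes)
    if config.out_dir:
        report.write(config.out_dir)
    return report


# --------------------------------------------------------------- comparison
def resolve_polytomies_ml(tree: PhyloTree, aln: dio.NucAlignment,
                          params: Optional[GtrGammaParams] = None) -> PhyloTree:
    """Resolve polytomies into zero-length bifurcations, choosing each join
    greedily by total likelihood under GTR+Γ."""
    tree = tree.copy()
    if params is None:
        states = np.array([[c for c in row] for row in aln.rows])
        freqs = np.array([(states == b).mean() for b in "ACGT"])
        freqs = np.maximum(freqs, 1e-3)
        params = GtrGammaParams(np.ones(6), freqs / freqs.sum(), alpha=1.0)
    for node in [n for n in tree.root.postorder() if len(n.children) > 2]:
        while len(node.children) > 2:
            best = None
            for i in range(len(node.children)):
                for j in range(i + 1, len(node.children)):
                    joint = Node(length=0.0)
                    a, b = node.children[i], node.children[j]
                    rest = [c for c in node.children if c not in (a, b)]
                    joint.children = [a, b]
                    node.children = rest + [joint]
                    joint.parent = node
                    a.parent = b.parent = joint
                    lnl = float(gtr_gamma_site_loglik(tree, aln, params).sum())
                    if best is None or lnl > best[0]:
                        best = (lnl, i, j)
                    # undo
                    node.children = rest
                    node.children.insert(i, a)
                    node.children.insert(j, b)
                    a.parent = b.parent = node
            _, i, j = best
            joint = Node(length=0.0)
            a, b = node.children[i], node.children[j]
            node.children = [c for c in node.children if c not in (a, b)]
            joint.children = [a, b]
            a.parent = b.parent = joint
            joint.parent = node
            node.children.append(joint)
    return tree


@dataclass
class ComparisonReport:
    support_vs_intensity: pd.DataFrame
    topology_tests: dict
    rate_comparison: object
    alpha_adjusted: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.support_vs_intensity.to_csv(out / "support_vs_intensity.tsv",
                                         sep="\t", index=False)
        for gene, result in self.topology_tests.items():
            result.to_frame().to_csv(out / f"{gene}.topotest.tsv",
                                     sep="\t", index=False)
        if self.rate_comparison is not None:
            self.rate_comparison.posthoc.to_csv(out / "rate_posthoc.tsv",
                                                sep="\t", index=False)


def run_comparison_report(
    gene_inputs: Sequence[tuple[GeneReport, dio.NucAlignment]],
    supertree: PhyloTree,
    config: RunConfig = RunConfig(),
) -> ComparisonReport:
    """Cross-gene report: support-vs-intensity table, SH/AU congruence of each
    gene's parsimony candidates against the pruned supertree, and the
    divergence-rate comparison across genes."""
    if len(gene_inputs) < 2:
        raise SizeError("comparison needs at least 2 gene reports")
    records = []
    for report, _ in gene_inputs:
        if report.support is None or report.intensity is None:
            raise ValueError(f"gene {report.gene} lacks support or intensity")
        records.append((report.gene, report.support, report.intensity))
    fig_table = support_vs_selection_table(records)

    topo_results, alpha_adj = {}, {}
    for report, aln in gene_inputs:
        gene = report.gene
        candidates, score = parsimony_candidates(
            aln, n_starts=config.parsimony_starts, seed=config.seed
        )
        log.info("[%s] %d parsimony candidates (score %d)", gene,
                 len(candidates), score)
        try:
            constrained = prune_to_shared_taxa(supertree, aln.taxa)
        except PruningError as exc:
            log.warning("[%s] supertree pruning failed: %s", gene, exc)
            continue
        if not constrained.is_binary():
            constrained = resolve_polytomies_ml(constrained, aln)
        trees = candidates + [constrained]
        labels = [f"{gene}_mp{i + 1}" for i in range(len(candidates))]
        labels.append("constrained_supertree")
        rows = []
        for t in trees:
            fitted, params, _ = fit_gtr_tree(t, aln)
            rows.append(gtr_gamma_site_loglik(fitted, aln, params))
        matrix = SiteLnLMatrix(np.vstack(rows), tuple(labels))
        m = len(trees)
        topo_results[gene] = topology_test_suite(
            matrix, B=config.rell_B, seed=config.seed, alpha=config.alpha, m=m
        )
        alpha_adj[gene] = bonferroni(config.alpha, m)

    groups = {
        report.gene: [r.normalized_rate for r in report.rate_records]
        for report, _ in gene_inputs
        if report.rate_records
    }
    comparison = None
    if len(groups) >= 2:
        try:
            comparison = rate_comparison(groups)
        except (SizeError, ValidationError) as exc:
            log.warning("rate comparison skipped: %s", exc)
    return ComparisonReport(fig_table, topo_results, comparison, alpha_adj)
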