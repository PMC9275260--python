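"""Canonical synthetic study designs.

These functions freeze the simulation conditions under which the package's
statistical guarantees are stated (parameter recovery, LRT calibration and
power, SH/AU topology-test calibration, divergence-rate recovery), so tests,
examples, and the reproduction script all run the same experiments. Problem
sizes are desk-scale: see docs/methods.md for the rationale behind each
design choice.

All randomness derives from a single integer seed; replicate seeds are
spawned deterministically from it and stay below 2**31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import SiteLnLMatrix, fit_gtr_tree, gtr_gamma_site_loglik
from .models import (
    CodonModelParams,
    GtrGammaParams,
    SiteClassDistribution,
    equal_codon_frequencies,
)
from .selection import SiteModelAnalysis, likelihood_ratio_test
from .simulate import (
    CladeSpec,
    simulate_codon_alignment,
    simulate_labeled_tree,
    simulate_nuc_alignment,
)
from .topology import au_test, sh_test
from .trees import PhyloTree
from .treestats import (
    normalize_rates,
    rank_rate_breakpoint,
    tip_divergence_rates,
)

__all__ = [
    "ZAN_POINT",
    "zan_point_tree",
    "m8_recovery_experiment",
    "lrt_calibration_experiment",
    "topology_calibration_experiment",
    "rate_recovery_experiment",
]


def _subseeds(seed: int, n: int, tag: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), tag)))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ------------------------------------------------------------ selection study
@dataclass(frozen=True)
class ZanPoint:
    """The positive-selection operating point reported for the focal gene:
    positive-class dN/dS 8.67 on 22% of sites over 1932 codons, here placed
    on a strongly purifying beta background."""

    omega_s: float = 8.67
    p1: float = 0.22
    beta_p: float = 0.2
    beta_q: float = 2.0
    kappa: float = 2.0
    n_codons: int = 1932
    n_tips: int = 16
    tree_height: float = 2.5  # expected codon substitutions, root to tip

    def classes(self) -> SiteClassDistribution:
        return SiteClassDistribution.m8(
            self.beta_p, self.beta_q, 1.0 - self.p1, self.omega_s
        )

    def codon_params(self) -> CodonModelParams:
        return CodonModelParams(self.kappa, equal_codon_frequencies())


ZAN_POINT = ZanPoint()


def zan_point_tree(seed: int, n_tips: int | None = None,
                   tree_height: float | None = None) -> PhyloTree:
    """Two-superorder balanced tree for the selection experiments."""
    n = n_tips or ZAN_POINT.n_tips
    half = n // 2
    spec = [
        CladeSpec("SO1", "O1", (("F1", half),)),
        CladeSpec("SO2", "O2", (("F2", n - half),)),
    ]
    tree, _ = simulate_labeled_tree(
        n, clade_spec=spec, seed=seed,
        tree_height=tree_height or ZAN_POINT.tree_height,
    )
    return tree


def m8_recovery_experiment(
    n_replicates: int = 10,
    seed: int = 0,
    omega_tol: float = 0.25,
    p1_tol: float = 0.05,
) -> dict:
    """Simulate at the focal operating point and refit M8 per replicate.

    Returns per-replicate estimates and the count recovering ω_s within
    ``omega_tol`` (relative) and p1 within ``p1_tol`` (absolute).
    """
    point = ZAN_POINT
    tree = zan_point_tree(seed)
    classes = point.classes()
    params = point.codon_params()
    estimates, n_ok = [], 0
    for rep_seed in _subseeds(seed, n_replicates, tag=101):
        aln, _ = simulate_codon_alignment(
            tree, classes, params, point.n_codons, seed=rep_seed
        )
        m8 = SiteModelAnalysis(aln, tree).fit_m8()
        ws, p1 = m8.params["omega_s"], m8.params["p1"]
        ok = (abs(ws - point.omega_s) / point.omega_s <= omega_tol
              and abs(p1 - point.p1) <= p1_tol)
        n_ok += ok
        estimates.append({"omega_s": ws, "p1": p1, "recovered": bool(ok)})
    return {
        "n_replicates": n_replicates,
        "n_recovered": n_ok,
        "estimates": estimates,
        "true_omega_s": point.omega_s,
        "true_p1": point.p1,
    }


def lrt_calibration_experiment(
    n_null: int = 60,
    n_power: int = 40,
    n_codons: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """M7-vs-M8 LRT size under M7 truth and power at the focal point.

    The null simulates the purifying beta background alone; the alternative
    simulates the full positive-selection mixture. Rejection at the
    chi-square(2) alpha level is counted (the null sits on the boundary of
    the alternative, so the test is expected to be conservative).
    """
    point = ZAN_POINT
    tree = zan_point_tree(seed)
    params = point.codon_params()
    null_classes = SiteClassDistribution.m7(point.beta_p, point.beta_q)
    alt_classes = point.classes()

    def run(classes, seeds):
        rejections, pvals = 0, []
        for s in seeds:
            aln, _ = simulate_codon_alignment(tree, classes, params, n_codons, seed=s)
            analysis = SiteModelAnalysis(aln, tree)
            lrt = likelihood_ratio_test(analysis.fit_m7(), analysis.fit_m8(), df=2)
            pvals.append(lrt.p_value)
            rejections += lrt.p_value < alpha
        return rejections, pvals

    null_rej, null_p = run(null_classes, _subseeds(seed, n_null, tag=201))
    power_rej, power_p = run(alt_classes, _subseeds(seed, n_power, tag=202))
    return {
        "n_null": n_null,
        "null_rejections": null_rej,
        "null_rejection_rate": null_rej / n_null,
        "n_power": n_power,
        "power_rejections": power_rej,
        "power": power_rej / n_power,
        "null_pvalues": null_p,
        "power_pvalues": power_p,
        "alpha": alpha,
    }


# ------------------------------------------------------------ topology study
def _random_wrong_topology(tree: PhyloTree, seed: int) -> PhyloTree:
    """A grossly wrong random topology over the same tips: none of the true
    tree's non-trivial splits are retained (falls back to the candidate with
    fewest shared splits)."""
    from .topology import _random_addition_tree

    rng = np.random.default_rng(seed)
    target = tree.splits()
    best, best_shared = None, None
    for _ in range(200):
        cand = _random_addition_tree(tree.tip_names, rng)
        shared = len(cand.splits() & target)
        if shared == 0:
            return cand
        if cand.splits() != target and (best is None or shared < best_shared):
            best, best_shared = cand, shared
    return best


def topology_calibration_experiment(
    n_replicates: int = 100,
    n_tips: int = 8,
    n_sites: int = 500,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    tree_height: float = 0.8,
) -> dict:
    """SH/AU calibration: data simulated under GTR+Γ on a known topology,
    tested against that topology and a random wrong topology.

    Counts how often the generating topology is retained (p > alpha) and the
    wrong one rejected (p < alpha) by each test.
    """
    gtr = GtrGammaParams(
        np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0]),
        np.array([0.3, 0.2, 0.2, 0.3]),
        alpha=0.5,
    )
    counts = {"au_true_retained": 0, "au_wrong_rejected": 0,
              "sh_true_retained": 0, "sh_wrong_rejected": 0,
              "sh_au_agree": 0}
    rep_seeds = _subseeds(seed, n_replicates, tag=301)
    for rep, s in enumerate(rep_seeds):
        true_tree, _ = simulate_labeled_tree(
            n_tips, seed=s, tree_height=tree_height,
        )
        aln, _ = simulate_nuc_alignment(true_tree, gtr, n_sites, seed=s)
        wrong = _random_wrong_topology(true_tree, seed=s + 1)
        rows, labels = [], ["true", "wrong"]
        for topo in (true_tree, wrong):
            fitted, fitted_params, _ = fit_gtr_tree(
                topo, aln, fit_exchangeabilities=False, fit_alpha=True,
                initial=gtr, max_iter=80,
            )
            rows.append(gtr_gamma_site_loglik(fitted, aln, fitted_params))
        matrix = SiteLnLMatrix(np.vstack(rows), tuple(labels))
        p_sh = sh_test(matrix, B=B, seed=s)
        p_au = au_test(matrix, B_per_scale=B, seed=s + 1)
        counts["au_true_retained"] += p_au[0] > alpha
        counts["au_wrong_rejected"] += p_au[1] < alpha
        counts["sh_true_retained"] += p_sh[0] > alpha
        counts["sh_wrong_rejected"] += p_sh[1] < alpha
        agree = ((p_au[1] < alpha) == (p_sh[1] < alpha)) and (
            (p_au[0] > alpha) == (p_sh[0] > alpha)
        )
        counts["sh_au_agree"] += agree
    counts["n_replicates"] = n_replicates
    return counts


# ----------------------------------------------------------------- rate study
def rate_recovery_experiment(
    seed: int = 0,
    n_slow: int = 91,
    n_fast: int = 21,
    multiplier: float = 3.0,
    jitter: float = 0.1,
) -> dict:
    """The 91-slow / 21-fast divergence-rate regime.

    A two-superorder tree gets a clade rate multiplier on the fast group and
    mild lognormal tip-rate jitter; per-tip crown-anchored rates are
    normalized and the rank-rate breakpoint and clade mean ratio measured.
    """
    # both superorders get two families so their crown origins sit at the
    # same depth and the clade mean-rate ratio identifies the multiplier
    spec = [
        CladeSpec("SlowSO", "SlowO", (("SF1", n_slow // 2),
                                      ("SF2", n_slow - n_slow // 2))),
        CladeSpec("FastSO", "FastO", (("FF1", n_fast // 2),
                                      ("FF2", n_fast - n_fast // 2))),
    ]
    tree, taxonomy = simulate_labeled_tree(
        n_slow + n_fast,
        clade_spec=spec,
        rate_multipliers={"FastSO": multiplier},
        seed=seed,
        tree_height=1.0,
        tip_rate_jitter=jitter,
    )
    records = tip_divergence_rates(tree, taxonomy, anchor="crown", gene="sim")
    normalized, ranges = normalize_rates(records)
    fit = rank_rate_breakpoint(normalized)
    fast = [r.normalized_rate for r in normalized if r.superorder == "FastSO"]
    slow = [r.normalized_rate for r in normalized if r.superorder == "SlowSO"]
    ratio = float(np.mean(fast) / np.mean(slow))
    return {
        "breakpoint": fit.breakpoint,
        "expected_breakpoint": n_slow,
        "dynamic_range": ranges["sim"],
        "clade_ratio": ratio,
        "true_multiplier": multiplier,
        "records": normalized,
        "tree": tree,
        "taxonomy": taxonomy,
    }
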