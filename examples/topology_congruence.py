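"""Test candidate topologies against a constraint tree with SH and AU tests.

Simulates nucleotide data under GTR+Γ on a known species tree, searches for
maximum-parsimony candidate topologies, evaluates per-site GTR+Γ
log-likelihoods for each candidate plus a deliberately wrong topology, and
runs the RELL-bootstrap SH and AU tests with Bonferroni correction.
"""

import numpy as np

from divsel.likelihood import SiteLnLMatrix, fit_gtr_tree, gtr_gamma_site_loglik
from divsel.models import GtrGammaParams
from divsel.simulate import simulate_labeled_tree, simulate_nuc_alignment
from divsel.studies import _random_wrong_topology
from divsel.topology import parsimony_candidates, topology_test_suite

gtr = GtrGammaParams(
    np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0]),
    np.array([0.3, 0.2, 0.2, 0.3]),
    alpha=0.5,
)
true_tree, _ = simulate_labeled_tree(8, seed=4, tree_height=0.8)
aln, _ = simulate_nuc_alignment(true_tree, gtr, n_sites=500, seed=4)

candidates, score = parsimony_candidates(aln, n_starts=8, seed=0)
print(f"parsimony search: {len(candidates)} candidate tree(s), length {score}")

trees = candidates + [_random_wrong_topology(true_tree, seed=5)]
labels = [f"mp{i + 1}" for i in range(len(candidates))] + ["wrong"]
rows = []
for topo in trees:
    fitted, params, lnl = fit_gtr_tree(topo, aln, fit_exchangeabilities=False,
                                       initial=gtr)
    rows.append(gtr_gamma_site_loglik(fitted, aln, params))
matrix = SiteLnLMatrix(np.vstack(rows), tuple(labels))

result = topology_test_suite(matrix, B=10_000, seed=1)
print(result.to_frame().to_string(index=False))
print(f"alpha (Bonferroni-adjusted for {len(trees)} trees): "
      f"{result.alpha_adjusted:.4f}")
# the parsimony candidate matching the generating tree is retained (large
# p_SH/p_AU); the scrambled topology is rejected at the adjusted level
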