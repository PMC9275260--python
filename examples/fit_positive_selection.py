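"""Detect positive selection in a simulated gene.

Simulates a 16-species codon alignment in which 22% of sites evolve under
intense positive selection (dN/dS = 8.67) on a purifying background, then
fits the M0/M7/M8 site models, runs the M7-vs-M8 likelihood-ratio test,
identifies selected sites by empirical Bayes, and reports the aggregate
selection intensity ω×f.
"""

from divsel.selection import (
    SiteModelAnalysis,
    empirical_bayes_sites,
    likelihood_ratio_test,
    selection_intensity,
)
from divsel.simulate import simulate_codon_alignment
from divsel.studies import ZAN_POINT, zan_point_tree

tree = zan_point_tree(seed=1)
aln, truth = simulate_codon_alignment(
    tree, ZAN_POINT.classes(), ZAN_POINT.codon_params(), n_codons=600, seed=2
)
print(f"simulated {aln.n_taxa} species x {aln.n_codons} codons; "
      f"true omega_s={ZAN_POINT.omega_s}, true p1={ZAN_POINT.p1}")

analysis = SiteModelAnalysis(aln, tree)
for model in ("M0", "M7", "M8"):
    fit = analysis.fit(model)
    print(f"{model}: lnL={fit.lnl:.2f} {fit.params}")

m7, m8 = analysis.fit("M7"), analysis.fit("M8")
lrt = likelihood_ratio_test(m7, m8, df=2)
print(f"LRT M7 vs M8: 2dlnL={lrt.statistic:.2f}, df={lrt.df}, p={lrt.p_value:.3g}")
# a small p-value rejects the no-positive-selection model M7

detection = empirical_bayes_sites(m8, aln, tree, threshold=0.95)
print(f"sites with posterior >= 0.95: {len(detection.selected_sites)} "
      f"({detection.f_percent:.1f}% of {aln.n_codons})")

intensity = selection_intensity(m8.params["omega_s"], detection.f_percent)
print(f"selection intensity omega_s x f = {intensity.intensity:.1f}")
# omega_s near 8.67 and a significant LRT recover the simulated signal; the
# site fraction at the 0.95 posterior cutoff is conservative at 16 species
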