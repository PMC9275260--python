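# Methods

`divsel` implements, at desk scale, the comparative toolkit used to evaluate
whether a rapidly evolving gene behaves as a speciation gene: codon
site-model inference of positive selection with the aggregate ω×f intensity
statistic, node-support profiling of Bayesian gene trees, SH/AU congruence
tests of candidate topologies against a species supertree, normalized
divergence-rate analysis anchored at Superorder origins, and rule-based
synteny authentication of candidate zonadhesin (Zan / ZanL) loci. Real
sequence data are not bundled; every analysis is exercised on synthetic data
with recorded ground truth, generated by the package itself.

## Codon substitution model

Selection inference uses a GY94-style codon model over the 61 sense codons of
the standard code. The instantaneous rate from codon *i* to codon *j* is 0
if they differ at more than one position, and otherwise

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

with the diagonal set so rows sum to zero. Codon frequencies π are F3×4
(empirical position-specific nucleotide frequencies, stops excluded,
renormalized; a pseudo-count of 0.5 per base guards sparse alignments) or
equal (1/61). Transition matrices come from an eigendecomposition in the
π-symmetrized basis, which is exact for reversible generators and stable for
the branch lengths used here.

**Scaling convention.** Every class's rate matrix is normalized to one
expected substitution per codon site per unit branch length — per ω class,
on both the simulation and the inference side. Under this convention branch
lengths are expected substitutions within a site's own class, classes differ
only in their substitution *pattern* (nonsynonymous vs synonymous), and the
per-site likelihood is a one-dimensional function of ω for a fixed tree and
κ. The widely used alternative normalizes by the mixture-weighted mean rate,
making high-ω sites also evolve faster; under that convention the scale
factor moves with the mixture parameters during optimization. We adopt the
per-class convention uniformly because simulation and fitting must share one
convention for parameter-recovery statements to be meaningful, and because it
decouples the ω profile from the mixture weights (see below). ω and the
class weights are invariant to this choice; only the interpretation of
branch lengths differs from tools using mixture scaling.

## Site models and fitting

The site-model family is M0 (one ω), M1a (ω₀ < 1 plus a neutral class), M7
(ω ~ Beta(p, q) discretized into K = 10 equal-probability classes at their
bin means), and M8 (the M7 beta with weight p₀ plus one positive class with
ω_s ≥ 1 and weight p₁ = 1 − p₀). Mixture per-site likelihoods are
`logsumexp` over classes.

Fitting proceeds in two stages:

1. **M0**: bounded quasi-Newton (L-BFGS-B) over (log κ, log ω, log tree
   scale), where the scale multiplies the input branch lengths. κ and the
   scaled branch lengths are then frozen for the site-class models. Holding
   branch lengths (and here also κ) at their M0 estimates stabilizes the
   desk-scale optimization and is a common costing shortcut; joint
   re-estimation would change ℓ values slightly but not the LRT behaviour
   observed in calibration.
2. **Site-class models**: with tree and κ fixed, the per-site log-likelihood
   ℓ_h(ω) is evaluated exactly (full pruning) on a fixed grid of ~28 ω
   values (dense in (0, 1], log-spaced in [1, 50]) and interpolated with a
   cubic spline in log ω. M1a/M7/M8 likelihoods are maximized on this
   profile with multi-start L-BFGS-B (parameters transformed: log for beta
   shapes, logistic for proportions, log(ω_s − 1) with ω_s ∈ [1, 50]).
   The reported log-likelihood is then recomputed **exactly** at the
   maximizing parameters, so interpolation error enters only through the
   argmax (second-order in ℓ; measured at ≲0.05 lnL on 2,000-codon
   datasets). M8 is additionally evaluated exactly at the fitted M7
   boundary (p₁ = 0), so ℓ(M8) ≥ ℓ(M7) holds by construction and the LRT
   statistic is never negative.

The M7-vs-M8 likelihood-ratio test uses 2Δℓ against chi-square with 2
degrees of freedom (clamped at zero). The null sits on the boundary of the
alternative, so the test is conservative; the calibration experiment below
measures this directly.

**Site identification.** NEB (default) computes the posterior probability of
the positive class per site at the MLEs. A BEB-style variant integrates over
a coarse uniform grid on (p, q, p₀, ω_s) (default 8 points per axis: p, q on
(0, 2), p₀ on (0, 1), ω_s on (1, 11)), weighting grid points by their data
likelihood; grid likelihoods reuse the ω profile. The reported site fraction
f is the percentage of sites with posterior ≥ 0.95; the mixture weight p₁ is
reported alongside, since with few taxa the posterior cutoff is conservative
and f < p₁ even when p₁ itself is recovered accurately.

**ω×f.** The aggregate selection intensity is the positive-class ω times the
percentage of selected sites (percent scale, so ω = 8.67 at f = 22.0% gives
190.7, printed as 191). Full precision is kept internally; rounding is left
to presentation. Genes whose LRT is not significant, or with no selected
sites, take intensity 0 (the purifying/neutral path).

## Nucleotide model and topology tests

Topology work uses GTR+Γ(+I): 6 exchangeabilities, empirical base
frequencies, K = 4 equal-probability gamma categories at their bin means,
optional invariant class (gamma rates rescaled by 1/(1 − p_inv) so the
overall mean rate is 1). Branch lengths and model parameters are refit per
candidate topology by L-BFGS-B.

Candidate topologies come from Fitch parsimony (bitset implementation, gaps
as missing) with NNI hill-climbing from random-addition starting trees; all
topologies attaining the best score are retained, including a bounded
plateau walk over equal-score NNI neighbours, because equally
most-parsimonious trees are genuine candidates. The species constraint tree
is pruned to the shared taxa (degree-2 nodes suppressed with lengths summed,
polytomies preserved); polytomies are resolved for likelihood evaluation by
greedy ML joins with zero-length edges.

SH and AU tests operate on the per-site log-likelihood matrix with RELL
bootstrapping (resampled site log-likelihoods, default B = 10,000, same
resampled sites for every tree). SH centers replicates per tree and compares
the centered best-minus-candidate differences to the observed ones
(one-tailed). AU uses the multiscale bootstrap: ten relative sample sizes in
[0.5, 1.4]; Φ⁻¹(1 − BP) is regressed on d√r + c/√r by weighted least squares
and p = 1 − Φ(d − c). Bootstrap proportions of exactly 0 or 1 carry no
information about the boundary geometry, so those scales are dropped from
the fit; if fewer than three informative scales remain the tree is decided
directly (p = 0 if it essentially never wins, p = 1 if it essentially always
wins). Candidate sets are Bonferroni-corrected (α/m, m = number of trees in
the gene's comparison; corrections are not pooled across genes).

## Support accounting and divergence rates

Support summaries count internal nodes with support ≥ threshold (default
0.95, inclusive) under an explicit denominator convention — all internal
nodes, internal minus root, or annotated nodes only (default). Published
node-count pairs are reproduced by the same arithmetic via
`SupportSummary.from_counts`. Terminal nodes are internal nodes whose
descendant tips share one family (or genus); all others are deep.

Per-tip divergence rates sum branch lengths from the tip to its Superorder's
crown MRCA (default) or to the top of the MRCA's stem edge. Crown anchoring
is the default because it is well-defined for every in-group tip;
single-tip superorders have zero crown path, are flagged, and force stem
mode. Superorders must be monophyletic (checked, loud error otherwise).
Rates are normalized per gene to the slowest species; the dynamic range is
max/min of the raw rates. The rank-rate breakpoint fits two least-squares
lines to the sorted rates over all admissible splits (each segment ≥ 3
points) and declares no inflection when the two-segment fit reduces the
single-line residual sum of squares by less than 50%.

The rate comparison follows a gated decision tree: Shapiro-Wilk per group
and mean-centered Levene across groups; normal + heteroscedastic data go to
Welch's ANOVA, non-normal data are log-transformed and compared by
Kruskal-Wallis on ranks, normal + homoscedastic data use one-way ANOVA.
Post hoc: Games-Howell (Welch-type pairwise statistics referred to the
studentized range with Welch degrees of freedom) when variances are unequal,
Ryan's Q (REGWQ step-down studentized range with pooled variance) when
equal. Zero-variance groups are refused as degenerate rather than producing
undefined statistics.

## Synteny authentication

A candidate locus is scored against the reference AchE–Tfr2 gene set:
content (shared fraction of the reference genes), order (longest common
subsequence of the shared genes, orientation-agnostic, as a fraction), and
orientation (fraction of shared genes matching after fixing the majority
orientation), so progressively decayed synteny yields progressively lower
scores. The Ephb4–Epo anchor gap and any genes inside it are measured
directly. Domain verdicts: the Zan pattern requires ≥1 MAM before ≥1 mucin
before ≥2 consecutive full VWD domains; mucin plus tandem VWD without that
ordered pattern is the Zan-like pattern. Classification: ZAN requires the
Zan pattern, content and order ≥ 0.8, and a candidate ≥ 100 kb in the gap;
a ZanL-patterned candidate is ZANL at any synteny level; no candidate in the
gap (e.g. a 30 kb gap that cannot hold a 100+ kb gene) is ABSENT. The 0.8
and 100 kb thresholds are this package's operationalization of criteria the
original analysis applied qualitatively, and are exposed in configuration.

## Synthetic data

Generators are pure functions of (parameters, seed); each operation draws
from an independent stream derived from (seed, operation tag).

- **Trees**: ultrametric by hierarchical assembly — birth-death subtrees per
  family (crown at 25% of total height), families joined under order/
  superorder backbones (crowns at 60%), superorders joined at the root.
  Clade rate multipliers scale every branch inside a group's crown;
  optional lognormal tip-rate jitter adds lineage-specific noise. Trees are
  ultrametric before multipliers/jitter.
- **Codon alignments**: per site, an ω class is drawn from the mixture and
  one codon evolved down the tree by sampling from exp(Q(ω)t) row-wise;
  alignments are gap-free (no indel process) and the truth records every
  site's class.
- **Support annotations**: Beta-distributed supports per internal node
  (root unannotated, as in consensus trees), with a penalized distribution
  for deep nodes to emulate resolved-terminal/unresolved-deep regimes.
- **Locus tables**: a stylized 12-gene AchE–Tfr2 locus (synthetic gene order;
  only the modelled quantities — 12 vs 11 genes, the 30 kb deleted-scenario
  anchor gap, the >100 kb candidate — are meaningful).

What the generators do **not** emulate: alignment error and indels,
selection on synonymous codon usage, among-branch ω variation, non-binary
gene flow, and real taxon sampling. Passing the synthetic experiments
therefore demonstrates correctness and calibration of the estimators under
the stated models, not robustness to real-data violations of them.

## Frozen study designs and problem sizes

The canonical experiments (in `divsel.studies`, shared by the tests, the
examples, and `scripts/acceptance.py`) use desk-scale problem sizes chosen
once, by pilot, so that each experiment carries enough information for its
stated tolerance on a single CPU in minutes:

- **Selection operating point**: ω_s = 8.67 on 22% of sites over 1,932
  codons (the reported values for the focal gene), placed on a strongly
  purifying Beta(0.2, 2.0) background (the shape is not reported; a mostly
  conserved background matches the biology of a structural gamete-adhesion
  gene), κ = 2, equal codon frequencies, 16 tips in two superorders, tree
  height 2.5 expected codon substitutions root-to-tip (≈0.8 nucleotide
  substitutions per site — a fast gene across ~100 Myr of divergence). Ten
  replicates; recovery demanded within 25% (ω_s) and ±0.05 (p₁) in ≥8.
- **LRT calibration**: 60 null (M7-truth) and 40 alternative replicates at
  300 codons; size ≤ 0.10 at α = 0.05 (boundary-conservative; observed ~0)
  and power ≥ 0.90 at the operating point.
- **SH/AU calibration**: 100 replicates, 8 tips, 500 sites, GTR+Γ
  (α = 0.5), B = 2,000 per scale; the generating topology must be retained
  and a random topology sharing no splits with the truth rejected, each in
  ≥95 replicates. B = 10,000 remains the library default for analyses.
- **Rate regime**: 112 species, 91 slow / 21 fast with a ×3 clade
  multiplier and 10% lognormal tip jitter; the breakpoint must land within
  ±2 of rank 91 and the clade mean-rate ratio within 10% of the multiplier.

## Numerical choices and degenerate inputs

Per-site scaling in the pruning recursion guards underflow; all-missing
columns have likelihood exactly 1. Codons containing N or a gap are missing
data (partials of 1), preserving site indexing for the empirical-Bayes
report. Transition-matrix entries are clipped at 0 after eigendecomposition
round-off. Optimizer bounds: κ, ω, scale ∈ e^[−10, 6]; beta shapes
∈ [0.004, 100]; ω_s ∈ [1, 50] (matching "ω > 1 allowed" while preventing
divergence on degenerate data). LRT statistics are clamped at 0. Fitch
treats gaps/N as full ambiguity. The breakpoint fit requires ≥6 points.

## Known limitations

Branch lengths and κ are not re-optimized per site model; BEB uses a coarse
grid with the profile approximation; the AU fallback for fully decided trees
reports 0/1 rather than a Monte-Carlo-bounded p; parsimony search is NNI
only (no SPR/TBR), adequate at the taxon counts used here; the synteny
screen consumes declared domain architectures rather than inferring them
from sequence. Branch-length interpretation differs from mixture-scaled
implementations (see Scaling convention above).
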