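"""Site-model selection analysis: M0/M1a/M7/M8 fits, likelihood-ratio tests,
empirical-Bayes identification of positively selected sites, and the ω×f
selection-intensity statistic.

Fitting strategy
----------------
M0 (one global ω) is fitted first by bounded quasi-Newton over (κ, ω, tree
scale). κ and the scaled branch lengths are then held fixed for the site-class
models, which makes the per-site log-likelihood a smooth one-dimensional
function of ω. That function is evaluated exactly (full pruning) on a fixed ω
grid and interpolated by a cubic spline in log ω; the M1a/M7/M8 mixture
likelihoods are maximized on the interpolated profile (cheap, so multi-start
is free) and the reported log-likelihood is then recomputed exactly at the
maximizing parameters. M8 is additionally evaluated exactly at the fitted M7
boundary (p1 = 0), so the nesting ℓ(M8) ≥ ℓ(M7) holds by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import CubicSpline
from scipy.special import expit, logit, logsumexp

from .errors import ConvergenceError, ParameterError, ValidationError
from .io import CodonAlignment
from .likelihood import (
    ReversibleModel,
    codon_omega_loglik,
    mixture_loglik,
    pruning_loglik,
    site_class_loglik,
)
from .models import (
    CodonModelParams,
    SiteClassDistribution,
    discretize_beta,
    equal_codon_frequencies,
    f3x4_frequencies,
    gy94_rate_matrix,
)
from .trees import PhyloTree

__all__ = [
    "FitOptions",
    "SiteModelFit",
    "LRTResult",
    "SelectionIntensity",
    "SiteModelAnalysis",
    "fit_site_model",
    "likelihood_ratio_test",
    "empirical_bayes_sites",
    "selection_intensity",
    "support_vs_selection_table",
]

_OMEGA_MAX = 50.0
_OMEGA_MIN = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Knobs for the site-model fits."""

    K: int = 10  # beta categories for M7/M8
    pi_mode: str = "F3x4"  # or "equal"
    n_restarts: int = 5
    max_iter: int = 200
    m0_max_iter: int = 80
    grid_size_below_one: int = 16
    grid_size_above_one: int = 12


@dataclass(frozen=True)
class SiteModelFit:
    """MLEs and diagnostics for one site model on one gene."""

    model: str
    lnl: float
    kappa: float
    tree_scale: float
    classes: SiteClassDistribution
    params: dict
    n_free_params: int
    converged: bool
    n_iter: int
    restarts_used: int

    def __post_init__(self):
        if not np.isfinite(self.lnl):
            raise ConvergenceError(f"{self.model}: non-finite log-likelihood")


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


@dataclass(frozen=True)
class SelectionIntensity:
    """ω̂_s (positive-class dN/dS), f (percent of sites under positive
    selection) and their product, on the percentage scale."""

    omega_s: float
    f_percent: float

    def __post_init__(self):
        if self.omega_s < 0:
            raise ParameterError("omega_s must be >= 0")
        if not (0.0 <= self.f_percent <= 100.0):
            raise ParameterError("f must be a percentage in [0, 100]")

    @property
    def intensity(self) -> float:
        return self.omega_s * self.f_percent


def selection_intensity(omega_s: float, f_percent: float) -> SelectionIntensity:
    """Aggregate selection intensity ω × f (f on the percent scale)."""
    return SelectionIntensity(float(omega_s), float(f_percent))


def likelihood_ratio_test(null_fit, alt_fit, df: int = 2) -> LRTResult:
    """2Δℓ against the chi-square reference; the statistic is clamped at 0
    (optimizer noise can leave ℓ_alt marginally below ℓ_null)."""
    if df < 1:
        raise ParameterError("df must be >= 1")
    lnl_null = null_fit.lnl if hasattr(null_fit, "lnl") else float(null_fit)
    lnl_alt = alt_fit.lnl if hasattr(alt_fit, "lnl") else float(alt_fit)
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


# ------------------------------------------------------------------ analysis
class SiteModelAnalysis:
    """Fits the site-model family for one codon alignment on one tree,
    sharing the M0 fit and the ω profile across models."""

    def __init__(self, codon_aln: CodonAlignment, tree: PhyloTree,
                 options: FitOptions = FitOptions()):
        if not tree.has_branch_lengths():
            raise ValidationError("tree must carry initial branch lengths")
        self.aln = codon_aln
        self.tree = tree
        self.opt = options
        if options.pi_mode == "F3x4":
            pi = f3x4_frequencies(codon_aln)
        elif options.pi_mode == "equal":
            pi = equal_codon_frequencies(codon_aln.code_id)
        else:
            raise ParameterError(f"unknown pi_mode {options.pi_mode!r}")
        self._pi = pi
        self._fits: dict[str, SiteModelFit] = {}
        self._profile: Optional[CubicSpline] = None
        self._grid: Optional[np.ndarray] = None
        self._scaled_tree: Optional[PhyloTree] = None

    # ------------------------------------------------------------------ M0
    def _params(self, kappa: float) -> CodonModelParams:
        return CodonModelParams(kappa, self._pi, self.aln.code_id)

    def _m0_loglik(self, kappa: float, omega: float, scale: float) -> float:
        model = ReversibleModel(
            gy94_rate_matrix(self._params(kappa), omega), self._pi
        )
        return float(pruning_loglik(self.tree, self.aln, model, rate=scale).sum())

    def fit_m0(self) -> SiteModelFit:
        if "M0" in self._fits:
            return self._fits["M0"]

        def objective(theta):
            kappa, omega, scale = np.exp(np.clip(theta, -10, 6))
            return -self._m0_loglik(kappa, omega, scale)

        starts = [np.log([2.0, 0.4, 1.0]), np.log([1.0, 1.0, 0.5])]
        best = None
        used = 0
        for x0 in starts[: max(1, min(len(starts), self.opt.n_restarts))]:
            used += 1
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"maxiter": self.opt.m0_max_iter, "ftol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < np.inf and used >= 1 and best.success:
                break
        kappa, omega, scale = np.exp(np.clip(best.x, -10, 6))
        fit = SiteModelFit(
            model="M0",
            lnl=-float(best.fun),
            kappa=float(kappa),
            tree_scale=float(scale),
            classes=SiteClassDistribution.m0(float(omega)),
            params={"omega": float(omega)},
            n_free_params=3,
            converged=bool(best.success),
            n_iter=int(best.nit),
            restarts_used=used,
        )
        self._fits["M0"] = fit
        return fit

    # -------------------------------------------------------------- profile
    @property
    def scaled_tree(self) -> PhyloTree:
        if self._scaled_tree is None:
            m0 = self.fit_m0()
            t = self.tree.copy()
            t.scale_branch_lengths(m0.tree_scale)
            self._scaled_tree = t
        return self._scaled_tree

    def _omega_profile(self) -> CubicSpline:
        """Exact per-site log-likelihood on an ω grid, interpolated in log ω."""
        if self._profile is not None:
            return self._profile
        m0 = self.fit_m0()
        grid = np.unique(
            np.concatenate(
                [
                    [_OMEGA_MIN],
                    np.geomspace(1e-4, 1.0, self.opt.grid_size_below_one),
                    np.geomspace(1.0, _OMEGA_MAX, self.opt.grid_size_above_one),
                ]
            )
        )
        params = self._params(m0.kappa)
        values = codon_omega_loglik(self.scaled_tree, self.aln, params, grid).T
        self._grid = grid
        self._profile = CubicSpline(np.log(grid), values, axis=0)
        return self._profile

    def _profile_site_class_loglik(self, omegas: np.ndarray) -> np.ndarray:
        spline = self._omega_profile()
        om = np.clip(np.asarray(omegas, dtype=float), _OMEGA_MIN, _OMEGA_MAX)
        return spline(np.log(om)).T  # (S, K)

    def _profile_total(self, classes: SiteClassDistribution) -> float:
        ll = self._profile_site_class_loglik(classes.omegas)
        return float(mixture_loglik(ll, classes.weights).sum())

    def exact_class_loglik(self, classes: SiteClassDistribution) -> np.ndarray:
        m0 = self.fit_m0()
        return site_class_loglik(
            self.scaled_tree, self.aln, self._params(m0.kappa), classes
        )

    def exact_total(self, classes: SiteClassDistribution) -> float:
        return float(
            mixture_loglik(self.exact_class_loglik(classes), classes.weights).sum()
        )

    # ------------------------------------------------------------ mixtures
    def _optimize_mixture(self, make_classes, starts) -> tuple:
        """Maximize the profile likelihood over transformed parameters."""

        def objective(theta):
            try:
                classes = make_classes(theta)
            except (ParameterError, ValidationError):
                return 1e12
            return -self._profile_total(classes)

        best, used, total_nit = None, 0, 0
        n = max(1, min(len(starts), self.opt.n_restarts))
        for x0 in starts[:n]:
            used += 1
            res = optimize.minimize(
                objective, np.asarray(x0, dtype=float), method="L-BFGS-B",
                options={"maxiter": self.opt.max_iter, "ftol": 1e-10},
            )
            total_nit += int(res.nit)
            if best is None or res.fun < best.fun:
                best = res
        return make_classes(best.x), best, used, total_nit

    def fit_m1a(self) -> SiteModelFit:
        if "M1a" in self._fits:
            return self._fits["M1a"]
        m0 = self.fit_m0()

        def make(theta):
            omega0 = expit(theta[0]) * (1.0 - 1e-9)
            p0 = expit(theta[1])
            return SiteClassDistribution.m1a(float(omega0), float(p0))

        starts = [
            [logit(0.2), logit(0.7)],
            [logit(0.05), logit(0.9)],
            [logit(0.5), logit(0.5)],
        ]
        classes, res, used, nit = self._optimize_mixture(make, starts)
        fit = SiteModelFit(
            model="M1a", lnl=self.exact_total(classes), kappa=m0.kappa,
            tree_scale=m0.tree_scale, classes=classes,
            params={"omega0": float(classes.omegas[0]),
                    "p0": float(classes.weights[0])},
            n_free_params=2, converged=bool(res.success),
            n_iter=nit, restarts_used=used,
        )
        self._fits["M1a"] = fit
        return fit

    def fit_m7(self) -> SiteModelFit:
        if "M7" in self._fits:
            return self._fits["M7"]
        m0 = self.fit_m0()
        K = self.opt.K

        def make(theta):
            p, q = np.exp(np.clip(theta, -5.5, 4.6))
            return SiteClassDistribution.m7(float(p), float(q), K)

        starts = [
            np.log([0.5, 1.5]), np.log([0.2, 0.5]), np.log([1.0, 1.0]),
            np.log([2.0, 5.0]), np.log([0.1, 2.0]),
        ]
        classes, res, used, nit = self._optimize_mixture(make, starts)
        fit = SiteModelFit(
            model="M7", lnl=self.exact_total(classes), kappa=m0.kappa,
            tree_scale=m0.tree_scale, classes=classes,
            params={"p": float(classes.p), "q": float(classes.q)},
            n_free_params=2, converged=bool(res.success),
            n_iter=nit, restarts_used=used,
        )
        self._fits["M7"] = fit
        return fit

    def fit_m8(self) -> SiteModelFit:
        if "M8" in self._fits:
            return self._fits["M8"]
        m0 = self.fit_m0()
        m7 = self.fit_m7()
        K = self.opt.K

        def make(theta):
            p, q = np.exp(np.clip(theta[:2], -5.5, 4.6))
            p0 = expit(theta[2])
            omega_s = 1.0 + np.exp(np.clip(theta[3], -14, np.log(_OMEGA_MAX - 1.0)))
            return SiteClassDistribution.m8(
                float(p), float(q), float(p0), float(omega_s), K
            )

        lp, lq = np.log(max(m7.classes.p, 1e-3)), np.log(max(m7.classes.q, 1e-3))
        starts = [
            [lp, lq, logit(0.9), np.log(3.0)],
            [lp, lq, logit(0.7), np.log(7.0)],
            [np.log(0.5), np.log(1.5), logit(0.8), np.log(1.5)],
            [lp, lq, logit(0.99), np.log(0.5)],
            [np.log(0.2), np.log(0.5), logit(0.6), np.log(15.0)],
        ]
        classes, res, used, nit = self._optimize_mixture(make, starts)
        lnl = self.exact_total(classes)
        # boundary guard: M8 at p1 -> 0 contains M7 exactly
        if lnl < m7.lnl:
            classes = SiteClassDistribution.m8(
                m7.classes.p, m7.classes.q, 1.0, 1.0, K
            )
            lnl = m7.lnl
        fit = SiteModelFit(
            model="M8", lnl=lnl, kappa=m0.kappa, tree_scale=m0.tree_scale,
            classes=classes,
            params={
                "p": float(classes.p), "q": float(classes.q),
                "p0": float(classes.p0), "p1": float(1.0 - classes.p0),
                "omega_s": float(classes.omega_s),
            },
            n_free_params=4, converged=bool(res.success),
            n_iter=nit, restarts_used=used,
        )
        self._fits["M8"] = fit
        return fit

    def fit(self, model: str) -> SiteModelFit:
        dispatch = {"M0": self.fit_m0, "M1a": self.fit_m1a,
                    "M7": self.fit_m7, "M8": self.fit_m8}
        try:
            return dispatch[model]()
        except KeyError:
            raise ParameterError(f"unknown site model {model!r}") from None


def fit_site_model(
    codon_aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    options: FitOptions = FitOptions(),
) -> SiteModelFit:
    """Fit one site model by maximum likelihood (see SiteModelAnalysis for
    the shared-profile protocol; use the class directly to fit several
    models without redundant work)."""
    return SiteModelAnalysis(codon_aln, tree, options).fit(model)


# ------------------------------------------------------------ site detection
@dataclass(frozen=True)
class SiteDetection:
    posterior: np.ndarray  # P(site in positive class), per site
    selected_sites: tuple[int, ...]  # 0-based codon indices
    threshold: float
    method: str

    @property
    def f_percent(self) -> float:
        return 100.0 * len(self.selected_sites) / len(self.posterior)


def empirical_bayes_sites(
    m8_fit: SiteModelFit,
    codon_aln: CodonAlignment,
    tree: PhyloTree,
    threshold: float = 0.95,
    method: str = "NEB",
    options: FitOptions = FitOptions(),
    beb_grid_points: int = 8,
) -> SiteDetection:
    """Posterior probability per site of the positive-selection class.

    NEB plugs in the MLEs. BEB integrates over a coarse uniform grid on
    (p, q, p0, ω_s), weighting each grid point by its data likelihood;
    per-site class likelihoods on the grid come from the ω profile.
    """
    if m8_fit.model != "M8":
        raise ParameterError("site detection requires an M8 fit")
    analysis = SiteModelAnalysis(codon_aln, tree, options)
    # reuse the fit's fixed quantities rather than refitting M0
    analysis._fits["M0"] = SiteModelFit(
        model="M0", lnl=0.0, kappa=m8_fit.kappa, tree_scale=m8_fit.tree_scale,
        classes=SiteClassDistribution.m0(1.0), params={}, n_free_params=3,
        converged=True, n_iter=0, restarts_used=0,
    )
    p1 = 1.0 - m8_fit.classes.p0
    n_sites = codon_aln.n_codons
    if p1 <= 0.0:
        warnings.warn("M8 fit has p1 = 0; no sites can be under positive selection")
        return SiteDetection(np.zeros(n_sites), (), threshold, method)

    if method == "NEB":
        class_ll = analysis.exact_class_loglik(m8_fit.classes)
        logw = np.log(np.maximum(m8_fit.classes.weights, 1e-300))
        log_join = class_ll + logw[None, :]
        log_mix = logsumexp(log_join, axis=1)
        posterior = np.exp(log_join[:, -1] - log_mix)
    elif method == "BEB":
        posterior = _beb_posterior(analysis, m8_fit, beb_grid_points)
    else:
        raise ParameterError(f"unknown method {method!r}")
    selected = tuple(int(i) for i in np.flatnonzero(posterior >= threshold))
    return SiteDetection(posterior, selected, threshold, method)


def _beb_posterior(analysis: SiteModelAnalysis, m8_fit: SiteModelFit,
                   n_grid: int) -> np.ndarray:
    """Grid-integrated positive-class posterior (uniform priors)."""
    K = len(m8_fit.classes.omegas) - 1
    mid = (np.arange(n_grid) + 0.5) / n_grid
    p_grid = 2.0 * mid  # (0, 2)
    q_grid = 2.0 * mid
    p0_grid = mid  # (0, 1)
    ws_grid = 1.0 + 10.0 * mid  # (1, 11)

    beta_means = {
        (p, q): discretize_beta(p, q, K) for p in p_grid for q in q_grid
    }
    n_sites = analysis.aln.n_codons
    log_post_grid = []
    site_pos_given_grid = []
    for (p, q), means in beta_means.items():
        ll_beta = analysis._profile_site_class_loglik(means)  # (S, K)
        for ws in ws_grid:
            ll_pos = analysis._profile_site_class_loglik(np.array([ws]))  # (S,1)
            ll = np.concatenate([ll_beta, ll_pos], axis=1)
            for p0 in p0_grid:
                w = np.append(np.full(K, p0 / K), 1.0 - p0)
                logw = np.log(np.maximum(w, 1e-300))
                join = ll + logw[None, :]
                mix = logsumexp(join, axis=1)
                log_post_grid.append(mix.sum())
                site_pos_given_grid.append(np.exp(join[:, -1] - mix))
    log_post_grid = np.asarray(log_post_grid)
    grid_w = np.exp(log_post_grid - logsumexp(log_post_grid))
    post = np.zeros(n_sites)
    for w, sp in zip(grid_w, site_pos_given_grid):
        if w > 1e-12:
            post += w * sp
    return post


# ------------------------------------------------------------- summary table
def support_vs_selection_table(records: Sequence[tuple]) -> pd.DataFrame:
    """One row per gene: node support %, ω̂_s, f %, intensity; stable sort by
    intensity descending (the support-vs-selection comparison)."""
    if not records:
        raise ValidationError("no records")
    genes = [r[0] for r in records]
    if len(genes) != len(set(genes)):
        raise ValidationError("duplicate gene ids")
    rows = []
    for gene, support, intens in records:
        support_pct = getattr(support, "supported_pct", support)
        rows.append(
            {
                "gene": gene,
                "support_pct": float(support_pct),
                "omega_s": intens.omega_s,
                "f_percent": intens.f_percent,
                "intensity": intens.intensity,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        "intensity", ascending=False, kind="stable", ignore_index=True
    )
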