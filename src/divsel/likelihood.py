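"""Felsenstein pruning and per-site log-likelihoods.

One engine serves both state spaces: nucleotides (4 states, GTR+Γ+I) and
sense codons (61 states under the standard code, GY94). Transition matrices
come from an eigendecomposition in the π-symmetrized basis, valid for any
reversible generator and numerically stable. Missing states (gaps, N, codons
containing either) enter as partial likelihoods of 1, so site indexing is
preserved for the empirical-Bayes site reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .errors import MappingError, ParameterError, ValidationError
from .io import CodonAlignment, NucAlignment
from .models import (
    CodonModelParams,
    GtrGammaParams,
    SiteClassDistribution,
    get_code,
    gtr_rate_matrix,
    gy94_rate_matrix,
)
from .trees import PhyloTree

__all__ = [
    "ReversibleModel",
    "SiteLnLMatrix",
    "encode_nucleotides",
    "encode_codons",
    "pruning_loglik",
    "site_class_loglik",
    "mixture_loglik",
    "gtr_gamma_site_loglik",
    "fit_gtr_tree",
]

_TINY = 1e-300


class ReversibleModel:
    """Reversible CTMC with stationary distribution π; supplies P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        Q = np.asarray(Q, dtype=float)
        pi = np.asarray(pi, dtype=float)
        self.pi = pi
        self.n_states = Q.shape[0]
        sq = np.sqrt(pi)
        B = Q * (sq[:, None] / sq[None, :])
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        self._lam = lam
        self._A = U / sq[:, None]  # D^{-1/2} U
        self._B = (U * sq[:, None]).T  # U^T D^{1/2}

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t < 0:
            raise ParameterError(f"negative branch length {t}")
        if rate == 0.0 or t == 0.0:
            return np.eye(self.n_states)
        P = (self._A * np.exp(self._lam * (t * rate))) @ self._B
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_rates(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stacked P(t·r) for several rates, shape (R, n, n)."""
        if t < 0:
            raise ParameterError(f"negative branch length {t}")
        expo = np.exp(np.outer(np.asarray(rates, float) * t, self._lam))
        P = (self._A[None, :, :] * expo[:, None, :]) @ self._B
        np.clip(P, 0.0, None, out=P)
        zero = np.asarray(rates, float) * t == 0.0
        if zero.any():
            P[zero] = np.eye(self.n_states)
        return P


# ------------------------------------------------------------------ encoding
def encode_nucleotides(aln: NucAlignment) -> np.ndarray:
    """(n_taxa, n_sites) int8 states; -1 for N or gap."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return np.stack(
        [lut[np.frombuffer(row.encode(), dtype=np.uint8)] for row in aln.rows]
    )


def encode_codons(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) int16 states over sense codons; -1 for any codon
    containing N or a gap (or a stop, which validation normally excludes)."""
    code = get_code(aln.code_id)
    out = np.empty((aln.n_taxa, aln.n_codons), dtype=np.int16)
    for r, row in enumerate(aln.rows):
        for k in range(aln.n_codons):
            out[r, k] = code.codon_index.get(row[3 * k: 3 * k + 3], -1)
    return out


_STATE_CACHE: dict[tuple[int, int], tuple[dict[str, np.ndarray], int]] = {}


def _tip_states(aln, n_states: int) -> tuple[dict[str, np.ndarray], int]:
    # encoding is pure and alignments are immutable; cache by identity so
    # repeated likelihood evaluations on the same alignment skip re-encoding
    key = (id(aln), n_states)
    hit = _STATE_CACHE.get(key)
    if hit is not None and hit[2] is aln:
        return hit[0], hit[1]
    if n_states == 4:
        mat = encode_nucleotides(aln)
    else:
        if not isinstance(aln, CodonAlignment):
            raise ValidationError("codon model requires a CodonAlignment")
        mat = encode_codons(aln)
    states = {name: mat[i] for i, name in enumerate(aln.taxa)}
    if len(_STATE_CACHE) > 64:
        _STATE_CACHE.clear()
    _STATE_CACHE[key] = (states, mat.shape[1], aln)
    return states, mat.shape[1]


# ------------------------------------------------------------------- pruning
def _prune(tree: PhyloTree, tips: dict[str, np.ndarray], n_sites: int,
           P_of, pi: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood given per-edge transition matrices.

    ``P_of(node)`` returns P over the edge above ``node``.
    """
    n_states = len(pi)
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        F = np.ones((n_states, n_sites))
        for child in node.children:
            P = P_of(child)
            if child.is_leaf:
                try:
                    st = tips[child.name]
                except KeyError:
                    raise MappingError(
                        f"tip {child.name!r} absent from alignment"
                    ) from None
                M = np.ones((n_states, n_sites))
                obs = st >= 0
                M[:, obs] = P[:, st[obs]]
            else:
                M = P @ partials.pop(id(child))
            F *= M
        m = F.max(axis=0)
        pos = m > 0
        F[:, pos] /= m[pos]
        logscale += np.where(pos, np.log(np.maximum(m, _TINY)), -np.inf)
        partials[id(node)] = F
    if tree.root.is_leaf:
        raise ValidationError("tree root is a single tip")
    L = pi @ partials[id(tree.root)]
    return np.log(np.maximum(L, _TINY)) + logscale


def _edge_lengths_or_raise(tree: PhyloTree) -> None:
    for node in tree.postorder():
        if node is not tree.root and node.length is None:
            raise ValidationError("tree has missing branch lengths")


def _prune_multi(tree: PhyloTree, tips: dict[str, np.ndarray], n_sites: int,
                 P_of, pi: np.ndarray, R: int) -> np.ndarray:
    """Batched pruning over R models at once; P_of(node) -> (R, n, n).
    Returns per-model per-site log-likelihoods, shape (R, n_sites)."""
    n_states = len(pi)
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros((R, n_sites))
    for node in tree.postorder():
        if node.is_leaf:
            continue
        F = None
        for child in node.children:
            P = P_of(child)
            if child.is_leaf:
                try:
                    st = tips[child.name]
                except KeyError:
                    raise MappingError(
                        f"tip {child.name!r} absent from alignment"
                    ) from None
                M = np.ones((R, n_states, n_sites))
                obs = st >= 0
                M[:, :, obs] = P[:, :, st[obs]]
            else:
                M = P @ partials.pop(id(child))
            F = M if F is None else F * M
        m = F.max(axis=1)  # (R, S)
        pos = m > 0
        F /= np.where(pos, m, 1.0)[:, None, :]
        logscale += np.where(pos, np.log(np.maximum(m, _TINY)), -np.inf)
        partials[id(node)] = F
    if tree.root.is_leaf:
        raise ValidationError("tree root is a single tip")
    L = np.einsum("j,rjs->rs", pi, partials[id(tree.root)])
    return np.log(np.maximum(L, _TINY)) + logscale


def _check_tips(tree: PhyloTree, aln: NucAlignment) -> None:
    missing = set(tree.tip_names) - set(aln.taxa)
    if missing:
        raise MappingError(f"tree tips absent from alignment: {sorted(missing)}")


def pruning_loglik(tree: PhyloTree, aln: NucAlignment,
                   model: ReversibleModel, rate: float = 1.0) -> np.ndarray:
    """Per-site log-likelihoods under a single reversible model, root
    weighted by the stationary frequencies."""
    _edge_lengths_or_raise(tree)
    tips, n_sites = _tip_states(aln, model.n_states)
    _check_tips(tree, aln)
    return _prune(tree, tips, n_sites,
                  lambda nd: model.transition(nd.length, rate), model.pi)


def codon_omega_loglik(
    tree: PhyloTree,
    codon_aln: CodonAlignment,
    params: CodonModelParams,
    omegas,
    chunk: int = 8,
) -> np.ndarray:
    """(n_sites, K) per-site log-likelihoods for K ω values (batched)."""
    _edge_lengths_or_raise(tree)
    tips, n_sites = _tip_states(codon_aln, get_code(params.code_id).n_states)
    _check_tips(tree, codon_aln)
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    out = np.empty((len(omegas), n_sites))
    for lo in range(0, len(omegas), chunk):
        batch = omegas[lo: lo + chunk]
        models = [
            ReversibleModel(gy94_rate_matrix(params, float(om)), params.pi)
            for om in batch
        ]

        def P_of(node, models=models):
            return np.stack([m.transition(node.length) for m in models])

        out[lo: lo + len(batch)] = _prune_multi(
            tree, tips, n_sites, P_of, params.pi, len(batch)
        )
    return out.T


def site_class_loglik(
    tree: PhyloTree,
    codon_aln: CodonAlignment,
    params: CodonModelParams,
    classes: SiteClassDistribution,
) -> np.ndarray:
    """(n_sites, n_classes) log-likelihoods, one GY94 model per ω class."""
    return codon_omega_loglik(tree, codon_aln, params, classes.omegas)


def mixture_loglik(class_loglik: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-site mixture log-likelihood: logsumexp over classes."""
    logw = np.where(weights > 0, np.log(np.maximum(weights, _TINY)), -np.inf)
    return logsumexp(class_loglik + logw[None, :], axis=1)


def gtr_gamma_site_loglik(
    tree: PhyloTree, nuc_aln: NucAlignment, params: GtrGammaParams
) -> np.ndarray:
    """Per-site log-likelihoods under GTR+Γ+I (equal-weight gamma categories
    at their bin means, plus the invariant class)."""
    _edge_lengths_or_raise(tree)
    model = ReversibleModel(gtr_rate_matrix(params), params.freqs)
    rates, weights = params.rate_classes()
    tips, n_sites = _tip_states(nuc_aln, 4)
    _check_tips(tree, nuc_aln)
    per_class = _prune_multi(
        tree, tips, n_sites,
        lambda nd: model.transition_rates(nd.length, rates),
        params.freqs, len(rates),
    )
    return mixture_loglik(per_class.T, weights)


# --------------------------------------------------------------- lnL matrix
@dataclass(frozen=True)
class SiteLnLMatrix:
    """Per-site log-likelihoods for candidate topologies (rows = trees)."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValidationError("site lnL matrix must be 2-D")
        if len(self.labels) != v.shape[0]:
            raise ValidationError("one label per tree row required")
        if not np.all(np.isfinite(v)):
            raise ValidationError("site log-likelihoods must be finite")

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def total_lnls(self) -> np.ndarray:
        return self.values.sum(axis=1)


# ------------------------------------------------------------- GTR tree fit
def fit_gtr_tree(
    tree: PhyloTree,
    nuc_aln: NucAlignment,
    *,
    fit_branch_lengths: bool = True,
    fit_exchangeabilities: bool = True,
    fit_alpha: bool = True,
    fit_p_inv: bool = False,
    n_categories: int = 4,
    initial: GtrGammaParams | None = None,
    max_iter: int = 200,
) -> tuple[PhyloTree, GtrGammaParams, float]:
    """Maximum-likelihood GTR+Γ(+I) fit of branch lengths and model
    parameters on a fixed topology. Base frequencies are empirical.

    Returns (tree with fitted lengths, fitted params, total lnL).
    """
    tree = tree.copy()
    states = encode_nucleotides(nuc_aln)
    counts = np.bincount(states[states >= 0], minlength=4).astype(float) + 0.5
    freqs = counts / counts.sum()

    edges = [n for n in tree.postorder() if n is not tree.root]
    for e in edges:
        if e.length is None or e.length <= 0:
            e.length = 0.1

    init = initial or GtrGammaParams(
        np.ones(6), freqs, alpha=1.0, n_categories=n_categories, p_inv=0.0
    )

    # parameter packing: [log branch lengths | log exch (5 free, GT fixed) |
    #                     log alpha | logit p_inv]
    theta0, unpack_specs = [], []
    if fit_branch_lengths:
        theta0 += [np.log(max(e.length, 1e-6)) for e in edges]
    if fit_exchangeabilities:
        theta0 += list(np.log(init.exchangeabilities[:5] / init.exchangeabilities[5]))
    if fit_alpha:
        theta0.append(np.log(init.alpha))
    if fit_p_inv:
        p = min(max(init.p_inv, 1e-4), 0.5)
        theta0.append(np.log(p / (1 - p)))
    theta0 = np.array(theta0)

    def unpack(theta):
        pos = 0
        if fit_branch_lengths:
            bl = np.exp(np.clip(theta[pos: pos + len(edges)], -14, 5))
            pos += len(edges)
        else:
            bl = None
        if fit_exchangeabilities:
            ex = np.append(np.exp(np.clip(theta[pos: pos + 5], -7, 7)), 1.0)
            pos += 5
        else:
            ex = init.exchangeabilities
        alpha = np.exp(np.clip(theta[pos], -4, 7)) if fit_alpha else init.alpha
        pos += int(fit_alpha)
        if fit_p_inv:
            p_inv = 1.0 / (1.0 + np.exp(-np.clip(theta[pos], -12, 12)))
        else:
            p_inv = init.p_inv
        params = GtrGammaParams(ex, freqs, alpha=alpha,
                                n_categories=n_categories, p_inv=p_inv)
        return bl, params

    def objective(theta):
        bl, params = unpack(theta)
        if bl is not None:
            for e, b in zip(edges, bl):
                e.length = float(b)
        return -float(gtr_gamma_site_loglik(tree, nuc_aln, params).sum())

    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-10},
    )
    bl, params = unpack(res.x)
    if bl is not None:
        for e, b in zip(edges, bl):
            e.length = float(b)
    lnl = -float(res.fun)
    return tree, params, lnl
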