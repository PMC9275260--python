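"""Substitution models: GY94-style codon model and nucleotide GTR+Γ+I.

The codon model follows Goldman & Yang (1994) as used for site-class dN/dS
inference: instantaneous rates between codons differing at one position are
proportional to the target codon frequency, multiplied by κ for transitions
and by ω for nonsynonymous changes. Stop codons are excluded from the state
space.

Scaling convention: every rate matrix handed to the likelihood or simulation
engines is normalized to one expected substitution per (codon or nucleotide)
site per unit branch length, per ω class. Branch lengths on codon trees are
therefore in expected codon substitutions within each class. See
docs/methods.md for why the per-class convention is used on both the
simulation and inference sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable
from scipy import special

from .errors import ParameterError, ValidationError

__all__ = [
    "GeneticCode",
    "CodonModelParams",
    "SiteClassDistribution",
    "GtrGammaParams",
    "gy94_rate_matrix",
    "gtr_rate_matrix",
    "discretize_beta",
    "discretize_gamma",
    "equal_codon_frequencies",
    "f3x4_frequencies",
]

_NUC = "ACGT"
_NUC_INDEX = {b: i for i, b in enumerate(_NUC)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class GeneticCode:
    """Sense-codon state space for a numbered NCBI translation table."""

    def __init__(self, code_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[code_id]
        self.code_id = code_id
        self.stop_codons = frozenset(table.stop_codons)
        self.sense_codons = tuple(
            sorted(c for c in table.forward_table if set(c) <= set(_NUC))
        )
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self.amino_acids = tuple(table.forward_table[c] for c in self.sense_codons)
        self.n_states = len(self.sense_codons)

    def __repr__(self):
        return f"GeneticCode(id={self.code_id}, n_sense={self.n_states})"


@lru_cache(maxsize=8)
def get_code(code_id: int = 1) -> GeneticCode:
    return GeneticCode(code_id)


@lru_cache(maxsize=8)
def _gy94_structure(code_id: int):
    """Precomputed masks for single-position codon changes: returns boolean
    (n, n) arrays (is_single, is_transition, is_nonsynonymous)."""
    code = get_code(code_id)
    n = code.n_states
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diff[0] in _TRANSITIONS
            nonsyn[i, j] = code.amino_acids[i] != code.amino_acids[j]
    return single, transition, nonsyn


@dataclass(frozen=True)
class CodonModelParams:
    """κ, codon frequencies π over sense codons, and the genetic code id."""

    kappa: float
    pi: np.ndarray
    code_id: int = 1

    def __post_init__(self):
        if self.kappa <= 0:
            raise ParameterError(f"kappa must be > 0, got {self.kappa}")
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        code = get_code(self.code_id)
        if pi.shape != (code.n_states,):
            raise ValidationError(
                f"pi has shape {pi.shape}, expected ({code.n_states},)"
            )
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValidationError("codon frequencies must be >= 0 and sum to 1")

    @property
    def code(self) -> GeneticCode:
        return get_code(self.code_id)


def equal_codon_frequencies(code_id: int = 1) -> np.ndarray:
    n = get_code(code_id).n_states
    return np.full(n, 1.0 / n)


def f3x4_frequencies(codon_aln, code_id: int | None = None) -> np.ndarray:
    """Empirical F3×4 codon frequencies: product of position-specific
    nucleotide frequencies, stop codons zeroed, renormalized."""
    cid = code_id if code_id is not None else getattr(codon_aln, "code_id", 1)
    code = get_code(cid)
    counts = np.zeros((3, 4))
    for row in codon_aln.rows:
        for k in range(0, len(row), 3):
            for p in range(3):
                b = row[k + p]
                if b in _NUC_INDEX:
                    counts[p, _NUC_INDEX[b]] += 1
    if counts.sum() == 0:
        raise ValidationError("alignment has no unambiguous nucleotides")
    counts += 0.5  # guard against absent bases at a position
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, _NUC_INDEX[c[0]]]
            * freqs[1, _NUC_INDEX[c[1]]]
            * freqs[2, _NUC_INDEX[c[2]]]
            for c in code.sense_codons
        ]
    )
    return pi / pi.sum()


def gy94_rate_matrix(
    params: CodonModelParams, omega: float, scaled: bool = True
) -> np.ndarray:
    """GY94 generator over sense codons.

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for single-position
    changes, 0 otherwise; diagonal set so rows sum to 0. With ``scaled`` the
    matrix is normalized so −Σ_i π_i q_ii = 1.
    """
    if omega < 0:
        raise ParameterError(f"omega must be >= 0, got {omega}")
    single, transition, nonsyn = _gy94_structure(params.code_id)
    q = np.where(single, params.pi[None, :], 0.0)
    q = q * np.where(transition, params.kappa, 1.0)
    q = q * np.where(nonsyn, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scaled:
        rate = -(params.pi * np.diag(q)).sum()
        if rate <= 0:
            raise ParameterError("degenerate model: zero expected rate")
        q = q / rate
    return q


# ------------------------------------------------------------- site classes
@dataclass(frozen=True)
class SiteClassDistribution:
    """Discrete distribution of ω across sites.

    ``omegas`` and ``weights`` define the classes; for the beta-based models
    the generating shape parameters are kept so fits can report them.
    """

    omegas: np.ndarray
    weights: np.ndarray
    name: str = "custom"
    p: float | None = None  # beta shape 1
    q: float | None = None  # beta shape 2
    p0: float | None = None  # weight of the beta component (M8)
    omega_s: float | None = None  # positive-selection class ω (M8)

    def __post_init__(self):
        om = np.asarray(self.omegas, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "omegas", om)
        object.__setattr__(self, "weights", w)
        if om.shape != w.shape or om.ndim != 1:
            raise ValidationError("omegas and weights must be 1-D and equal length")
        if np.any(om < 0):
            raise ParameterError("class omegas must be >= 0")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("class weights must be >= 0 and sum to 1")
        if self.omega_s is not None and self.omega_s < 1.0:
            raise ParameterError("omega_s must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.omegas)

    # ------------------------------------------------------------ factories
    @classmethod
    def m0(cls, omega: float) -> "SiteClassDistribution":
        return cls(np.array([omega]), np.array([1.0]), name="M0")

    @classmethod
    def m1a(cls, omega0: float, p0: float) -> "SiteClassDistribution":
        if not (0.0 <= omega0 < 1.0):
            raise ParameterError("M1a omega0 must be in [0, 1)")
        if not (0.0 <= p0 <= 1.0):
            raise ParameterError("M1a p0 must be in [0, 1]")
        return cls(np.array([omega0, 1.0]), np.array([p0, 1.0 - p0]), name="M1a")

    @classmethod
    def m7(cls, p: float, q: float, K: int = 10) -> "SiteClassDistribution":
        om = discretize_beta(p, q, K)
        return cls(om, np.full(K, 1.0 / K), name="M7", p=p, q=q)

    @classmethod
    def m8(
        cls, p: float, q: float, p0: float, omega_s: float, K: int = 10
    ) -> "SiteClassDistribution":
        if not (0.0 <= p0 <= 1.0):
            raise ParameterError("M8 p0 must be in [0, 1]")
        if omega_s < 1.0:
            raise ParameterError("M8 omega_s must be >= 1")
        om = np.append(discretize_beta(p, q, K), omega_s)
        w = np.append(np.full(K, p0 / K), 1.0 - p0)
        return cls(om, w, name="M8", p=p, q=q, p0=p0, omega_s=omega_s)


def discretize_beta(p: float, q: float, K: int = 10) -> np.ndarray:
    """Means of K equal-probability bins of Beta(p, q).

    E[X | bin] · K = K · p/(p+q) · [I(x_hi; p+1, q) − I(x_lo; p+1, q)]
    with I the regularized incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ParameterError("beta shapes must be > 0")
    if K < 1:
        raise ParameterError("K must be >= 1")
    edges = special.betaincinv(p, q, np.linspace(0.0, 1.0, K + 1))
    upper = special.betainc(p + 1.0, q, edges)
    means = K * (p / (p + q)) * np.diff(upper)
    return np.clip(means, 0.0, 1.0)


def discretize_gamma(alpha: float, K: int = 4) -> np.ndarray:
    """Means of K equal-probability bins of Gamma(α, rate α) (mean 1)."""
    if alpha <= 0:
        raise ParameterError("gamma shape must be > 0")
    if K < 1:
        raise ParameterError("K must be >= 1")
    edges = special.gammaincinv(alpha, np.linspace(0.0, 1.0, K + 1)) / alpha
    upper = special.gammainc(alpha + 1.0, edges * alpha)
    return K * np.diff(upper)


# ----------------------------------------------------------------- GTR+Γ+I
_GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


@dataclass(frozen=True)
class GtrGammaParams:
    """GTR exchangeabilities (AC, AG, AT, CG, CT, GT order), base
    frequencies (A, C, G, T), gamma shape α with K categories, and an
    invariant-site proportion."""

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "freqs", fr)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValidationError("need 6 positive exchangeabilities")
        if fr.shape != (4,) or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-8:
            raise ValidationError("base frequencies must be positive and sum to 1")
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0")
        if not (0.0 <= self.p_inv < 1.0):
            raise ParameterError("p_inv must be in [0, 1)")

    def rate_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the Γ+I mixture, scaled to overall mean 1."""
        gamma_rates = discretize_gamma(self.alpha, self.n_categories)
        if self.p_inv > 0:
            rates = np.concatenate(([0.0], gamma_rates / (1.0 - self.p_inv)))
            weights = np.concatenate(
                ([self.p_inv], np.full(self.n_categories,
                                       (1.0 - self.p_inv) / self.n_categories))
            )
        else:
            rates = gamma_rates
            weights = np.full(self.n_categories, 1.0 / self.n_categories)
        return rates, weights


def gtr_rate_matrix(params: GtrGammaParams, scaled: bool = True) -> np.ndarray:
    """GTR generator over A, C, G, T, normalized to mean rate 1."""
    q = np.zeros((4, 4))
    for (i, j), s in zip(_GTR_PAIRS, params.exchangeabilities):
        q[i, j] = s * params.freqs[j]
        q[j, i] = s * params.freqs[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    if scaled:
        rate = -(params.freqs * np.diag(q)).sum()
        q = q / rate
    return q
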