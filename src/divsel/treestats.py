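"""Node-support accounting and divergence-rate analysis.

Support: fraction of internal nodes with posterior support at or above a
threshold (default 0.95), under an explicit denominator convention, split
into terminal (within one family or genus) and deep nodes.

Rates: per-tip branch-length sums back to the origin (crown MRCA by default,
stem optionally) of the tip's Superorder, normalized per gene to the slowest
species, with a rank-rate breakpoint fit and the omnibus/post-hoc statistical
battery (Shapiro-Wilk and Levene gating, Welch ANOVA or Kruskal-Wallis on
log-transformed rates, Games-Howell or Ryan's Q post hoc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    MappingError,
    MonophylyError,
    ParameterError,
    SizeError,
    ValidationError,
)
from .io import TaxonomyMap
from .trees import Node, PhyloTree

__all__ = [
    "SupportSummary",
    "RateRecord",
    "support_summary",
    "split_deep_terminal",
    "tip_divergence_rates",
    "normalize_rates",
    "rank_rate_breakpoint",
    "rate_comparison",
    "welch_anova",
    "games_howell",
    "ryan_q",
]


# ------------------------------------------------------------------- support
@dataclass(frozen=True)
class SupportSummary:
    n_internal: int
    n_supported: int
    threshold: float = 0.95
    denominator: str = "annotated"

    def __post_init__(self):
        if self.n_supported > self.n_internal:
            raise ValidationError("more supported nodes than counted nodes")

    @property
    def supported_pct(self) -> float:
        return 100.0 * self.n_supported / self.n_internal

    @property
    def unsupported_pct(self) -> float:
        return 100.0 * (self.n_internal - self.n_supported) / self.n_internal

    @classmethod
    def from_counts(cls, n_supported: int, n_internal: int,
                    threshold: float = 0.95) -> "SupportSummary":
        """Percentage arithmetic on externally supplied count pairs (e.g.
        published node counts)."""
        if n_internal < 1:
            raise SizeError("denominator must be >= 1")
        return cls(n_internal, n_supported, threshold, denominator="given")


def support_summary(
    tree: PhyloTree,
    threshold: float = 0.95,
    denominator: str = "annotated",
    nodes: Optional[Sequence[Node]] = None,
) -> SupportSummary:
    """Count internal nodes with support >= threshold (inclusive).

    denominator: "internal" counts every internal node, "internal_minus_root"
    excludes the root, "annotated" counts only nodes carrying a support value.
    """
    if nodes is None:
        nodes = tree.internal_nodes()
    if denominator == "internal":
        counted = list(nodes)
    elif denominator == "internal_minus_root":
        counted = [n for n in nodes if n is not tree.root]
    elif denominator == "annotated":
        counted = [n for n in nodes if n.support is not None]
    else:
        raise ParameterError(f"unknown denominator convention {denominator!r}")
    if not counted:
        raise SizeError("no countable internal nodes under this convention")
    n_sup = sum(1 for n in counted if (n.support or 0.0) >= threshold)
    return SupportSummary(len(counted), n_sup, threshold, denominator)


def split_deep_terminal(
    tree: PhyloTree,
    taxonomy: TaxonomyMap,
    level: str = "family",
    threshold: float = 0.95,
    denominator: str = "annotated",
) -> tuple[Optional[SupportSummary], Optional[SupportSummary]]:
    """(deep, terminal) support summaries.

    A terminal node is an internal node whose descendant tips all share one
    label at the chosen level; every other internal node is deep. A side with
    no countable nodes is returned as None.
    """
    deep_nodes, term_nodes = [], []
    for node in tree.internal_nodes():
        tips = tree.descendant_tip_names(node)
        try:
            labels = {taxonomy.level(t, level) for t in tips}
        except KeyError as exc:
            raise MappingError(str(exc)) from None
        (term_nodes if len(labels) == 1 else deep_nodes).append(node)

    def maybe(ns):
        try:
            return support_summary(tree, threshold, denominator, nodes=ns)
        except SizeError:
            return None

    return maybe(deep_nodes), maybe(term_nodes)


# --------------------------------------------------------------------- rates
@dataclass(frozen=True)
class RateRecord:
    tip: str
    superorder: str
    order: str
    raw_rate: float
    normalized_rate: Optional[float] = None
    gene: str = ""
    valid: bool = True


def tip_divergence_rates(
    tree: PhyloTree,
    taxonomy: TaxonomyMap,
    anchor: str = "crown",
    gene: str = "",
) -> list[RateRecord]:
    """Sum of branch lengths from each tip back to the origin of its
    Superorder: the crown MRCA ("crown") or the top of the MRCA's parent
    edge ("stem"). Superorders must be monophyletic. A single-tip superorder
    has zero crown path and is flagged invalid in crown mode."""
    if anchor not in ("crown", "stem"):
        raise ParameterError("anchor must be 'crown' or 'stem'")
    groups: dict[str, list[str]] = {}
    for tip in tree.tip_names:
        try:
            so = taxonomy[tip].superorder
        except KeyError as exc:
            raise MappingError(str(exc)) from None
        groups.setdefault(so, []).append(tip)

    records = []
    for so, tips in groups.items():
        mrca = tree.mrca(tips)
        clade_tips = tree.descendant_tip_names(mrca)
        if clade_tips != set(tips):
            raise MonophylyError(
                f"superorder {so!r} is not monophyletic: clade also contains "
                f"{sorted(clade_tips - set(tips))}"
            )
        stem_extra = 0.0
        if anchor == "stem":
            if mrca.length is None:
                raise ValidationError(f"missing stem branch length above {so!r}")
            stem_extra = mrca.length
        for leaf in mrca.leaves():
            total, node = 0.0, leaf
            while node is not mrca:
                if node.length is None:
                    raise ValidationError(f"missing branch length above {leaf.name!r}")
                total += node.length
                node = node.parent
            raw = total + stem_extra
            records.append(
                RateRecord(
                    tip=leaf.name,
                    superorder=so,
                    order=taxonomy[leaf.name].order,
                    raw_rate=raw,
                    gene=gene,
                    valid=raw > 0.0,
                )
            )
    return records


def normalize_rates(
    records: Sequence[RateRecord],
) -> tuple[list[RateRecord], dict[str, float]]:
    """Divide each gene's raw rates by that gene's minimum; the dynamic range
    is max/min of the raw rates per gene. Zero or negative rates refuse to
    normalize (use stem anchoring for single-tip superorders)."""
    by_gene: dict[str, list[RateRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    out, ranges = [], {}
    for gene, recs in by_gene.items():
        raws = np.array([r.raw_rate for r in recs])
        if raws.min() <= 0:
            raise ValidationError(
                f"gene {gene!r}: non-positive raw rate; cannot normalize"
            )
        mn = raws.min()
        ranges[gene] = float(raws.max() / mn)
        for r in recs:
            out.append(
                RateRecord(r.tip, r.superorder, r.order, r.raw_rate,
                           normalized_rate=r.raw_rate / mn, gene=gene,
                           valid=r.valid)
            )
    return out, ranges


@dataclass(frozen=True)
class BreakpointFit:
    breakpoint: Optional[int]  # size of the slow segment; None if no inflection
    rss_single: float
    rss_two_segment: float
    improvement: float  # 1 - rss2/rss1
    sorted_rates: np.ndarray


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def rank_rate_breakpoint(
    records: Sequence[RateRecord],
    min_segment: int = 3,
    min_improvement: float = 0.5,
    use_normalized: bool = True,
) -> BreakpointFit:
    """Two-segment least-squares fit of the rank-rate curve.

    Rates are sorted ascending; the breakpoint is the split minimizing the
    summed residual sum of squares of two straight lines, each segment
    holding at least ``min_segment`` points. If the two-segment fit improves
    on a single line by less than ``min_improvement`` (fractional RSS
    reduction), no inflection is declared."""
    if len(records) < 2 * min_segment:
        raise SizeError(f"need at least {2 * min_segment} records")
    vals = [
        (r.normalized_rate if use_normalized and r.normalized_rate is not None
         else r.raw_rate)
        for r in records
    ]
    y = np.sort(np.asarray(vals, dtype=float))
    x = np.arange(1, len(y) + 1, dtype=float)
    rss1 = _ols_rss(x, y)
    best_k, best_rss = None, np.inf
    for k in range(min_segment, len(y) - min_segment + 1):
        rss = _ols_rss(x[:k], y[:k]) + _ols_rss(x[k:], y[k:])
        if rss < best_rss:
            best_k, best_rss = k, rss
    if rss1 <= 1e-12 * max(1.0, float(y @ y)):
        improvement = 0.0
        best_k = None
    else:
        improvement = 1.0 - best_rss / rss1
        if improvement < min_improvement:
            best_k = None
    return BreakpointFit(best_k, rss1, best_rss, improvement, y)


# ----------------------------------------------------------- rate comparison
def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df_denom, p)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    vars_ = np.array([np.var(g, ddof=1) for g in groups])
    w = ns / vars_
    mw = (w * means).sum() / w.sum()
    a = (w * (means - mw) ** 2).sum() / (k - 1)
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
    f = a / b
    df2 = (k**2 - 1.0) / (3.0 * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum())
    p = float(stats.f.sf(f, k - 1, df2))
    return float(f), float(df2), p


def games_howell(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (Welch t referred to the studentized
    range with Welch degrees of freedom)."""
    names = list(groups)
    k = len(names)
    rows = []
    for a, b in combinations(names, 2):
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        na, nb = len(xa), len(xb)
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        se2 = va / na + vb / nb
        t = (xa.mean() - xb.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = abs(t) * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group_a": a, "group_b": b, "statistic": float(t),
                     "df": float(df), "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def ryan_q(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Ryan's Q (REGWQ stepdown studentized-range test, pooled variance).

    Means are ordered; a stretch of p means is tested at
    α_p = 1 − (1 − α)^(p/k) (α_p = α for p ≥ k − 1), and a pair is declared
    different only if every enclosing stretch was rejected."""
    names = sorted(groups, key=lambda g: np.mean(groups[g]))
    k = len(names)
    ns = {g: len(groups[g]) for g in names}
    df_err = sum(ns[g] - 1 for g in names)
    mse = sum((ns[g] - 1) * np.var(groups[g], ddof=1) for g in names) / df_err
    means = {g: float(np.mean(groups[g])) for g in names}
    memo: dict[tuple[int, int], bool] = {}

    def stretch_rejected(i: int, j: int) -> bool:
        key = (i, j)
        if key not in memo:
            p = j - i + 1
            alpha_p = alpha if p >= k - 1 else 1.0 - (1.0 - alpha) ** (p / k)
            a, b = names[i], names[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(means[b] - means[a]) / se
            pval = float(stats.studentized_range.sf(q, p, df_err))
            memo[key] = pval < alpha_p
        return memo[key]

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            # a pair differs only if every stretch containing it is rejected
            sig = all(
                stretch_rejected(a, b)
                for a in range(0, i + 1)
                for b in range(j, k)
            )
            a_name, b_name = names[i], names[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a_name] + 1.0 / ns[b_name]))
            q = abs(means[b_name] - means[a_name]) / se
            p_len = j - i + 1
            pval = float(stats.studentized_range.sf(q, p_len, df_err))
            rows.append({"group_a": a_name, "group_b": b_name,
                         "statistic": float(q), "df": float(df_err),
                         "p_value": pval, "significant": bool(sig)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RateComparison:
    shapiro_p: dict
    levene_p: float
    normal: bool
    homoscedastic: bool
    path: str
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str
    posthoc: pd.DataFrame = field(repr=False)


def rate_comparison(
    groups: dict[str, Sequence[float]],
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> RateComparison:
    """The gated divergence-rate comparison.

    Shapiro-Wilk per group and Levene (mean-centered) across groups choose
    the path: normal but heteroscedastic data go to Welch's ANOVA;
    non-normal data are log-transformed and compared by Kruskal-Wallis on
    ranks; normal homoscedastic data use ordinary one-way ANOVA. Post hoc:
    Games-Howell when variances are unequal, Ryan's Q when equal."""
    if len(groups) < 2:
        raise SizeError("need at least 2 groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < min_group_size:
            raise SizeError(
                f"group {name!r} has {len(arr)} observations; need >= {min_group_size}"
            )
        if np.var(arr) == 0.0:
            raise ValidationError(
                f"group {name!r} has zero variance; comparison is degenerate"
            )
        arrays[name] = arr
    shapiro_p = {
        name: float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 1.0
        for name, a in arrays.items()
    }
    normal = all(p > alpha for p in shapiro_p.values())
    levene_p = float(stats.levene(*arrays.values(), center="mean").pvalue)
    homoscedastic = levene_p > alpha

    vals = list(arrays.values())
    if normal and not homoscedastic:
        f, df2, p = welch_anova(vals)
        omnibus = ("Welch", f, p)
        path = "normal+heteroscedastic -> Welch ANOVA"
    elif normal and homoscedastic:
        f, p = stats.f_oneway(*vals)
        omnibus = ("ANOVA", float(f), float(p))
        path = "normal+homoscedastic -> one-way ANOVA"
    else:
        if any(np.any(a <= 0) for a in vals):
            raise ValidationError("log transform requires positive rates")
        logged = [np.log(a) for a in vals]
        h, p = stats.kruskal(*logged)
        omnibus = ("Kruskal-Wallis", float(h), float(p))
        path = "non-normal -> log transform -> Kruskal-Wallis"

    if homoscedastic:
        posthoc_test = "RyanQ"
        posthoc = ryan_q(arrays, alpha)
    else:
        posthoc_test = "Games-Howell"
        posthoc = games_howell(arrays, alpha)
    return RateComparison(
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        normal=normal,
        homoscedastic=homoscedastic,
        path=path,
        omnibus_test=omnibus[0],
        omnibus_statistic=omnibus[1],
        omnibus_p=omnibus[2],
        posthoc_test=posthoc_test,
        posthoc=posthoc,
    )
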