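"""Candidate-topology search and topology congruence tests.

Parsimony: Fitch lengths with NNI hill-climbing from random-addition starting
trees, retaining every equally-most-parsimonious topology found (ties are
real candidates, not noise). Congruence: SH and AU tests on per-site
log-likelihoods with RELL bootstrapping — replicates resample site
log-likelihoods rather than re-optimizing — and Bonferroni correction across
the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AuFitError,
    MappingError,
    ParameterError,
    PruningError,
    SizeError,
)
from .io import NucAlignment
from .likelihood import SiteLnLMatrix
from .trees import Node, PhyloTree

__all__ = [
    "fitch_score",
    "all_topologies",
    "parsimony_candidates",
    "prune_to_shared_taxa",
    "rell_bootstrap",
    "sh_test",
    "au_test",
    "bonferroni",
    "TopologyTestResult",
    "topology_test_suite",
]

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15, "-": 15}


# ----------------------------------------------------------------- parsimony
def _tip_bitsets(aln: NucAlignment) -> dict[str, np.ndarray]:
    out = {}
    for name, row in zip(aln.taxa, aln.rows):
        out[name] = np.array([_BIT[c] for c in row], dtype=np.uint8)
    return out


def fitch_score(tree: PhyloTree, aln: NucAlignment,
                _bitsets: Optional[dict] = None) -> int:
    """Minimum number of state changes (unordered states, gaps missing)."""
    tips = _bitsets if _bitsets is not None else _tip_bitsets(aln)
    missing = set(tree.tip_names) - set(tips)
    if missing:
        raise MappingError(f"tree tips absent from alignment: {sorted(missing)}")
    n_sites = len(next(iter(tips.values())))
    changes = np.zeros(n_sites, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}

    def tip_set(node: Node) -> np.ndarray:
        return tips[node.name]

    for node in tree.postorder():
        if node.is_leaf:
            continue
        acc = None
        for child in node.children:
            s = tip_set(child) if child.is_leaf else sets.pop(id(child))
            if acc is None:
                acc = s.copy()
                continue
            inter = acc & s
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | s, inter)
        sets[id(node)] = acc
    return int(changes.sum())


def _rooted_from_taxa(taxa: Sequence[str]) -> PhyloTree:
    """Canonical starting shape: tip0 plus a cherry of tip1, tip2, all
    hanging off the root (the rooted stand-in for the unrooted topology)."""
    root = Node()
    root.add_child(Node(name=taxa[0]))
    x = root.add_child(Node())
    x.add_child(Node(name=taxa[1]))
    x.add_child(Node(name=taxa[2]))
    return PhyloTree(root, validate=False)


def _insertable_edges(tree: PhyloTree) -> list[Node]:
    """Nodes whose parent edge is a distinct unrooted edge (the first tip's
    edge coincides with the edge above the top subtree node)."""
    first_tip = tree.root.children[0]
    return [
        n for n in tree.root.postorder()
        if n.parent is not None and n is not first_tip
    ]


def _insert_taxon(tree: PhyloTree, edge_node: Node, name: str) -> None:
    parent = edge_node.parent
    joint = Node()
    parent.children[parent.children.index(edge_node)] = joint
    joint.parent = parent
    joint.add_child(edge_node)
    joint.add_child(Node(name=name))


def all_topologies(taxa: Sequence[str]) -> list[PhyloTree]:
    """Every unrooted binary topology on the taxa (1·3·5···(2n−5) trees),
    via exhaustive stepwise addition. Intended for small n."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise SizeError("need at least 3 taxa")
    trees = [_rooted_from_taxa(taxa)]
    for name in taxa[3:]:
        nxt = []
        for t in trees:
            for i in range(len(_insertable_edges(t))):
                dup = t.copy()
                _insert_taxon(dup, _insertable_edges(dup)[i], name)
                nxt.append(dup)
        trees = nxt
    return trees


def _nni_neighbors(tree: PhyloTree) -> Iterable[PhyloTree]:
    """All NNI rearrangements across internal edges of the unrooted topology."""
    nodes = [n for n in tree.root.postorder() if n.parent is not None]
    for idx, v in enumerate(nodes):
        # skip leaf edges: tips, and the top node whose edge pairs with the
        # first tip in this rooted representation
        if v.is_leaf or v.parent is tree.root:
            continue
        for sib_pos, sib in enumerate(v.parent.children):
            if sib is v:
                continue
            for child_pos in range(len(v.children)):
                dup = tree.copy()
                dnodes = [n for n in dup.root.postorder() if n.parent is not None]
                dv = dnodes[idx]
                dsib = dv.parent.children[sib_pos]
                dchild = dv.children[child_pos]
                dv.parent.children[sib_pos] = dchild
                dchild.parent = dv.parent
                dv.children[child_pos] = dsib
                dsib.parent = dv
                yield dup
            break  # binary: exactly one sibling


def _random_addition_tree(taxa: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    order = list(rng.permutation(list(taxa)))
    tree = _rooted_from_taxa(order[:3])
    for name in order[3:]:
        edges = _insertable_edges(tree)
        _insert_taxon(tree, edges[int(rng.integers(len(edges)))], name)
    return tree


def parsimony_candidates(
    aln: NucAlignment,
    n_starts: int = 10,
    seed: int = 0,
    max_plateau: int = 200,
) -> tuple[list[PhyloTree], int]:
    """NNI hill-climbing from random-addition trees; returns all distinct
    topologies attaining the best Fitch score found, and that score.

    Equal-score NNI neighbors of optima are explored (bounded plateau walk)
    so ties — equally most-parsimonious candidate trees — are collected.
    """
    if aln.n_taxa < 4:
        raise SizeError("parsimony search needs at least 4 taxa")
    bits = _tip_bitsets(aln)
    rng = np.random.default_rng(seed)
    best_score = None
    optima: dict[frozenset, tuple[PhyloTree, int]] = {}

    def climb(tree: PhyloTree) -> tuple[PhyloTree, int]:
        score = fitch_score(tree, aln, bits)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(tree):
                s = fitch_score(nb, aln, bits)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
        return tree, score

    for _ in range(max(1, n_starts)):
        tree, score = climb(_random_addition_tree(aln.taxa, rng))
        if best_score is None or score < best_score:
            best_score = score
            optima = {}
        if score == best_score:
            optima.setdefault(tree.splits(), (tree, score))

    # plateau walk: equal-score neighbors are co-optimal candidates
    frontier = list(optima.values())
    visited = set(optima)
    while frontier and len(optima) < max_plateau:
        tree, score = frontier.pop()
        for nb in _nni_neighbors(tree):
            key = nb.splits()
            if key in visited:
                continue
            s = fitch_score(nb, aln, bits)
            if s == best_score:
                visited.add(key)
                optima[key] = (nb, s)
                frontier.append((nb, s))
    return [t for t, _ in optima.values()], int(best_score)


# ------------------------------------------------------------------- pruning
def prune_to_shared_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced subtree on the shared taxa: degree-2 nodes suppressed with
    branch lengths summed, polytomies preserved."""
    keep = set(taxa) & set(tree.tip_names)
    if len(keep) < 3:
        raise PruningError(f"only {len(keep)} shared taxa; need >= 3")
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.root.postorder()):
            if node.is_leaf and node.name not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif not node.is_leaf and not node.children and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
    tree.suppress_unifurcations()
    return PhyloTree(tree.root)


# ---------------------------------------------------------------------- RELL
def _rell_totals(values: np.ndarray, n_draw: int, B: int,
                 rng: np.random.Generator, chunk: int = 1000) -> np.ndarray:
    """(n_trees, B) bootstrap totals; the same resampled sites are applied to
    every tree (RELL)."""
    n_trees, n_sites = values.shape
    out = np.empty((n_trees, B))
    p = np.full(n_sites, 1.0 / n_sites)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        counts = rng.multinomial(n_draw, p, size=b)  # (b, S)
        out[:, done: done + b] = values @ counts.T
        done += b
    return out


def rell_bootstrap(site_lnl: SiteLnLMatrix, B: int = 10_000,
                   seed: int = 0) -> np.ndarray:
    """RELL bootstrap totals, shape (n_trees, B)."""
    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = np.random.default_rng(seed)
    return _rell_totals(site_lnl.values, site_lnl.n_sites, B, rng)


def sh_test(site_lnl: SiteLnLMatrix, B: int = 10_000, seed: int = 0) -> np.ndarray:
    """One-tailed Shimodaira–Hasegawa p-value per tree.

    Replicates are centered per tree; p_i is the fraction of replicates in
    which the centered best-minus-i difference reaches the observed one.
    """
    if site_lnl.n_trees < 2:
        import warnings

        warnings.warn("SH test with a single tree is degenerate; p = 1")
        return np.ones(site_lnl.n_trees)
    totals = site_lnl.total_lnls()
    delta_obs = totals.max() - totals
    boot = rell_bootstrap(site_lnl, B, seed)
    centered = boot - boot.mean(axis=1, keepdims=True)
    d_rep = centered.max(axis=0, keepdims=True) - centered  # (T, B)
    return (d_rep >= delta_obs[:, None]).mean(axis=1)


_DEFAULT_SCALES = tuple(np.linspace(0.5, 1.4, 10))


def au_test(
    site_lnl: SiteLnLMatrix,
    scales: Sequence[float] = _DEFAULT_SCALES,
    B_per_scale: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Approximately Unbiased test p-value per tree (multiscale RELL).

    For each relative sample size r, ⌈rn⌉ sites are resampled and the
    bootstrap proportion BP_i(r) of replicates where tree i is best recorded;
    Φ⁻¹(1 − BP) is regressed on d√r + c/√r by weighted least squares and
    p_AU = 1 − Φ(d − c). BP values of 0/1 are clamped to 1/(2B); trees never
    (or always) best at every scale get p = 0 (or 1) directly.
    """
    if site_lnl.n_trees < 2:
        raise SizeError("AU test needs at least 2 trees")
    scales = np.asarray(sorted(scales), dtype=float)
    if len(scales) < 3:
        raise AuFitError("need at least 3 bootstrap scales")
    rng = np.random.default_rng(seed)
    n = site_lnl.n_sites
    T = site_lnl.n_trees
    bp = np.empty((T, len(scales)))
    for s_idx, r in enumerate(scales):
        n_draw = max(1, int(np.ceil(r * n)))
        totals = _rell_totals(site_lnl.values, n_draw, B_per_scale, rng)
        best = totals.argmax(axis=0)
        bp[:, s_idx] = np.bincount(best, minlength=T) / B_per_scale

    eps = 1.0 / (2.0 * B_per_scale)
    p_au = np.empty(T)
    sqrt_r = np.sqrt(scales)
    for i in range(T):
        # scales with BP exactly 0 or 1 carry no information about the
        # signed-distance geometry and are dropped from the fit
        usable = (bp[i] > 0.0) & (bp[i] < 1.0)
        if usable.sum() < 3:
            # the tree is (almost) never or (almost) always best: decided
            p_au[i] = 0.0 if bp[i].mean() < 0.5 else 1.0
            continue
        bpc = np.clip(bp[i, usable], eps, 1.0 - eps)
        r = sqrt_r[usable]
        X = np.column_stack([r, 1.0 / r])
        z = stats.norm.ppf(1.0 - bpc)
        w = B_per_scale * stats.norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d, c = coef
        p_au[i] = float(stats.norm.sf(d - c))
    return p_au


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha/m."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class TopologyTestResult:
    labels: tuple[str, ...]
    lnls: np.ndarray
    delta_lnl: np.ndarray
    p_sh: np.ndarray
    p_au: np.ndarray
    alpha: float
    alpha_adjusted: float
    rejected_sh: np.ndarray
    rejected_au: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tree": self.labels,
                "lnL": self.lnls,
                "delta_lnL": self.delta_lnl,
                "p_SH": self.p_sh,
                "p_AU": self.p_au,
                "alpha_adjusted": self.alpha_adjusted,
                "rejected_SH": self.rejected_sh,
                "rejected_AU": self.rejected_au,
            }
        )


def topology_test_suite(
    site_lnl: SiteLnLMatrix,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    m: Optional[int] = None,
) -> TopologyTestResult:
    """SH + AU tests with Bonferroni-adjusted decisions over the candidates."""
    lnls = site_lnl.total_lnls()
    delta = lnls.max() - lnls
    p_sh = sh_test(site_lnl, B=B, seed=seed)
    p_au = au_test(site_lnl, B_per_scale=B, seed=seed + 1)
    m = m if m is not None else site_lnl.n_trees
    a_adj = bonferroni(alpha, m)
    return TopologyTestResult(
        labels=tuple(site_lnl.labels),
        lnls=lnls,
        delta_lnl=delta,
        p_sh=p_sh,
        p_au=p_au,
        alpha=alpha,
        alpha_adjusted=a_adj,
        rejected_sh=p_sh < a_adj,
        rejected_au=p_au < a_adj,
    )
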