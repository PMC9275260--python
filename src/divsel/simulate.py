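"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions the analyses are built for: a
clade-labelled ultrametric species tree (Superorder/Order/Family structure),
codon alignments evolved under site-class mixtures of the GY94 model,
support annotations in "well-resolved" vs "poorly-resolved" regimes,
clade-specific rate multipliers producing divergence-rate heterogeneity, and
stylized gene-locus tables for the intact / deleted / Zan-like synteny
scenarios. Every generator is a pure function of (parameters, seed); each
operation draws from an independent stream derived from (seed, operation
tag) so stages are reproducible in isolation.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import yaml

from .errors import ParameterError
from .io import CodonAlignment, LocusRecord, LocusTable, NucAlignment, TaxonomyMap, TaxonRanks
from .likelihood import ReversibleModel
from .models import (
    CodonModelParams,
    GtrGammaParams,
    SiteClassDistribution,
    get_code,
    gtr_rate_matrix,
    gy94_rate_matrix,
)
from .synteny import DomainArchitecture
from .trees import Node, PhyloTree

__all__ = [
    "CladeSpec",
    "SimulationTruth",
    "SupportRegime",
    "simulate_labeled_tree",
    "simulate_codon_alignment",
    "simulate_nuc_alignment",
    "simulate_support_annotations",
    "simulate_locus_table",
    "write_scenario_config",
]

_STREAM_TAGS = {"tree": 11, "codon": 12, "nuc": 13, "support": 14, "locus": 15}


def _stream(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAM_TAGS[tag])))


# ------------------------------------------------------------------- truth
@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded alongside a simulated alignment."""

    seed: int
    model: str
    kappa: float
    class_omegas: tuple[float, ...]
    class_weights: tuple[float, ...]
    site_classes: np.ndarray
    tree_newick: str
    rate_multipliers: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        sc = np.asarray(self.site_classes)
        object.__setattr__(self, "site_classes", sc)
        if sc.size and (sc.min() < 0 or sc.max() >= len(self.class_omegas)):
            raise ParameterError("site class index outside the stated class count")

    def to_config_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "model": self.model,
            "kappa": float(self.kappa),
            "class_omegas": [float(x) for x in self.class_omegas],
            "class_weights": [float(x) for x in self.class_weights],
            "rate_multipliers": {k: float(v) for k, v in self.rate_multipliers.items()},
            "tree": self.tree_newick,
            **{k: v for k, v in self.extra.items()},
        }


def write_scenario_config(truth: "SimulationTruth | dict", path) -> None:
    d = truth.to_config_dict() if isinstance(truth, SimulationTruth) else dict(truth)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


# ------------------------------------------------------------------- trees
@dataclass(frozen=True)
class CladeSpec:
    """A monophyletic Superorder/Order with family subdivisions.

    ``families`` maps family name -> number of tips.
    """

    superorder: str
    order: str
    families: tuple[tuple[str, int], ...]

    @property
    def n_tips(self) -> int:
        return sum(n for _, n in self.families)


def _bd_node(n: int, birth: float, death: float, rng: np.random.Generator) -> Node:
    """Ultrametric birth-death subtree with n extant tips (unlabelled)."""
    if n == 1:
        return Node(length=0.0)
    if n == 2:
        # a cherry's shape carries no information; heights are rescaled later
        root = Node(length=0.0)
        root.add_child(Node(length=1.0))
        root.add_child(Node(length=1.0))
        return root
    pyrng = _pyrandom.Random(int(rng.integers(0, 2**31 - 1)))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n, rng=pyrng,
        repeat_until_success=True,
    )

    def convert(dnode) -> Node:
        node = Node(length=dnode.edge.length or 0.0)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    # drop any unifurcations dendropy may leave at the root
    while len(root.children) == 1:
        root = root.children[0]
        root.length = 0.0
    return root


def _depth(node: Node) -> float:
    if node.is_leaf:
        return 0.0
    return max((c.length or 0.0) + _depth(c) for c in node.children)


def _scale_to_height(node: Node, height: float) -> None:
    d = _depth(node)
    if d <= 0:
        if not node.is_leaf:
            raise ParameterError("degenerate zero-depth subtree")
        return
    f = height / d
    for n in node.postorder():
        if n is not node and n.length is not None:
            n.length *= f


def _assemble(children: Sequence[Node], child_height: float, crown_height: float,
              birth: float, death: float, rng: np.random.Generator) -> Node:
    """Join ultrametric subtrees of common height under an ultrametric
    backbone so the result has height ``crown_height``."""
    if len(children) == 1:
        child = children[0]
        child.length = (child.length or 0.0) + (crown_height - child_height)
        return child
    backbone = _bd_node(len(children), birth, death, rng)
    _scale_to_height(backbone, crown_height - child_height)
    slots = backbone.leaves()
    for slot, sub in zip(slots, children):
        sub.length = (sub.length or 0.0) + (slot.length or 0.0)
        parent = slot.parent
        parent.children[parent.children.index(slot)] = sub
        sub.parent = parent
    return backbone


def simulate_labeled_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    clade_spec: Optional[Sequence[CladeSpec]] = None,
    rate_multipliers: Optional[dict] = None,
    seed: int = 0,
    tree_height: float = 0.5,
    family_height_frac: float = 0.25,
    clade_height_frac: float = 0.6,
    tip_rate_jitter: float = 0.0,
) -> tuple[PhyloTree, TaxonomyMap]:
    """Rooted ultrametric tree with labelled monophyletic clades.

    Families are crowns at ``family_height_frac`` of the total height, clades
    (Superorders) at ``clade_height_frac``, the root at 1. ``rate_multipliers``
    maps a superorder (or family) name to a factor applied to every branch
    inside that group's crown, producing divergence-rate heterogeneity; the
    tree is ultrametric before multipliers are applied. ``tip_rate_jitter``
    adds lognormal (sigma = jitter) rate variation to terminal branches,
    emulating lineage-specific rate noise.
    """
    if n_tips < 3:
        raise ParameterError("n_tips must be >= 3")
    if not (birth_rate > death_rate >= 0):
        raise ParameterError("need birth_rate > death_rate >= 0")
    if clade_spec is None:
        clade_spec = [CladeSpec("SO1", "O1", (("F1", n_tips),))]
    total = sum(c.n_tips for c in clade_spec)
    if total != n_tips:
        raise ParameterError(
            f"clade_spec assigns {total} tips but n_tips={n_tips}"
        )
    if any(n < 1 for c in clade_spec for _, n in c.families):
        raise ParameterError("every family needs at least one tip")

    rng = _stream(seed, "tree")
    h_fam = tree_height * family_height_frac
    h_clade = tree_height * clade_height_frac
    taxonomy = {}
    clade_roots = []
    for clade in clade_spec:
        fam_roots = []
        for fam, n in clade.families:
            sub = _bd_node(n, birth_rate, death_rate, rng)
            if not sub.is_leaf:
                _scale_to_height(sub, h_fam)
            else:
                sub.length = 0.0
            for i, leaf in enumerate(sub.leaves()):
                leaf.name = f"{clade.order}_{fam}_t{len(taxonomy) + 1}"
                taxonomy[leaf.name] = TaxonRanks(
                    clade.superorder, clade.order, fam, leaf.name
                )
            if sub.is_leaf:
                # single-tip family: pad the stem so the tip sits at depth 0
                sub.length = h_fam
            fam_roots.append(sub)
        clade_roots.append(
            _assemble(fam_roots, h_fam, h_clade, birth_rate, death_rate, rng)
        )
    root = _assemble(clade_roots, h_clade, tree_height, birth_rate, death_rate, rng)
    root.length = None
    tree = PhyloTree(root)

    if tip_rate_jitter > 0:
        for leaf in tree.tips():
            leaf.length *= float(rng.lognormal(0.0, tip_rate_jitter))

    multipliers = dict(rate_multipliers or {})
    if multipliers:
        known = {c.superorder for c in clade_spec} | {c.order for c in clade_spec} | {
            f for c in clade_spec for f, _ in c.families
        }
        unknown = set(multipliers) - known
        if unknown:
            raise ParameterError(f"rate multipliers for unknown groups: {sorted(unknown)}")
        for group, m in multipliers.items():
            tips = [t for t, r in taxonomy.items()
                    if group in (r.superorder, r.order, r.family)]
            if len(tips) < 2:
                continue
            mrca = tree.mrca(tips)
            for node in mrca.postorder():
                if node is not mrca and node.length is not None:
                    node.length *= m
    return tree, TaxonomyMap(taxonomy)


# -------------------------------------------------------------- sequences
def _evolve_states(tree: PhyloTree, model: ReversibleModel, n_sites: int,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate site states down the tree; returns tip name -> states."""
    n = model.n_states
    cum_pi = np.cumsum(model.pi)
    states = {id(tree.root): np.searchsorted(cum_pi, rng.random(n_sites))}
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = model.transition(node.length)
        cum = np.cumsum(P, axis=1)
        parent_states = states[id(node.parent)]
        u = rng.random(n_sites)
        st = (u[:, None] > cum[parent_states]).sum(axis=1)
        st = np.minimum(st, n - 1)
        if node.is_leaf:
            out[node.name] = st
        else:
            states[id(node)] = st
    return out


def simulate_codon_alignment(
    tree: PhyloTree,
    classes: SiteClassDistribution,
    params: CodonModelParams,
    n_codons: int,
    seed: int = 0,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve codons down the tree under a site-class GY94 mixture.

    Each site draws an ω class from the mixture and evolves under that
    class's normalized rate matrix; branch lengths are expected substitutions
    per codon site. The returned truth records the class index of every site.
    """
    if n_codons < 1:
        raise ParameterError("n_codons must be >= 1")
    rng = _stream(seed, "codon")
    site_class = rng.choice(classes.n_classes, size=n_codons, p=classes.weights)
    code = get_code(params.code_id)
    tip_states = {name: np.empty(n_codons, dtype=int) for name in tree.tip_names}
    for k in range(classes.n_classes):
        idx = np.flatnonzero(site_class == k)
        if idx.size == 0:
            continue
        model = ReversibleModel(
            gy94_rate_matrix(params, float(classes.omegas[k])), params.pi
        )
        sub = _evolve_states(tree, model, idx.size, rng)
        for name, st in sub.items():
            tip_states[name][idx] = st
    codons = np.array(code.sense_codons)
    rows = tuple("".join(codons[tip_states[name]]) for name in tree.tip_names)
    aln = CodonAlignment(tuple(tree.tip_names), rows, code_id=params.code_id)
    truth = SimulationTruth(
        seed=seed,
        model=classes.name,
        kappa=params.kappa,
        class_omegas=tuple(float(x) for x in classes.omegas),
        class_weights=tuple(float(x) for x in classes.weights),
        site_classes=site_class,
        tree_newick=tree.to_newick(),
        extra={
            k: float(v)
            for k, v in (("p", classes.p), ("q", classes.q),
                         ("p0", classes.p0), ("omega_s", classes.omega_s))
            if v is not None
        },
    )
    return aln, truth


def simulate_nuc_alignment(
    tree: PhyloTree,
    params: GtrGammaParams,
    n_sites: int,
    seed: int = 0,
) -> tuple[NucAlignment, SimulationTruth]:
    """Evolve nucleotides down the tree under GTR+Γ+I."""
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    rng = _stream(seed, "nuc")
    rates, weights = params.rate_classes()
    site_class = rng.choice(len(rates), size=n_sites, p=weights)
    model = ReversibleModel(gtr_rate_matrix(params), params.freqs)
    tip_states = {name: np.empty(n_sites, dtype=int) for name in tree.tip_names}
    base = np.array(list("ACGT"))
    for k, r in enumerate(rates):
        idx = np.flatnonzero(site_class == k)
        if idx.size == 0:
            continue
        if r == 0.0:
            cum = np.cumsum(params.freqs)
            st = np.searchsorted(cum, rng.random(idx.size))
            for name in tree.tip_names:
                tip_states[name][idx] = st
            continue
        scaled = ReversibleModel(gtr_rate_matrix(params) * float(r), params.freqs)
        sub = _evolve_states(tree, scaled, idx.size, rng)
        for name, st in sub.items():
            tip_states[name][idx] = st
    rows = tuple("".join(base[tip_states[name]]) for name in tree.tip_names)
    aln = NucAlignment(tuple(tree.tip_names), rows)
    truth = SimulationTruth(
        seed=seed, model="GTR+G+I", kappa=float("nan"),
        class_omegas=tuple(float(r) for r in rates),
        class_weights=tuple(float(w) for w in weights),
        site_classes=site_class, tree_newick=tree.to_newick(),
        extra={"alpha": float(params.alpha), "p_inv": float(params.p_inv)},
    )
    return aln, truth


# ---------------------------------------------------------------- supports
@dataclass(frozen=True)
class SupportRegime:
    """Support distribution for internal nodes: Beta(a, b), or a point mass;
    deep nodes (not confined to one family) may use a penalized variant."""

    a: float = 50.0
    b: float = 1.0
    deep_a: Optional[float] = None
    deep_b: Optional[float] = None
    point_mass: Optional[float] = None
    deep_point_mass: Optional[float] = None

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ParameterError("beta parameters must be > 0")
        if (self.deep_a is None) != (self.deep_b is None):
            raise ParameterError("deep_a and deep_b must be given together")


REGIMES = {
    "resolved": SupportRegime(a=50.0, b=1.0),
    "unresolved": SupportRegime(a=14.0, b=2.0, deep_a=2.0, deep_b=2.0),
}


def simulate_support_annotations(
    tree: PhyloTree,
    regime: "str | SupportRegime" = "resolved",
    seed: int = 0,
    taxonomy: Optional[TaxonomyMap] = None,
    level: str = "family",
) -> PhyloTree:
    """Assign supports to every internal node except the root.

    Deep nodes (descendant tips spanning more than one ``level`` group) draw
    from the regime's penalized distribution when one is given; that requires
    a taxonomy.
    """
    params = REGIMES[regime] if isinstance(regime, str) else regime
    rng = _stream(seed, "support")
    tree = tree.copy()
    deep_nodes: set[int] = set()
    if taxonomy is not None:
        for node in tree.internal_nodes(exclude_root=True):
            labels = {taxonomy.level(t, level)
                      for t in tree.descendant_tip_names(node)}
            if len(labels) > 1:
                deep_nodes.add(id(node))
    elif params.deep_a is not None or params.deep_point_mass is not None:
        raise ParameterError("deep-node penalty requires a taxonomy")
    for node in tree.internal_nodes(exclude_root=True):
        deep = id(node) in deep_nodes
        pm = params.deep_point_mass if (deep and params.deep_point_mass is not None) \
            else params.point_mass
        if pm is not None:
            node.support = float(pm)
            continue
        a, b = params.a, params.b
        if deep and params.deep_a is not None:
            a, b = params.deep_a, params.deep_b
        node.support = float(rng.beta(a, b))
    return tree


# -------------------------------------------------------------- locus tables
# Stylized AchE–Tfr2 locus (synthetic): 12 genes in the intact scenario with
# a >100 kb candidate between Ephb4 and Epo. Gene order and the unlisted
# residents are stylized; only gene count, flanking anchors, the 30 kb
# deleted-scenario gap, and the candidate size reflect the modelled locus.
_LOCUS_GENES = [
    # (gene, length bp, strand)
    ("AchE", 6000, "+"),
    ("Srrt", 10000, "-"),
    ("Actl6b", 12000, "+"),
    ("Gnb2", 5000, "-"),
    ("Ephb4", 25000, "+"),
    ("CANDIDATE", 105000, "+"),
    ("Epo", 3000, "+"),
    ("Gigyf1", 30000, "-"),
    ("Pop7", 2000, "+"),
    ("Ufsp1", 4000, "+"),
    ("Slc12a9", 8000, "-"),
    ("Tfr2", 20000, "+"),
]
_GAP = 3000
_ZAN_ARCH = DomainArchitecture(("MAM", "MAM", "MUCIN", "VWD", "VWD", "VWD", "VWD", "VWD"))
_ZANL_ARCH = DomainArchitecture(("MUCIN",) + ("VWD",) * 10)

SCENARIOS = ("zan_intact", "zan_deleted", "zanl_no_mam", "shuffled_order")


def simulate_locus_table(
    scenario: str, seed: int = 0, chrom: str = "chrA"
) -> tuple[LocusTable, Optional[DomainArchitecture]]:
    """Locus table + candidate domain architecture for a named scenario.

    zan_intact: 12 genes, >100 kb candidate ("Zan") between Ephb4 and Epo.
    zan_deleted: 11 genes, Ephb4–Epo intergenic gap exactly 30 kb.
    zanl_no_mam: candidate ("ZanL") lacking MAM, doubled full-VWD count.
    shuffled_order: intact gene content, seed-dependent order/orientation.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = _stream(seed, "locus")
    genes = []
    for name, length, strand in _LOCUS_GENES:
        if name == "CANDIDATE":
            if scenario == "zan_deleted":
                continue
            if scenario == "zanl_no_mam":
                genes.append(("ZanL", 80000, strand))
            else:
                genes.append(("Zan", length, strand))
        else:
            genes.append((name, length, strand))

    if scenario == "shuffled_order":
        order = rng.permutation(len(genes))
        genes = [genes[i] for i in order]
        genes = [
            (n, ln, "+" if rng.random() < 0.5 else "-") for n, ln, _ in genes
        ]

    records, pos = [], 0
    prev = None
    for name, length, strand in genes:
        if prev == "Ephb4" and name == "Epo" and scenario == "zan_deleted":
            pos += 30000 - _GAP  # paper-scale 30 kb intergenic gap
        records.append(LocusRecord(name, chrom, pos, pos + length, strand))
        pos += length + _GAP
        prev = name
    table = LocusTable(records)
    arch = {
        "zan_intact": _ZAN_ARCH,
        "shuffled_order": _ZAN_ARCH,
        "zanl_no_mam": _ZANL_ARCH,
        "zan_deleted": None,
    }[scenario]
    return table, arch
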