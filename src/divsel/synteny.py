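"""Rule-based authentication of candidate zonadhesin (Zan) loci.

Two criteria separate authentic Zan from Zan-like (ZanL) genes and from
absence: (1) protein domain architecture — MAM domain(s), then a mucin
domain, then tandem VWD domains — and (2) shared synteny (gene content,
order, orientation) across the locus between the Ephb4 and Epo anchors.
Synteny is scored gradually: content as the shared fraction of the reference
gene set, order as the longest-common-subsequence fraction of the shared
genes, orientation as the fraction of shared genes with matching relative
strand after fixing the majority orientation, so progressively decayed
synteny (reptile and fish ZanL loci) yields progressively lower scores.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AnchorError, ValidationError
from .io import LocusRecord, LocusTable

__all__ = [
    "DomainArchitecture",
    "SyntenyScores",
    "LocusClassification",
    "DEFAULT_THRESHOLDS",
    "synteny_scores",
    "flank_gap",
    "domain_verdict",
    "classify_locus",
]

_DOMAIN_LABELS = frozenset({"MAM", "MUCIN", "VWD", "VWD_PARTIAL"})


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered protein domain labels (N- to C-terminal)."""

    domains: tuple[str, ...]

    def __post_init__(self):
        bad = set(self.domains) - _DOMAIN_LABELS
        if bad:
            raise ValidationError(f"unknown domain labels {sorted(bad)}")

    def __iter__(self):
        return iter(self.domains)

    def __len__(self):
        return len(self.domains)


@dataclass(frozen=True)
class SyntenyScores:
    content: float
    order: float
    orientation: float


@dataclass(frozen=True)
class LocusClassification:
    label: str  # ZAN | ZANL | ABSENT
    scores: SyntenyScores
    flank_gap_bp: int
    candidate_genes: tuple[str, ...]
    domain_verdict: str
    notes: str = ""


@dataclass(frozen=True)
class Thresholds:
    min_content: float = 0.8
    min_order: float = 0.8
    min_candidate_length: int = 100_000


DEFAULT_THRESHOLDS = Thresholds()


def _lcs_length(a: list, b: list) -> int:
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[n]


def synteny_scores(
    query: LocusTable, reference: LocusTable, reference_gene_set=None
) -> SyntenyScores:
    """(content, order, orientation) conservation scores in [0, 1].

    Scores are invariant to reading the query locus from the other strand
    (whole-table reversal with all strands flipped)."""
    ref_set = set(reference_gene_set) if reference_gene_set else set(reference.genes())
    if not ref_set:
        raise ValidationError("reference gene set is empty")
    shared = [g for g in reference.genes() if g in ref_set and g in query]
    content = len(shared) / len(ref_set)
    if not shared:
        return SyntenyScores(0.0, 0.0, 0.0)
    ref_order = [g for g in reference.genes() if g in shared]
    qry_order = [g for g in query.genes() if g in shared]
    lcs = max(_lcs_length(ref_order, qry_order),
              _lcs_length(ref_order, qry_order[::-1]))
    order = lcs / len(shared)
    # orientation relative to the majority: strand agreement pattern
    agree = [int(query[g].strand == reference[g].strand) for g in shared]
    n_agree = sum(agree)
    orientation = max(n_agree, len(agree) - n_agree) / len(agree)
    return SyntenyScores(content, order, orientation)


def flank_gap(
    query: LocusTable, left: str = "Ephb4", right: str = "Epo"
) -> tuple[int, tuple[LocusRecord, ...]]:
    """Intergenic span between the two anchors and the genes strictly inside.

    Anchor order on the chromosome does not matter; both must be present on
    the same chromosome."""
    for anchor in (left, right):
        if anchor not in query:
            raise AnchorError(f"anchor gene {anchor!r} absent from locus table")
    a, b = query[left], query[right]
    if a.chrom != b.chrom:
        raise AnchorError(f"anchors {left!r} and {right!r} on different chromosomes")
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    gap = max(0, hi.start - lo.end)
    inside = tuple(
        r for r in query
        if r.chrom == a.chrom and r.start >= lo.end and r.end <= hi.start
    )
    return gap, inside


def domain_verdict(arch: "DomainArchitecture | None") -> str:
    """ZAN_PATTERN, ZANL_PATTERN, or NONE.

    ZAN_PATTERN: at least one MAM before at least one MUCIN before >= 2
    consecutive full VWD domains. ZANL_PATTERN: mucin and tandem VWD present
    without the ordered MAM-first pattern (e.g. the platypus architecture
    with no MAM and doubled VWD count).
    """
    if arch is None or len(arch) == 0:
        return "NONE"
    doms = list(arch)

    def first_tandem_vwd_after(pos: int) -> bool:
        run = 0
        for d in doms[pos:]:
            run = run + 1 if d == "VWD" else 0
            if run >= 2:
                return True
        return False

    has_zan = False
    for i, d in enumerate(doms):
        if d != "MAM":
            continue
        for j in range(i + 1, len(doms)):
            if doms[j] == "MUCIN" and first_tandem_vwd_after(j + 1):
                has_zan = True
                break
        if has_zan:
            break
    if has_zan:
        return "ZAN_PATTERN"
    if "MUCIN" in doms and first_tandem_vwd_after(0):
        return "ZANL_PATTERN"
    return "NONE"


def classify_locus(
    query: LocusTable,
    reference: LocusTable,
    candidate_arch: "DomainArchitecture | None",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    left: str = "Ephb4",
    right: str = "Epo",
    reference_gene_set=None,
) -> LocusClassification:
    """Label a locus ZAN, ZANL, or ABSENT.

    ZAN requires the full domain pattern, synteny scores at or above the
    thresholds, and a candidate of at least the minimum length in the
    anchor gap. A ZanL-patterned candidate is labelled ZANL at any synteny
    level (scores still reported). With no candidate in the gap, or a gap too
    short to hold one, the locus is ABSENT.
    """
    scores = synteny_scores(query, reference, reference_gene_set)
    gap, inside = flank_gap(query, left=left, right=right)
    verdict = domain_verdict(candidate_arch)
    candidate_names = tuple(r.gene for r in inside)
    max_len = max((r.length for r in inside), default=0)

    if not inside:
        label, notes = "ABSENT", f"no candidate gene between anchors (gap {gap} bp)"
    elif verdict == "ZAN_PATTERN" and (
        scores.content >= thresholds.min_content
        and scores.order >= thresholds.min_order
        and max_len >= thresholds.min_candidate_length
    ):
        label, notes = "ZAN", ""
    elif verdict == "ZANL_PATTERN":
        label, notes = "ZANL", ""
    elif verdict == "ZAN_PATTERN":
        label, notes = "ZANL", "Zan-patterned but synteny or length below threshold"
    else:
        label, notes = "ABSENT", "candidate without recognizable architecture"
    return LocusClassification(
        label=label,
        scores=scores,
        flank_gap_bp=gap,
        candidate_genes=candidate_names,
        domain_verdict=verdict,
        notes=notes,
    )
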