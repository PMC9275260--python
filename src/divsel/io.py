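"""Validated containers and file I/O for alignments, trees, taxonomy tables,
and gene-locus tables.

Coordinate conventions
----------------------
Alignment column intervals are 0-based half-open everywhere. Locus tables are
1-based inclusive base pairs at the file boundary (GFF-like) and converted to
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    AlignmentShapeError,
    FrameError,
    IntervalError,
    SchemaError,
    ValidationError,
)
from .trees import PhyloTree

__all__ = [
    "NucAlignment",
    "CodonAlignment",
    "TaxonomyMap",
    "LocusRecord",
    "LocusTable",
    "read_alignment",
    "write_alignment",
    "as_codon_alignment",
    "excise_columns",
    "read_tree",
    "write_tree",
    "read_taxonomy",
    "write_taxonomy",
    "read_locus_table",
    "write_locus_table",
]

_VALID_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class NucAlignment:
    """Aligned nucleotide sequences over {A, C, G, T, N, -}."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValidationError("alignment needs at least 2 taxa")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValidationError("duplicate taxon names in alignment")
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError("taxa and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged alignment, row lengths {sorted(lengths)}")
        for name, row in zip(self.taxa, self.rows):
            bad = set(row) - _VALID_CHARS
            if bad:
                raise ValidationError(f"invalid characters {sorted(bad)} in {name!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        try:
            return self.rows[self.taxa.index(name)]
        except ValueError:
            raise KeyError(f"taxon {name!r} not in alignment") from None

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "NucAlignment":
        names, seqs = zip(*pairs)
        return cls(tuple(names), tuple(s.upper() for s in seqs))


@dataclass(frozen=True)
class CodonAlignment(NucAlignment):
    """In-frame codon alignment. Codons containing N or ``-`` are treated as
    missing data downstream; in-frame internal stop codons are reported (and
    rejected in strict mode)."""

    code_id: int = 1
    stop_report: tuple[tuple[str, int], ...] = field(default=(), compare=False)

    def __post_init__(self):
        super().__post_init__()
        if self.n_sites % 3 != 0:
            raise FrameError(f"alignment length {self.n_sites} not divisible by 3")

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def codons(self, name: str) -> list[str]:
        row = self.row(name)
        return [row[i: i + 3] for i in range(0, len(row), 3)]


def _stop_codons(code_id: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[code_id].stop_codons)


def as_codon_alignment(
    aln: NucAlignment, code_id: int = 1, strict: bool = True
) -> CodonAlignment:
    """Validate reading frame and scan for premature stop codons.

    The final codon of each row may be a stop (terminal stops are normal);
    any earlier in-frame stop is recorded as ``(taxon, codon_index)`` in
    ``stop_report`` and raises in strict mode.
    """
    if aln.n_sites % 3 != 0:
        raise FrameError(f"alignment length {aln.n_sites} not divisible by 3")
    stops = _stop_codons(code_id)
    report = []
    n_codons = aln.n_sites // 3
    for name, row in zip(aln.taxa, aln.rows):
        for k in range(n_codons - 1):  # terminal codon exempt
            if row[3 * k: 3 * k + 3] in stops:
                report.append((name, k))
    if strict and report:
        raise ValidationError(f"internal stop codons: {report}")
    return CodonAlignment(
        aln.taxa, aln.rows, code_id=code_id, stop_report=tuple(report)
    )


def excise_columns(aln: NucAlignment, intervals: Sequence[tuple[int, int]]):
    """Remove 0-based half-open column intervals from all rows.

    Intervals must be in-bounds and non-overlapping; on a codon alignment the
    bounds must be multiples of 3 so the frame is preserved.
    """
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    prev_end = 0
    for a, b in ivs:
        if a < 0 or b > aln.n_sites or a >= b:
            raise IntervalError(f"interval [{a}, {b}) out of range or empty")
        if a < prev_end:
            raise IntervalError(f"interval [{a}, {b}) overlaps a previous one")
        prev_end = b
    if isinstance(aln, CodonAlignment):
        for a, b in ivs:
            if a % 3 or b % 3:
                raise FrameError(f"interval [{a}, {b}) not codon-aligned")

    def cut(row: str) -> str:
        keep, pos = [], 0
        for a, b in ivs:
            keep.append(row[pos:a])
            pos = b
        keep.append(row[pos:])
        return "".join(keep)

    rows = tuple(cut(r) for r in aln.rows)
    if isinstance(aln, CodonAlignment):
        return CodonAlignment(aln.taxa, rows, code_id=aln.code_id)
    return NucAlignment(aln.taxa, rows)


# ---------------------------------------------------------------- alignments
def read_alignment(path, format: str = "fasta") -> NucAlignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment (upper-cased)."""
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValidationError(f"no sequences in {path}")
        return NucAlignment.from_pairs(records)
    if format == "phylip":
        return _read_relaxed_phylip(path)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_relaxed_phylip(path: Path) -> NucAlignment:
    # Relaxed sequential dialect: header "ntax nchar"; each record is a name
    # token followed by sequence that may wrap across lines until nchar
    # characters have been collected.
    tokens_by_line = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    flat = [t for line in tokens_by_line for t in line]
    try:
        ntax, nchar = int(flat[0]), int(flat[1])
    except (IndexError, ValueError):
        raise SchemaError(f"{path}: missing PHYLIP header") from None
    pos, pairs = 2, []
    for _ in range(ntax):
        if pos >= len(flat):
            raise AlignmentShapeError(f"{path}: fewer records than header claims")
        name = flat[pos]
        pos += 1
        seq = []
        got = 0
        while got < nchar:
            if pos >= len(flat):
                raise AlignmentShapeError(f"{path}: sequence for {name!r} truncated")
            chunk = flat[pos]
            pos += 1
            seq.append(chunk)
            got += len(chunk)
        if got != nchar:
            raise AlignmentShapeError(
                f"{path}: sequence for {name!r} has {got} chars, expected {nchar}"
            )
        pairs.append((name, "".join(seq)))
    return NucAlignment.from_pairs(pairs)


def write_alignment(aln: NucAlignment, path, format: str = "fasta") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if format == "fasta":
            for name, row in zip(aln.taxa, aln.rows):
                fh.write(f">{name}\n{row}\n")
        elif format == "phylip":
            fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
            for name, row in zip(aln.taxa, aln.rows):
                fh.write(f"{name}  {row}\n")
        else:
            raise ValueError(f"unknown alignment format {format!r}")


# --------------------------------------------------------------------- trees
def read_tree(path, percent_supports: bool = True) -> PhyloTree:
    """Read a Newick tree; numeric internal-node labels become supports."""
    return PhyloTree.from_newick(Path(path).read_text(), percent_supports)


def write_tree(tree: PhyloTree, path, **kwargs) -> None:
    Path(path).write_text(tree.to_newick(**kwargs) + "\n")


# ------------------------------------------------------------------ taxonomy
@dataclass(frozen=True)
class TaxonRanks:
    superorder: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""


class TaxonomyMap:
    """tip name -> (superorder, order, family, genus). Lookups of unknown
    tips raise KeyError rather than defaulting silently."""

    _COLUMNS = ("tip", "superorder", "order", "family", "genus")

    def __init__(self, mapping: Mapping[str, TaxonRanks]):
        self._map = dict(mapping)

    def __getitem__(self, tip: str) -> TaxonRanks:
        try:
            return self._map[tip]
        except KeyError:
            raise KeyError(f"tip {tip!r} absent from taxonomy") from None

    def __contains__(self, tip: str) -> bool:
        return tip in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._map)

    def level(self, tip: str, level: str) -> str:
        return getattr(self[tip], level)

    def items(self):
        return self._map.items()


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TaxonomyMap._COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"taxonomy table missing columns {sorted(missing)}")
    return TaxonomyMap(
        {
            row.tip: TaxonRanks(row.superorder, row.order, row.family, row.genus)
            for row in df.itertuples()
        }
    )


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = [
        {"tip": tip, "superorder": r.superorder, "order": r.order,
         "family": r.family, "genus": r.genus}
        for tip, r in tax.items()
    ]
    pd.DataFrame(rows, columns=list(TaxonomyMap._COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------- locus table
@dataclass(frozen=True)
class LocusRecord:
    """One gene. ``start``/``end`` are 0-based half-open base pairs."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene}: start {self.start} not before end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


class LocusTable:
    """Ordered, stranded gene coordinates on one or more chromosomes.
    Records are kept sorted by (chrom, start)."""

    def __init__(self, records: Iterable[LocusRecord]):
        self.records = sorted(records, key=lambda r: (r.chrom, r.start))
        names = [r.gene for r in self.records]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate gene names in locus table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genes(self) -> list[str]:
        return [r.gene for r in self.records]

    def __getitem__(self, gene: str) -> LocusRecord:
        for r in self.records:
            if r.gene == gene:
                return r
        raise KeyError(f"gene {gene!r} not in locus table")

    def __contains__(self, gene: str) -> bool:
        return any(r.gene == gene for r in self.records)


def read_locus_table(path) -> LocusTable:
    """Read a TSV of (gene, chrom, start, end, strand); coordinates in the
    file are 1-based inclusive and converted to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    missing = {"gene", "chrom", "start", "end", "strand"} - set(df.columns)
    if missing:
        raise SchemaError(f"locus table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        start1, end1 = int(row.start), int(row.end)
        if start1 >= end1:
            raise ValidationError(f"{row.gene}: start {start1} >= end {end1}")
        records.append(
            LocusRecord(row.gene, row.chrom, start1 - 1, end1, str(row.strand))
        )
    return LocusTable(records)


def write_locus_table(table: LocusTable, path) -> None:
    rows = [
        {"gene": r.gene, "chrom": r.chrom, "start": r.start + 1,
         "end": r.end, "strand": r.strand}
        for r in table
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )
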