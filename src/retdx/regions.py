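"""Gene panel, transcript geometry and the clinically analysed region.

The diagnostic panel targets the coding regions of a set of disease genes.
Two nested windows matter downstream:

* the *enrichment* region — coding exon segments ± 50 bp, the territory the
  capture chemistry pulls down;
* the *clinical* region — coding exon segments ± 5 bp, the territory within
  which variants are clinically interpreted, plus any per-gene special
  intronic sites (the CEP290 deep-intronic hotspot harbouring the recurrent
  c.2991+1655A>G allele).

All internal coordinates are 0-based, half-open; VCF positions (1-based)
are converted on ingest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

INHERITANCE_MODES = frozenset({"AD", "AR", "XL"})

#: The ten clinical referral classifications used at intake.
REFERRAL_CATEGORIES = (
    "RCD/RP",
    "CD",
    "CRD",
    "MD/STGD",
    "EORD/LCA",
    "CSNB",
    "FEVR",
    "Usher",
    "Ciliopathy",
    "Other",
)

CLINICAL_FLANK = 5
ENRICHMENT_FLANK = 50


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/touching intervals; idempotent and order-independent."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        run_start = run_end = None
        for iv in sorted(by_chrom[chrom], key=lambda i: (i.start, i.end)):
            if run_start is None:
                run_start, run_end = iv.start, iv.end
            elif iv.start <= run_end:  # touching counts as mergeable
                run_end = max(run_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, run_start, run_end))
                run_start, run_end = iv.start, iv.end
        if run_start is not None:
            out.append(GenomicInterval(chrom, run_start, run_end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


START_CODON = "ATG"


@dataclass(slots=True)
class Transcript:
    """One designated transcript per gene: exon geometry plus the CDS.

    ``cds_sequence`` is the spliced coding sequence in translation order
    (i.e. already reverse-complemented for minus-strand genes). It must be a
    whole number of codons and begin with the start codon.
    """

    id: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.id}: exons unsorted or overlapping")
        if not any(e.start <= self.cds_start < e.end for e in self.exons):
            raise ValueError(f"{self.id}: cds_start outside exons")
        if not any(e.start < self.cds_end <= e.end for e in self.exons):
            raise ValueError(f"{self.id}: cds_end outside exons")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")
        if not self.cds_sequence.upper().startswith(START_CODON):
            raise ValueError(f"{self.id}: CDS does not begin with {START_CODON}")

    def cds_segments(self) -> list[GenomicInterval]:
        """Exon segments intersected with [cds_start, cds_end), genomic order."""
        segs = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s < t:
                segs.append(GenomicInterval(self.chrom, s, t))
        return segs

    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments())


@dataclass(slots=True)
class GeneRecord:
    symbol: str
    transcript: Transcript
    inheritance_modes: frozenset[str]
    phenotype_categories: frozenset[str]
    discovery_year: int
    lof_mechanism: bool

    def __post_init__(self) -> None:
        if not self.inheritance_modes:
            raise ValueError(f"{self.symbol}: at least one inheritance mode required")
        bad = set(self.inheritance_modes) - INHERITANCE_MODES
        if bad:
            raise ValueError(f"{self.symbol}: unknown inheritance modes {bad}")
        if not 1980 <= self.discovery_year <= 2016:
            raise ValueError(f"{self.symbol}: discovery_year {self.discovery_year} out of range")


@dataclass(slots=True)
class Panel:
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    special_intronic_sites: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, _ in self.special_intronic_sites:
            if gene not in self.genes:
                raise ValueError(f"special intronic site for unknown gene {gene}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self.genes[symbol]

    def symbols(self) -> list[str]:
        return sorted(self.genes)

    def special_sites_for(self, gene: str) -> list[GenomicInterval]:
        return [iv for g, iv in self.special_intronic_sites if g == gene]


# ---------------------------------------------------------------------------
# panel file IO
#
# Panel TSV columns (header required):
#   symbol, transcript_id, chrom, strand, exons, cds_start, cds_end,
#   modes, categories, discovery_year, lof_mechanism
# exons: comma-separated start-end pairs, 0-based half-open ("100-160,200-260")
# modes/categories: comma-separated.  CDS sequences live in a companion FASTA
# keyed by transcript_id.  Special intronic sites in an optional TSV:
#   gene, chrom, start, end.

_REQUIRED_COLUMNS = {
    "symbol", "transcript_id", "chrom", "strand", "exons",
    "cds_start", "cds_end", "modes", "categories",
    "discovery_year", "lof_mechanism",
}


def _parse_exons(chrom: str, text: str) -> list[GenomicInterval]:
    out = []
    for chunk in text.split(","):
        a, b = chunk.split("-")
        out.append(GenomicInterval(chrom, int(a), int(b)))
    return out


def load_panel(
    panel_file: str | Path,
    cds_fasta: str | Path,
    special_sites_file: str | Path | None = None,
) -> Panel:
    """Load a gene panel from its TSV definition and companion CDS FASTA.

    Raises ``ValueError`` on duplicated symbols, missing columns, missing
    inheritance modes or an empty file.
    """
    cds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    genes: dict[str, GeneRecord] = {}
    with open(panel_file, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{panel_file}: empty panel file")
        missing = _REQUIRED_COLUMNS - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{panel_file}: missing columns {sorted(missing)}")
        n_rows = 0
        for row in reader:
            n_rows += 1
            symbol = row["symbol"].strip()
            if symbol in genes:
                raise ValueError(f"duplicate panel symbol {symbol}")
            modes = frozenset(m for m in row["modes"].replace("|", ",").split(",") if m)
            if not modes:
                raise ValueError(f"{symbol}: missing inheritance mode")
            tid = row["transcript_id"].strip()
            if tid not in cds:
                raise ValueError(f"{symbol}: transcript {tid} absent from {cds_fasta}")
            tx = Transcript(
                id=tid,
                gene=symbol,
                chrom=row["chrom"],
                strand=row["strand"],
                exons=_parse_exons(row["chrom"], row["exons"]),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
                cds_sequence=cds[tid],
            )
            genes[symbol] = GeneRecord(
                symbol=symbol,
                transcript=tx,
                inheritance_modes=modes,
                phenotype_categories=frozenset(
                    c for c in row["categories"].replace("|", ",").split(",") if c
                ),
                discovery_year=int(row["discovery_year"]),
                lof_mechanism=row["lof_mechanism"].strip().lower() in ("1", "true", "yes"),
            )
    if not genes:
        raise ValueError(f"{panel_file}: no genes")
    sites: list[tuple[str, GenomicInterval]] = []
    if special_sites_file is not None:
        with open(special_sites_file, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                sites.append(
                    (row["gene"], GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])))
                )
    # deterministic ordering by symbol
    return Panel(genes={s: genes[s] for s in sorted(genes)}, special_intronic_sites=sites)


def _flanked_cds_region(panel: Panel, gene: str, flank: int) -> list[GenomicInterval]:
    if gene not in panel:
        raise KeyError(f"gene {gene} not in panel")
    tx = panel[gene].transcript
    flanked = [
        GenomicInterval(seg.chrom, max(0, seg.start - flank), seg.end + flank)
        for seg in tx.cds_segments()
    ]
    return merge_intervals(flanked)


def clinical_region(panel: Panel, gene: str) -> list[GenomicInterval]:
    """CDS-overlapping exon segments ± 5 bp, merged; plus special intronic
    sites configured for the gene (the CEP290 hotspot)."""
    base = _flanked_cds_region(panel, gene, CLINICAL_FLANK)
    return merge_intervals(base + panel.special_sites_for(gene))


def enrichment_region(panel: Panel, gene: str) -> list[GenomicInterval]:
    """CDS-overlapping exon segments ± 50 bp, merged, plus special sites."""
    base = _flanked_cds_region(panel, gene, ENRICHMENT_FLANK)
    return merge_intervals(base + panel.special_sites_for(gene))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, name: str = "") -> None:
    with open(path, "w") as fh:
        for iv in merge_intervals(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if name:
                fields.append(name)
            fh.write("\t".join(fields) + "\n")


def panel_clinical_regions(panel: Panel) -> Mapping[str, list[GenomicInterval]]:
    return {g: clinical_region(panel, g) for g in panel.symbols()}
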