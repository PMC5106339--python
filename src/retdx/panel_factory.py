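"""Deterministic synthetic 105-gene panel used by the simulator and the
worked-example fixture.

Real coordinates of the clinical assay are not redistributed with the
package, so the panel uses synthetic transcript geometry (one contig per
gene; X-linked genes share a synthetic chrX) while keeping real gene
symbols, inheritance modes, phenotype associations and approximate
discovery years for the genes the service's headline findings concern
(ABCA4, CERKL, EYS, RHO, CHM, GUCY2D, CEP290, USH2A, PRPF31).  The
remaining 96 genes are synthetic placeholders whose era/mode composition
matches the assay's published gene-discovery profile: 7 genes discovered
before 1995, 65 in 1995–2004 and 33 from 2005 on.

GUCY2D carries a deliberately GC-rich 731-base central coding exon
(76.20% GC) — the classic capillary-fallback exon.
"""

from __future__ import annotations

import zlib

import numpy as np

from .regions import GeneRecord, GenomicInterval, Panel, Transcript

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - _STOPS)

# symbol, mode, categories, discovery year, LoF mechanism, era tag
REAL_GENES = [
    ("ABCA4", "AR", ("MD/STGD", "CRD", "RCD/RP", "CD", "Usher"), 1997, True),
    ("USH2A", "AR", ("Usher", "RCD/RP"), 1998, True),
    ("EYS", "AR", ("RCD/RP",), 2008, True),
    ("RHO", "AD", ("RCD/RP",), 1990, False),
    ("CHM", "XL", ("Other",), 1990, True),
    ("GUCY2D", "AR", ("EORD/LCA", "CRD"), 1996, True),
    ("CEP290", "AR", ("EORD/LCA", "Ciliopathy"), 2006, True),
    ("CERKL", "AR", ("RCD/RP", "CRD", "CD", "MD/STGD"), 2004, True),
    ("PRPF31", "AD", ("RCD/RP",), 2001, True),
]

_AR_CATS = ("RCD/RP", "EORD/LCA", "CRD", "MD/STGD", "CD", "CSNB", "Usher", "Ciliopathy")
_CROSS_SECOND = {"RCD/RP": "CRD", "EORD/LCA": "CSNB", "CRD": "CD", "MD/STGD": "CD",
                 "CD": "CRD", "CSNB": "RCD/RP", "Usher": "RCD/RP", "Ciliopathy": "EORD/LCA"}


def _synthetic_rows() -> list[tuple[str, str, tuple[str, ...], int, bool, str]]:
    """96 synthetic genes: (symbol, mode, cats, year, lof, role).

    role ∈ {diag_single, diag_cross, background, carrier} — consumed by the
    worked-example fixture to allocate diagnoses; the simulator ignores it.
    """
    rows = []
    idx = 10

    def add(mode, year, lof, role, cats=None, n=1):
        nonlocal idx
        for _ in range(n):
            primary = _AR_CATS[idx % len(_AR_CATS)]
            if cats is None:
                c = (primary, _CROSS_SECOND[primary]) if role == "diag_cross" else (primary,)
            else:
                c = cats
            rows.append((f"IRD{idx:03d}", mode, c, year, lof, role))
            idx += 1

    # pre-1995 era: 5 synthetic (2 AR + 1 AD diagnosed, 2 background)
    add("AR", 1988, True, "diag_cross", cats=("RCD/RP", "CSNB"))   # PRE cross gene
    add("AR", 1991, True, "diag_single")
    add("AD", 1993, True, "diag_single")
    add("AR", 1989, False, "background")
    add("AD", 1994, False, "background")

    # 1995-2004 era: 60 synthetic
    add("XL", 1999, True, "diag_single", n=2)          # XL diagnosed (5 + 4 patients)
    add("AD", 1996, True, "diag_single", n=6)          # AD diagnosed (5 each)
    add("AR", 1997, True, "diag_cross", n=12)          # AR cross-category
    add("AR", 2000, True, "diag_single", n=15)         # AR single-category
    add("XL", 2002, False, "background", n=1)          # background XL (hemi VUS pool)
    add("AR", 2003, False, "carrier", n=5)             # carrier-finding genes
    add("AD", 1995, False, "background", n=4)
    add("AR", 2001, False, "background", n=15)

    # post-2005 era: 31 synthetic
    add("XL", 2006, True, "diag_single", n=1)
    add("AD", 2007, True, "diag_single", n=2)
    add("AR", 2009, True, "diag_cross", n=6)
    add("AR", 2010, True, "diag_single", n=6)
    add("XL", 2011, False, "background", n=1)
    add("AR", 2008, False, "background", n=15)

    assert len(rows) == 96, len(rows)
    return rows


def gene_roles() -> dict[str, str]:
    return {sym: role for sym, _, _, _, _, role in _synthetic_rows()}


def _rng_for(symbol: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(symbol.encode()) & 0x7FFFFFFF)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(_CODONS)[rng.integers(0, len(_CODONS), n)])


def _gucy2d_cds() -> str:
    """424 codons; CDS bases 240..970 form the GC-rich exon (557/731 GC)."""
    rng = _rng_for("GUCY2D")
    head = _random_codons(rng, 79)          # codons 1..79
    rich = []
    g, a = 185, 58                          # 185×GGC + 58×ATT interleaved
    while g or a:
        if g:
            rich.append("GGC")
            g -= 1
        if a:
            rich.append("ATT")
            a -= 1
    tail = _random_codons(rng, 99)          # codons 324..422
    cds = "ATG" + head + "".join(rich) + "GGT" + tail + "TAA"
    assert len(cds) == 1272
    return cds


_FLANK = 200
_INTRON = 120


def _build_gene(
    symbol: str,
    mode: str,
    cats: tuple[str, ...],
    year: int,
    lof: bool,
    chrom: str,
    offset: int,
) -> tuple[GeneRecord, str]:
    """Build one gene's record plus the genomic sequence of its locus."""
    rng = _rng_for(symbol)
    if symbol == "GUCY2D":
        cds = _gucy2d_cds()
        exon_lens = [240, 731, 301]
    else:
        n_codons = 300
        cds = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        exon_lens = [240, 360, 300]
    assert sum(exon_lens) == len(cds)
    exons = []
    pos = offset + _FLANK
    for length in exon_lens:
        exons.append(GenomicInterval(chrom, pos, pos + length))
        pos += length + _INTRON
    locus_end = exons[-1].end + _FLANK
    # assemble genomic sequence for the locus (plus strand throughout)
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(0, 4, locus_end - offset)]))
    cds_cursor = 0
    for e in exons:
        seq[e.start - offset : e.end - offset] = list(cds[cds_cursor : cds_cursor + len(e)])
        cds_cursor += len(e)
    tx = Transcript(
        id=f"TX_{symbol}",
        gene=symbol,
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=exons[0].start,
        cds_end=exons[-1].end,
        cds_sequence=cds,
    )
    rec = GeneRecord(
        symbol=symbol,
        transcript=tx,
        inheritance_modes=frozenset({mode}),
        phenotype_categories=frozenset(cats),
        discovery_year=year,
        lof_mechanism=lof,
    )
    return rec, "".join(seq)


_X_SPACING = 3000


def default_panel(with_genome: bool = False):
    """The canonical 105-gene synthetic panel (deterministic).

    Returns the Panel, or (Panel, genome dict chrom → sequence) when
    ``with_genome`` is set.
    """
    rows = [(s, m, c, y, l) for s, m, c, y, l in REAL_GENES]
    rows += [(s, m, c, y, l) for s, m, c, y, l, _ in _synthetic_rows()]
    genes: dict[str, GeneRecord] = {}
    genome: dict[str, str] = {}
    x_parts: list[tuple[int, str]] = []
    x_offset = 0
    for symbol, mode, cats, year, lof in rows:
        if mode == "XL":
            rec, seq = _build_gene(symbol, mode, cats, year, lof, "chrX", x_offset)
            x_parts.append((x_offset, seq))
            x_offset += _X_SPACING
        else:
            rec, seq = _build_gene(symbol, mode, cats, year, lof, f"chr_{symbol}", 0)
            genome[f"chr_{symbol}"] = seq
        genes[symbol] = rec
    # stitch chrX: loci padded to the fixed spacing
    x_seq = []
    for off, seq in x_parts:
        pad = off + _X_SPACING - (off + len(seq))
        x_seq.append(seq + "A" * pad)
    genome["chrX"] = "".join(x_seq)

    cep = genes["CEP290"].transcript
    intron_mid = (cep.exons[0].end + cep.exons[1].start) // 2
    special = [("CEP290", GenomicInterval(cep.chrom, intron_mid - 5, intron_mid + 5))]
    panel = Panel(genes={s: genes[s] for s in sorted(genes)}, special_intronic_sites=special)
    assert len(panel) == 105
    if with_genome:
        return panel, genome
    return panel


def write_panel_files(panel: Panel, genome: dict[str, str], outdir) -> None:
    """Emit panel.tsv, cds.fasta, genome.fasta and special_sites.tsv."""
    from pathlib import Path

    d = Path(outdir)
    with open(d / "panel.tsv", "w") as fh:
        fh.write(
            "symbol\ttranscript_id\tchrom\tstrand\texons\tcds_start\tcds_end\t"
            "modes\tcategories\tdiscovery_year\tlof_mechanism\n"
        )
        for sym in panel.symbols():
            g = panel[sym]
            tx = g.transcript
            exons = ",".join(f"{e.start}-{e.end}" for e in tx.exons)
            fh.write(
                f"{sym}\t{tx.id}\t{tx.chrom}\t{tx.strand}\t{exons}\t{tx.cds_start}\t"
                f"{tx.cds_end}\t{'|'.join(sorted(g.inheritance_modes))}\t"
                f"{'|'.join(sorted(g.phenotype_categories))}\t{g.discovery_year}\t"
                f"{int(g.lof_mechanism)}\n"
            )
    with open(d / "cds.fasta", "w") as fh:
        for sym in panel.symbols():
            tx = panel[sym].transcript
            fh.write(f">{tx.id}\n")
            for i in range(0, len(tx.cds_sequence), 70):
                fh.write(tx.cds_sequence[i : i + 70] + "\n")
    with open(d / "genome.fasta", "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            for i in range(0, len(genome[chrom]), 70):
                fh.write(genome[chrom][i : i + 70] + "\n")
    with open(d / "special_sites.tsv", "w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for gene, iv in panel.special_intronic_sites:
            fh.write(f"{gene}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
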