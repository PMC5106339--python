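"""Shared fixtures: toy transcripts, an independent consequence oracle, the
worked-example cohort and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from retdx.consequence import revcomp
from retdx.fixture import paper_fixture
from retdx.regions import GeneRecord, GenomicInterval, Panel, Transcript

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS
)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(np.asarray(_CODONS)[rng.integers(0, len(_CODONS), n_codons - 2)])
    return "ATG" + body + "TAA"


def make_toy_gene(
    cds: str,
    exon_lens: list[int] | None = None,
    strand: str = "+",
    chrom: str = "chrT",
    gene: str = "TOY",
    offset: int = 100,
    intron: int = 30,
    lof: bool = True,
) -> tuple[GeneRecord, str]:
    """Build a toy gene whose CDS covers its exons exactly; returns the
    record and the full chromosome sequence (reference for oracles)."""
    exon_lens = exon_lens or [len(cds)]
    assert sum(exon_lens) == len(cds)
    genomic_cds = cds if strand == "+" else revcomp(cds)
    exons, pos, cursor, pieces = [], offset, 0, []
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    pieces.append("".join(bases[rng.integers(0, 4, offset)]))
    for i, ln in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + ln))
        pieces.append(genomic_cds[cursor : cursor + ln])
        cursor += ln
        pos += ln
        if i < len(exon_lens) - 1:
            pieces.append("".join(bases[rng.integers(0, 4, intron)]))
            pos += intron
    pieces.append("".join(bases[rng.integers(0, 4, 50)]))
    tx = Transcript(
        id=f"TX_{gene}", gene=gene, chrom=chrom, strand=strand, exons=exons,
        cds_start=exons[0].start, cds_end=exons[-1].end, cds_sequence=cds,
    )
    rec = GeneRecord(
        symbol=gene, transcript=tx, inheritance_modes=frozenset({"AR"}),
        phenotype_categories=frozenset({"RCD/RP"}), discovery_year=2000,
        lof_mechanism=lof,
    )
    return rec, "".join(pieces)


def toy_panel(records: list[GeneRecord], special=None) -> Panel:
    return Panel(genes={r.symbol: r for r in records},
                 special_intronic_sites=special or [])


def oracle_snv_term(rec: GeneRecord, pos: int, alt: str) -> str:
    """Independent splice-mutate-translate oracle for coding SNVs, built on
    Biopython's translator rather than the annotator's codon logic."""
    tx = rec.transcript
    segs = tx.cds_segments()
    fwd_cds = tx.cds_sequence if tx.strand == "+" else revcomp(tx.cds_sequence)
    off = 0
    fwd_idx = None
    for seg in segs:
        if seg.start <= pos < seg.end:
            fwd_idx = off + (pos - seg.start)
            break
        off += len(seg)
    assert fwd_idx is not None, "oracle only covers coding SNVs"
    mutated_fwd = fwd_cds[:fwd_idx] + alt + fwd_cds[fwd_idx + 1 :]
    cds = tx.cds_sequence
    mutated = mutated_fwd if tx.strand == "+" else revcomp(mutated_fwd)
    ref_prot = str(Seq(cds).translate())
    alt_prot = str(Seq(mutated).translate())
    if mutated[:3] != "ATG":
        return "start_lost"
    if alt_prot == ref_prot:
        return "synonymous"
    ref_stop = ref_prot.index("*") if "*" in ref_prot else len(ref_prot)
    alt_stop = alt_prot.index("*") if "*" in alt_prot else len(alt_prot)
    if alt_stop < ref_stop:
        return "stop_gained"
    return "missense"


@pytest.fixture(scope="session")
def fx():
    return paper_fixture()


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """A 200-patient simulated cohort under the definitive evidence profile
    with its full pipeline output."""
    from retdx.pipeline import run_cohort
    from retdx.simulate import SimConfig, simulate_cohort

    d = tmp_path_factory.mktemp("sim200")
    cfg = SimConfig(seed=11, n_patients=200, evidence_profile="definitive")
    _, truths = simulate_cohort(cfg, d)
    results = run_cohort(d)
    return d, cfg, truths, results
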