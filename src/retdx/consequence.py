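"""Predicted consequence of a variant on its gene's designated transcript.

Coding SNVs are resolved by mutating the affected codon of the spliced CDS
on the coding strand and comparing translations.  Intronic SNVs within the
clinically analysed ±5 bp flank are split into canonical splice-site
(positions ±1/±2) and splice-region (±3..±5) changes.  Indels overlapping
the CDS are frameshift when the allele length difference is not a multiple
of three, otherwise in-frame; length-preserving multi-base substitutions
are coding_delins and count as truncating only when the re-translated CDS
gains a premature stop.  Variants at a configured special intronic site
(the CEP290 deep-intronic hotspot) are intronic_special.

The severity order used for junction-spanning events is
stop_gained > frameshift > start_lost > canonical_splice > coding_delins >
inframe events > missense > splice_region > synonymous > intronic_special.
"""

from __future__ import annotations

from dataclasses import dataclass

from .regions import GeneRecord, GenomicInterval, Transcript
from .triage import FrequencyRecord
from .variants import Variant

TERMS = (
    "missense", "stop_gained", "synonymous", "start_lost", "canonical_splice",
    "splice_region", "frameshift", "inframe_deletion", "inframe_insertion",
    "intronic_special", "coding_delins",
)

SEVERITY = {
    "stop_gained": 0, "frameshift": 1, "start_lost": 2, "canonical_splice": 3,
    "coding_delins": 4, "inframe_deletion": 5, "inframe_insertion": 6,
    "missense": 7, "splice_region": 8, "synonymous": 9, "intronic_special": 10,
}

TRUNCATING_TERMS = frozenset({"stop_gained", "frameshift", "start_lost"})

# standard genetic code, written out so the annotator does not depend on a
# translation library (the test oracle does, independently)
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class Consequence:
    term: str
    protein_change: str | None = None
    truncating: bool = False

    def __post_init__(self) -> None:
        if self.term not in TERMS:
            raise ValueError(f"unknown consequence term {self.term}")


def genomic_to_cds_index(tx: Transcript, pos: int) -> int | None:
    """CDS index (0-based, translation order) of a genomic position, or
    None when the position is non-coding."""
    offset = 0
    for seg in tx.cds_segments():
        if seg.start <= pos < seg.end:
            fwd = offset + (pos - seg.start)
            if tx.strand == "+":
                return fwd
            return tx.cds_length() - 1 - fwd
        offset += len(seg)
    return None


def _intron_distance(tx: Transcript, pos: int) -> int | None:
    """Distance (≥1) from a non-coding position to the nearest CDS segment
    boundary, or None if the position is coding."""
    best: int | None = None
    for seg in tx.cds_segments():
        if seg.start <= pos < seg.end:
            return None
        d = seg.start - pos if pos < seg.start else pos - seg.end + 1
        best = d if best is None else min(best, d)
    return best


def _in_exon(tx: Transcript, pos: int) -> bool:
    return any(e.start <= pos < e.end for e in tx.exons)


def _protein_change(ref_aa: str, codon_number: int, alt_aa: str) -> str:
    return f"p.({AA3[ref_aa]}{codon_number}{AA3[alt_aa]})"


def _snv_coding(tx: Transcript, cds_idx: int, ref: str, alt: str) -> Consequence:
    cds = tx.cds_sequence.upper()
    ref_c, alt_c = (ref, alt) if tx.strand == "+" else (revcomp(ref), revcomp(alt))
    if cds[cds_idx] != ref_c:
        raise ValueError(
            f"{tx.id}: reference base {ref_c} does not match CDS base {cds[cds_idx]} "
            f"at CDS index {cds_idx}"
        )
    codon_i = cds_idx // 3
    within = cds_idx % 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1 :]
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    change = _protein_change(ref_aa, codon_i + 1, alt_aa)
    if codon_i == 0 and alt_codon != "ATG":
        return Consequence("start_lost", change, truncating=True)
    if alt_aa == "*" and ref_aa != "*":
        return Consequence("stop_gained", change, truncating=True)
    if alt_aa == ref_aa:
        return Consequence("synonymous", change, truncating=False)
    return Consequence("missense", change, truncating=False)


def _splice_term(dist: int) -> str:
    return "canonical_splice" if dist <= 2 else "splice_region"


def _apply_to_cds(tx: Transcript, variant: Variant) -> str | None:
    """Mutated spliced CDS, when the variant footprint sits wholly inside a
    single CDS segment; None otherwise."""
    for seg_idx, seg in enumerate(tx.cds_segments()):
        if seg.start <= variant.pos and variant.end <= seg.end:
            offset = sum(len(s) for s in tx.cds_segments()[:seg_idx])
            fwd = offset + (variant.pos - seg.start)
            fwd_cds = tx.cds_sequence if tx.strand == "+" else revcomp(tx.cds_sequence)
            mutated_fwd = fwd_cds[:fwd] + variant.alt + fwd_cds[fwd + len(variant.ref) :]
            return mutated_fwd if tx.strand == "+" else revcomp(mutated_fwd)
    return None


def _translate(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE.get(cds[i : i + 3], "X")
        aas.append(aa)
        if aa == "*":
            break
    return "".join(aas)


def _gains_premature_stop(tx: Transcript, variant: Variant) -> bool:
    mutated = _apply_to_cds(tx, variant)
    if mutated is None:
        return False
    ref_prot = _translate(tx.cds_sequence.upper())
    alt_prot = _translate(mutated.upper())
    return alt_prot.endswith("*") and len(alt_prot) < len(ref_prot)


def annotate(
    variant: Variant,
    gene: GeneRecord,
    special_sites: list[GenomicInterval] | None = None,
) -> Consequence:
    """Annotate a normalized variant lying inside the gene's clinical or
    special region; raises ``ValueError`` outside all annotatable regions."""
    tx = gene.transcript
    for site in special_sites or []:
        if site.chrom == variant.chrom and variant.pos < site.end and variant.end > site.start:
            return Consequence("intronic_special", None, truncating=False)
    if variant.chrom != tx.chrom:
        raise ValueError(f"variant on {variant.chrom}, transcript on {tx.chrom}")

    if variant.vclass == "SNV":
        cds_idx = genomic_to_cds_index(tx, variant.pos)
        if cds_idx is not None:
            return _snv_coding(tx, cds_idx, variant.ref.upper(), variant.alt.upper())
        dist = _intron_distance(tx, variant.pos)
        if dist is None or dist > 5:
            raise ValueError(f"SNV at {variant.pos} outside the annotatable region")
        return Consequence(_splice_term(dist), None, truncating=False)

    # indels / delins: classify by footprint overlap with CDS segments
    footprint = range(variant.pos, max(variant.end, variant.pos + 1))
    coding_positions = [p for p in footprint if genomic_to_cds_index(tx, p) is not None]
    overlaps_cds = bool(coding_positions)
    if variant.vclass == "insertion" and not overlaps_cds:
        # an insertion between two coding bases is coding when both anchors are
        nxt = genomic_to_cds_index(tx, variant.pos + 1)
        overlaps_cds = genomic_to_cds_index(tx, variant.pos) is not None and nxt is not None
    length_diff = len(variant.alt) - len(variant.ref)

    if overlaps_cds:
        spans_junction = len(coding_positions) not in (0, len(list(footprint)))
        if variant.vclass == "delins" and length_diff == 0 and not spans_junction:
            trunc = _gains_premature_stop(tx, variant)
            return Consequence("coding_delins", None, truncating=trunc)
        if length_diff % 3 != 0:
            return Consequence("frameshift", None, truncating=True)
        if spans_junction:  # in-frame length but disrupts the splice site
            return Consequence("canonical_splice", None, truncating=False)
        if length_diff < 0:
            return Consequence("inframe_deletion", None, truncating=False)
        if length_diff > 0:
            return Consequence("inframe_insertion", None, truncating=False)
        trunc = _gains_premature_stop(tx, variant)
        return Consequence("coding_delins", None, truncating=trunc)

    dists = [_intron_distance(tx, p) for p in footprint]
    dists = [d for d in dists if d is not None]
    if not dists or min(dists) > 5:
        raise ValueError(f"indel at {variant.pos} outside the annotatable region")
    return Consequence(_splice_term(min(dists)), None, truncating=False)


def is_novel(variant: Variant, freq: FrequencyRecord) -> bool:  # noqa: ARG001
    """Novel = absent from both dbSNP and EVS (presence at any frequency,
    however rare, defeats novelty)."""
    return freq.dbsnp_af is None and freq.evs_af is None
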