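"""Normalized variant records, zygosity calls and per-patient VCF ingest.

One :class:`GenotypeCall` is produced per alternate allele observed in a
patient, carrying the platform quality metrics (depth, mean quality value,
alt-supporting reads) that the triage stage thresholds on.  Zygosity follows
the clinical convention: hom (two identical alt alleles), het (one), hemi
(a single allele on male chrX/chrY), het_het (a site with two distinct alt
alleles — each allele gets its own call tagged het_het).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pysam

from .regions import REFERRAL_CATEGORIES

VARIANT_CLASSES = ("SNV", "insertion", "deletion", "delins")
ZYGOSITIES = ("hom", "het", "hemi", "het_het")
PLATFORMS = ("SOLiD", "HiSeq")

_SEX_CHROMS = {"chrX", "X", "chrY", "Y"}


def allele_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    return "delins"


@dataclass(frozen=True, slots=True)
class Variant:
    """A normalized allele observation; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if not self.ref or not self.alt:
            raise ValueError("empty allele (use anchor-base representation)")

    @property
    def vclass(self) -> str:
        return allele_class(self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.vclass != "SNV"

    @property
    def end(self) -> int:
        """End of the reference footprint, half-open."""
        return self.pos + len(self.ref)

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(slots=True)
class GenotypeCall:
    variant: Variant
    zygosity: str
    depth: int
    mqv: float
    alt_reads: int
    platform: str

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"bad zygosity {self.zygosity}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("alt_reads outside [0, depth]")


@dataclass(slots=True)
class PatientCase:
    patient_id: str
    sex: str  # "M" | "F"
    referral_category: str
    platform: str
    calls: list[GenotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"bad sex {self.sex}")
        if self.referral_category not in REFERRAL_CATEGORIES:
            raise ValueError(f"unknown referral category {self.referral_category}")
        for c in self.calls:
            if c.platform != self.platform:
                raise ValueError("platform must be uniform within a patient")


# ---------------------------------------------------------------------------
# normalization


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared suffix then shared prefix, keeping one anchor base for
    pure insertions/deletions."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize(variant: Variant, reference_window: str, window_start: int) -> Variant:
    """Trim shared flanks and left-align within ``reference_window``.

    ``reference_window`` is genomic sequence starting at 0-based
    ``window_start`` and must cover the variant's reference footprint.
    Left-aligning shifts an indel to the smallest position that spells an
    identical alternate haplotype (the classic homopolymer/repeat ambiguity).
    """
    off = variant.pos - window_start
    if off < 0 or off + len(variant.ref) > len(reference_window):
        raise ValueError("reference window does not cover the variant")
    window = reference_window.upper()
    if window[off : off + len(variant.ref)] != variant.ref.upper():
        raise ValueError(
            f"ref allele {variant.ref} does not match reference at {variant.chrom}:{variant.pos}"
        )
    pos, ref, alt = variant.pos, variant.ref.upper(), variant.alt.upper()
    # alternate right-truncation of shared trailing bases with left extension
    # from the reference (allowing transiently empty alleles), then trim any
    # shared prefix — the canonical left-alignment procedure.
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif not ref or not alt:
            i = pos - window_start
            if i <= 0:
                break
            pos -= 1
            prev = window[i - 1]
            ref, alt = prev + ref, prev + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:  # ran into the window edge: re-anchor on the right
        nxt = window[pos + len(ref) - window_start]
        ref, alt = ref + nxt, alt + nxt
    if ref == alt:
        raise ValueError("ref == alt after trimming")
    return Variant(variant.chrom, pos, ref, alt)


def spliced_haplotype(window: str, window_start: int, v: Variant) -> str:
    """Apply ``v`` to a reference window — the string oracle used to check
    that normalization preserves the alternate haplotype."""
    i = v.pos - window_start
    return window[:i] + v.alt + window[i + len(v.ref) :]


# ---------------------------------------------------------------------------
# VCF ingest

_MISSING = {None, -1}


def _format_value(rec: pysam.VariantRecord, sample: str, key: str):
    if key in rec.samples[sample]:
        val = rec.samples[sample][key]
        if isinstance(val, tuple):
            val = val[0] if val else None
        if val not in _MISSING:
            return val
    if key in rec.info:
        val = rec.info[key]
        if isinstance(val, tuple):
            val = val[0] if val else None
        return val
    return None


def read_vcf(
    path: str | Path,
    patient_id: str,
    sex: str,
    referral_category: str,
    platform: str,
    mqv_key: str = "MQV",
) -> PatientCase:
    """Read a single-sample VCF into a :class:`PatientCase`.

    One call per alternate allele; a 1/2 site yields two calls tagged
    het_het.  A haploid GT — or any single-alt genotype on chrX in a male —
    is recorded as hemi.  MQV is looked up under ``mqv_key`` (FORMAT first,
    then INFO) with GQ as fallback; depth from DP, alt reads from AD.
    """
    case = PatientCase(patient_id, sex, referral_category, platform)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: no sample column")
        sample = samples[0]
        for rec in vcf:
            gt = rec.samples[sample].get("GT")
            if gt is None or all(a is None for a in gt):
                raise ValueError(f"{path}: missing GT at line for {rec.chrom}:{rec.pos}")
            alleles = [a for a in gt if a is not None]
            alt_idx = sorted({a for a in alleles if a > 0})
            if not alt_idx:
                continue  # hom-ref record: nothing to call
            depth = _format_value(rec, sample, "DP")
            mqv = _format_value(rec, sample, mqv_key)
            if mqv is None:
                mqv = _format_value(rec, sample, "GQ")
            ad = rec.samples[sample].get("AD")
            for idx in alt_idx:
                alt = rec.alts[idx - 1]
                pos0, ref, alt_a = trim_alleles(rec.pos - 1, rec.ref.upper(), alt.upper())
                variant = Variant(rec.chrom, pos0, ref, alt_a)
                if len(alt_idx) > 1:
                    zyg = "het_het"
                elif len(alleles) == 1:
                    zyg = "hemi"
                elif alleles.count(idx) == 2:
                    zyg = "hom"
                elif sex == "M" and rec.chrom in _SEX_CHROMS:
                    zyg = "hemi"
                else:
                    zyg = "het"
                alt_reads = None
                if ad is not None and len(ad) > idx and ad[idx] is not None:
                    alt_reads = ad[idx]
                d = int(depth) if depth is not None else 0
                ar = int(alt_reads) if alt_reads is not None else min(d, max(1, d // 2))
                case.calls.append(
                    GenotypeCall(
                        variant=variant,
                        zygosity=zyg,
                        depth=d,
                        mqv=float(mqv) if mqv is not None else float("nan"),
                        alt_reads=min(ar, d),
                        platform=platform,
                    )
                )
    return case


# ---------------------------------------------------------------------------
# results output

RESULT_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "vclass", "zygosity",
    "consequence", "protein_change", "pathogenicity", "novel_db", "reported",
]


def write_results_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Write per-variant result rows (1-based positions) in fixed column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS, delimiter="\t", extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
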