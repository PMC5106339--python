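"""Reduce raw variant calls to the clinically analysable set.

Four filters run in a fixed order, and the first one that fires is recorded
as the drop reason:

1. *off_region* — the call lies outside the gene panel's clinical region
   (coding exons ± 5 bp plus configured special intronic sites);
2. *qc_fail* — platform-specific depth/quality thresholds.  The two
   shipped profiles encode the service's validated criteria: SOLiD SNVs need
   ≥18× depth and MQV strictly >18, SOLiD indels >5 alt-supporting reads;
   HiSeq SNVs need ≥50× depth and MQV ≥45, HiSeq indels alt support from
   >25% of aligned reads;
3. *common_polymorphism* — population frequency >1% in a control database,
   provided the database evidence is adequately supported (EVS calls
   additionally require a sufficiently large/diverse cohort and mean read
   depth >18×);
4. *recurrent_artefact* — rare in the databases but recurrent in-house
   above a configurable fraction of the local cohort (run artefacts and
   unannotated local polymorphisms).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .regions import GenomicInterval, Panel, clinical_region
from .variants import GenotypeCall, PatientCase, Variant

DROP_REASONS = ("off_region", "qc_fail", "common_polymorphism", "recurrent_artefact")

COMMON_AF_THRESHOLD = 0.01
EVS_MIN_MEAN_DEPTH = 18.0
DEFAULT_RECURRENCE_THRESHOLD = 0.10


@dataclass(frozen=True, slots=True)
class PlatformQC:
    """Per-platform pass thresholds; exactly one indel rule form is set."""

    platform: str
    snv_min_depth: int
    snv_min_mqv: float
    snv_mqv_strict: bool
    min_alt_reads: int | None = None       # indel rule: alt_reads strictly >
    min_alt_fraction: float | None = None  # indel rule: alt_reads/depth strictly >

    def __post_init__(self) -> None:
        if (self.min_alt_reads is None) == (self.min_alt_fraction is None):
            raise ValueError("exactly one indel rule (reads or fraction) required")
        if self.snv_min_depth <= 0 or self.snv_min_mqv <= 0:
            raise ValueError("thresholds must be positive")


#: The two validated service profiles.
DEFAULT_QC: dict[str, PlatformQC] = {
    "SOLiD": PlatformQC("SOLiD", snv_min_depth=18, snv_min_mqv=18.0,
                        snv_mqv_strict=True, min_alt_reads=5),
    "HiSeq": PlatformQC("HiSeq", snv_min_depth=50, snv_min_mqv=45.0,
                        snv_mqv_strict=False, min_alt_fraction=0.25),
}


def apply_qc(call: GenotypeCall, qc: PlatformQC) -> tuple[bool, str | None]:
    """Return (passes, reason).  Missing metrics fail closed."""
    if call.depth is None or math.isnan(call.mqv):
        return False, "qc_fail(missing_metric)"
    if call.variant.is_indel:
        if qc.min_alt_reads is not None:
            ok = call.alt_reads > qc.min_alt_reads
        else:
            if call.depth == 0:
                return False, "qc_fail(missing_metric)"
            ok = call.alt_reads / call.depth > qc.min_alt_fraction
        return (True, None) if ok else (False, "qc_fail")
    if call.depth < qc.snv_min_depth:
        return False, "qc_fail"
    mqv_ok = call.mqv > qc.snv_min_mqv if qc.snv_mqv_strict else call.mqv >= qc.snv_min_mqv
    return (True, None) if mqv_ok else (False, "qc_fail")


@dataclass(slots=True)
class FrequencyRecord:
    """Population/in-house frequency annotations for one allele.

    ``None`` means "absent from that database" — which is what novelty is
    defined on — not "frequency zero".
    """

    dbsnp_af: float | None = None
    evs_af: float | None = None
    evs_mean_depth: float | None = None
    evs_cohort_ok: bool = False
    exac_af: float | None = None
    inhouse_count: int = 0
    inhouse_cohort_size: int = 0

    def __post_init__(self) -> None:
        for af in (self.dbsnp_af, self.evs_af, self.exac_af):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} outside [0,1]")
        if self.inhouse_count < 0 or self.inhouse_cohort_size < 0:
            raise ValueError("negative in-house counts")


def is_common_polymorphism(freq: FrequencyRecord) -> bool:
    """>1% in a control database counts as a benign polymorphism, with EVS
    evidence additionally requiring adequate cohort and mean depth >18×."""
    if freq.dbsnp_af is not None and freq.dbsnp_af > COMMON_AF_THRESHOLD:
        return True
    return (
        freq.evs_af is not None
        and freq.evs_af > COMMON_AF_THRESHOLD
        and freq.evs_cohort_ok
        and freq.evs_mean_depth is not None
        and freq.evs_mean_depth > EVS_MIN_MEAN_DEPTH
    )


def recurrence_flag(freq: FrequencyRecord, threshold: float = DEFAULT_RECURRENCE_THRESHOLD) -> bool:
    """True when the allele recurs in-house in strictly more than
    ``threshold`` of the local cohort."""
    if freq.inhouse_cohort_size <= 0:
        raise ValueError("in-house cohort size must be positive")
    return freq.inhouse_count / freq.inhouse_cohort_size > threshold


class FrequencyTable:
    """Frequency records keyed by (chrom, pos0, ref, alt); absent keys
    resolve to an all-absent record."""

    def __init__(self, records: dict[tuple[str, int, str, str], FrequencyRecord] | None = None,
                 inhouse_cohort_size: int = 0):
        self.records = records or {}
        self.inhouse_cohort_size = inhouse_cohort_size

    def lookup(self, variant: Variant) -> FrequencyRecord:
        rec = self.records.get(variant.key())
        if rec is None:
            return FrequencyRecord(inhouse_cohort_size=self.inhouse_cohort_size)
        return rec

    @classmethod
    def from_tsv(cls, path: str | Path, inhouse_cohort_size: int = 0) -> "FrequencyTable":
        """TSV columns: chrom, pos (1-based), ref, alt, dbsnp_af, evs_af,
        evs_mean_depth, evs_cohort_ok, exac_af, inhouse_count (last optional).
        Empty/'.' fields mean absent."""
        def opt(v: str) -> float | None:
            v = v.strip()
            return None if v in ("", ".", "NA") else float(v)

        records: dict[tuple[str, int, str, str], FrequencyRecord] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = (row["chrom"], int(row["pos"]) - 1, row["ref"], row["alt"])
                records[key] = FrequencyRecord(
                    dbsnp_af=opt(row.get("dbsnp_af", "")),
                    evs_af=opt(row.get("evs_af", "")),
                    evs_mean_depth=opt(row.get("evs_mean_depth", "")),
                    evs_cohort_ok=row.get("evs_cohort_ok", "").strip().lower()
                    in ("1", "true", "yes"),
                    exac_af=opt(row.get("exac_af", "")),
                    inhouse_count=int(row.get("inhouse_count") or 0),
                    inhouse_cohort_size=inhouse_cohort_size,
                )
        return cls(records, inhouse_cohort_size)


@dataclass(slots=True)
class TriageResult:
    retained: list[GenotypeCall] = field(default_factory=list)
    dropped: list[tuple[GenotypeCall, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.retained) + len(self.dropped)


def _region_tree(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def build_clinical_lookup(panel: Panel) -> dict[str, IntervalTree]:
    """Interval lookup over the union of every gene's clinical region."""
    all_ivs: list[GenomicInterval] = []
    for gene in panel.symbols():
        all_ivs.extend(clinical_region(panel, gene))
    return _region_tree(all_ivs)


def in_clinical_region(variant: Variant, lookup: dict[str, IntervalTree]) -> bool:
    tree = lookup.get(variant.chrom)
    if tree is None:
        return False
    return bool(tree.overlap(variant.pos, max(variant.end, variant.pos + 1)))


def triage_patient(
    case: PatientCase,
    panel: Panel,
    freqs: FrequencyTable,
    qc_table: dict[str, PlatformQC] | None = None,
    recurrence_threshold: float = DEFAULT_RECURRENCE_THRESHOLD,
    region_lookup: dict[str, IntervalTree] | None = None,
) -> TriageResult:
    """Apply the four triage filters in order; partition is conserved."""
    qc_table = qc_table or DEFAULT_QC
    if case.platform not in qc_table:
        raise KeyError(f"no QC profile for platform {case.platform}")
    qc = qc_table[case.platform]
    lookup = region_lookup if region_lookup is not None else build_clinical_lookup(panel)
    result = TriageResult()
    for call in case.calls:
        if not in_clinical_region(call.variant, lookup):
            result.dropped.append((call, "off_region"))
            continue
        ok, reason = apply_qc(call, qc)
        if not ok:
            result.dropped.append((call, reason or "qc_fail"))
            continue
        freq = freqs.lookup(call.variant)
        if is_common_polymorphism(freq):
            result.dropped.append((call, "common_polymorphism"))
            continue
        if freq.inhouse_cohort_size > 0 and recurrence_flag(freq, recurrence_threshold):
            result.dropped.append((call, "recurrent_artefact"))
            continue
        result.retained.append(call)
    assert len(result) == len(case.calls)
    return result


def retrospective_af_summary(
    variants: Sequence[Variant] | Sequence[tuple[str, int, str, str]],
    exac: dict[tuple[str, int, str, str], float],
) -> tuple[float, float, float, float]:
    """(mean, median, max, fraction >1%) of ExAC allele frequencies over the
    given variants; a variant absent from the table counts as AF 0."""
    import numpy as np

    afs = []
    for v in variants:
        key = v.key() if isinstance(v, Variant) else v
        afs.append(exac.get(key, 0.0))
    if not afs:
        return 0.0, 0.0, 0.0, 0.0
    arr = np.asarray(afs, dtype=float)
    return (
        float(arr.mean()),
        float(np.median(arr)),
        float(arr.max()),
        float((arr > COMMON_AF_THRESHOLD).mean()),
    )
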