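"""End-to-end per-patient and per-cohort orchestration.

Wires the stages together: VCF ingest → triage → consequence annotation →
pathogenicity classification → diagnosis and segregation → per-patient
result records ready for cohort reporting.
"""

from __future__ import annotations

import csv
from pathlib import Path

from intervaltree import IntervalTree

from .classify import EvidenceBundle, classify, load_evidence_tsv
from .consequence import annotate, is_novel
from .diagnose import (
    ClassifiedVariant,
    DiagnosisResult,
    FamilyGenotypes,
    apply_segregation,
    call_diagnosis,
    resolve_phase,
)
from .regions import Panel, clinical_region, load_panel
from .report import AnalysedVariant, PatientResult
from .triage import DEFAULT_QC, FrequencyTable, PlatformQC, triage_patient
from .variants import PatientCase, Variant, read_vcf

_CODING_TERMS = frozenset(
    {"missense", "stop_gained", "synonymous", "start_lost",
     "frameshift", "inframe_deletion", "inframe_insertion", "coding_delins"}
)


def build_gene_lookup(panel: Panel) -> dict[str, IntervalTree]:
    """chrom → interval tree whose payloads are gene symbols."""
    trees: dict[str, IntervalTree] = {}
    for gene in panel.symbols():
        for iv in clinical_region(panel, gene):
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gene)
    return trees


def gene_for_variant(variant: Variant, lookup: dict[str, IntervalTree]) -> str | None:
    tree = lookup.get(variant.chrom)
    if tree is None:
        return None
    hits = tree.overlap(variant.pos, max(variant.end, variant.pos + 1))
    if not hits:
        return None
    return sorted(h.data for h in hits)[0]


def variant_uid(v: Variant) -> str:
    return f"{v.chrom}:{v.pos + 1}:{v.ref}:{v.alt}"


def run_patient(
    case: PatientCase,
    panel: Panel,
    freqs: FrequencyTable,
    evidence: dict[tuple[str, int, str, str], EvidenceBundle] | None = None,
    qc_table: dict[str, PlatformQC] | None = None,
    family: FamilyGenotypes | None = None,
    gene_lookup: dict[str, IntervalTree] | None = None,
) -> PatientResult:
    """Run one patient through every stage and package the outcome."""
    evidence = evidence or {}
    lookup = gene_lookup if gene_lookup is not None else build_gene_lookup(panel)
    tri = triage_patient(case, panel, freqs, qc_table or DEFAULT_QC, region_lookup=lookup)

    analysed: list[AnalysedVariant] = []
    classified: list[ClassifiedVariant] = []
    for call in tri.retained:
        gene = gene_for_variant(call.variant, lookup)
        if gene is None:
            continue
        rec = panel[gene]
        cons = annotate(call.variant, rec, panel.special_sites_for(gene))
        freq = freqs.lookup(call.variant)
        ev = evidence.get(call.variant.key(), EvidenceBundle())
        pclass = classify(cons, rec, freq, ev)
        cv = ClassifiedVariant(
            variant=call.variant,
            gene=gene,
            zygosity=call.zygosity,
            pathogenicity=pclass,
            consequence_term=cons.term,
            truncating=cons.truncating,
            novel_db=is_novel(call.variant, freq),
        )
        classified.append(cv)
        analysed.append(
            AnalysedVariant(
                uid=variant_uid(call.variant),
                gene=gene,
                vclass=call.variant.vclass,
                zygosity=call.zygosity,
                term=cons.term,
                truncating=cons.truncating,
                novel_db=cv.novel_db,
                pathogenicity=pclass,
                coding_indel=call.variant.is_indel and cons.term in _CODING_TERMS,
                exac_af=freq.exac_af,
            )
        )

    diagnosis = call_diagnosis(case, classified, panel)
    if (
        family is not None
        and diagnosis.mode == "AR"
        and len(diagnosis.causal_variants) == 2
        and all(cv.zygosity == "het" for cv in diagnosis.causal_variants)
    ):
        phase, _ = resolve_phase(tuple(diagnosis.causal_variants), family)
        diagnosis = apply_segregation(diagnosis, phase)

    reported_keys = {variant_uid(cv.variant) for cv in diagnosis.causal_variants}
    for av in analysed:
        av.reported = av.uid in reported_keys
    return PatientResult.from_pipeline(case, tri, analysed, diagnosis)


# ---------------------------------------------------------------------------
# cohort-directory convenience (the layout the synthetic simulator emits)


def load_families_tsv(path: str | Path) -> dict[str, FamilyGenotypes]:
    """TSV columns: proband_id, role, chrom, pos (1-based), ref, alt, zygosity.

    Zygosity ``ref`` marks a relative genotyped and negative for the allele:
    the role is registered (so phase can be resolved) without recording a
    carried variant.
    """
    fams: dict[str, FamilyGenotypes] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["proband_id"]
            fam = fams.setdefault(pid, FamilyGenotypes(proband_id=pid))
            genotypes = fam.relatives.setdefault(row["role"], {})
            if row["zygosity"] not in ("ref", "0/0", "negative"):
                key = (row["chrom"], int(row["pos"]) - 1, row["ref"], row["alt"])
                genotypes[key] = row["zygosity"]
    return fams


def run_cohort(cohort_dir: str | Path) -> list[PatientResult]:
    """Run every patient in a simulator-emitted cohort directory."""
    d = Path(cohort_dir)
    panel = load_panel(d / "panel.tsv", d / "cds.fasta", d / "special_sites.tsv")
    with open(d / "patients.tsv", newline="") as fh:
        patients = list(csv.DictReader(fh, delimiter="\t"))
    freqs = FrequencyTable.from_tsv(d / "freq.tsv", inhouse_cohort_size=len(patients))
    evidence = load_evidence_tsv(d / "evidence.tsv")
    fam_path = d / "families.tsv"
    families = load_families_tsv(fam_path) if fam_path.exists() else {}
    lookup = build_gene_lookup(panel)
    results = []
    for row in patients:
        case = read_vcf(
            d / row["vcf"],
            patient_id=row["patient_id"],
            sex=row["sex"],
            referral_category=row["referral_category"],
            platform=row["platform"],
        )
        results.append(
            run_patient(
                case, panel, freqs, evidence,
                family=families.get(row["patient_id"]),
                gene_lookup=lookup,
            )
        )
    return results
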