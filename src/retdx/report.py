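"""Cohort-level aggregation: screening-burden tables, diagnostic yield,
novelty percentages, gene spectrum and gene-discovery-year analysis.

The central container is :class:`PatientResult` — one patient's journey
through the pipeline: raw-call tallies, the clinically analysed variants
with their annotations and classes, and the diagnosis outcome.  The
reporting operations only ever *recount* these records; every printed
percentage is recomputed with round-half-up at the conventional precision
(whole percents; rates to one decimal).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .diagnose import DiagnosisResult
from .regions import Panel
from .triage import TriageResult
from .variants import PatientCase

STAGES = ("raw", "analysed", "reported")
CLASS_GROUPS = ("SNV", "indel")
ZYGOSITIES = ("hom", "het", "hemi", "het_het")

#: gene-discovery era bins (label, first year, last year inclusive)
DEFAULT_ERA_BINS = (
    ("pre-1995", 1980, 1994),
    ("1995-2004", 1995, 2004),
    ("post-2005", 2005, 2016),
)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal precision (the
    convention used for all printed percentages and rates)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass(slots=True)
class AnalysedVariant:
    """One clinically analysed variant occurrence in one patient."""

    uid: str                      # shared across patients carrying the same allele
    gene: str
    vclass: str                   # SNV | insertion | deletion | delins
    zygosity: str
    term: str                     # consequence term
    truncating: bool = False
    novel_db: bool = False        # absent from both dbSNP and EVS
    novel_cause: bool = False     # novel as a cause of disease (literature)
    reported: bool = False        # clinically reported as (potential) cause
    pathogenicity: str = "vus"
    coding_indel: bool = False    # indel footprint overlaps the CDS
    exac_af: float | None = None
    reported_zygosity: str | None = None  # confirmed zygosity, when it differs
                                          # from the pileup estimate

    @property
    def class_group(self) -> str:
        return "SNV" if self.vclass == "SNV" else "indel"


@dataclass(slots=True)
class PatientResult:
    patient_id: str
    referral_category: str
    raw_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    analysed: list[AnalysedVariant] = field(default_factory=list)
    diagnosis: DiagnosisResult | None = None
    n_carrier_findings: int = 0

    @classmethod
    def from_pipeline(
        cls,
        case: PatientCase,
        triage_result: TriageResult,
        analysed: list[AnalysedVariant],
        diagnosis: DiagnosisResult,
    ) -> "PatientResult":
        raw = Counter()
        for call in case.calls:
            grp = "SNV" if call.variant.vclass == "SNV" else "indel"
            raw[(grp, call.zygosity)] += 1
        return cls(
            patient_id=case.patient_id,
            referral_category=case.referral_category,
            raw_counts=dict(raw),
            analysed=analysed,
            diagnosis=diagnosis,
            n_carrier_findings=len(diagnosis.carrier_findings),
        )


def _empty_table() -> dict[str, dict[str, dict[str, int]]]:
    return {
        stage: {grp: {z: 0 for z in ZYGOSITIES} for grp in CLASS_GROUPS}
        for stage in STAGES
    }


@dataclass(slots=True)
class CohortSummary:
    counts: dict = field(default_factory=_empty_table)
    n_patients: int = 0
    novel_analysed: dict = field(default_factory=dict)      # class group → (novel, total)
    novel_by_term: Counter = field(default_factory=Counter)  # analysed novel SNV terms
    novel_coding_indels: int = 0
    novel_splice_indels: int = 0
    coding_indels: int = 0
    splice_flank_indels: int = 0
    truncating_indels: dict = field(default_factory=dict)    # zygosity → count
    unique_reported: dict = field(default_factory=dict)      # uid → summary dict

    def stage_total(self, stage: str, grp: str | None = None) -> int:
        grps = [grp] if grp else list(CLASS_GROUPS)
        return sum(self.counts[stage][g][z] for g in grps for z in ZYGOSITIES)

    def row(self, stage: str, grp: str | None = None) -> tuple[int, int, int, int, int]:
        """(hom, het, hemi, het_het, total) — the screening-table row shape."""
        grps = [grp] if grp else list(CLASS_GROUPS)
        cells = tuple(sum(self.counts[stage][g][z] for g in grps) for z in ZYGOSITIES)
        return cells + (sum(cells),)


def tabulate(cohort: list[PatientResult]) -> CohortSummary:
    """Exact tallies over a cohort's per-patient results."""
    s = CohortSummary(n_patients=len(cohort))
    novel = {g: [0, 0] for g in CLASS_GROUPS}
    trunc_indels = Counter()
    for pr in cohort:
        for (grp, zyg), n in pr.raw_counts.items():
            s.counts["raw"][grp][zyg] += n
        for av in pr.analysed:
            grp = av.class_group
            s.counts["analysed"][grp][av.zygosity] += 1
            novel[grp][1] += 1
            if av.novel_db:
                novel[grp][0] += 1
                if grp == "SNV":
                    s.novel_by_term[av.term] += 1
                elif av.coding_indel:
                    s.novel_coding_indels += 1
                else:
                    s.novel_splice_indels += 1
            if grp == "indel":
                if av.coding_indel:
                    s.coding_indels += 1
                    if av.truncating:
                        trunc_indels[av.zygosity] += 1
                else:
                    s.splice_flank_indels += 1
            if av.reported:
                s.counts["reported"][grp][av.reported_zygosity or av.zygosity] += 1
                u = s.unique_reported.setdefault(
                    av.uid,
                    {
                        "gene": av.gene, "term": av.term, "truncating": av.truncating,
                        "novel_db": av.novel_db, "novel_cause": av.novel_cause,
                        "class_group": grp, "n_occurrences": 0,
                    },
                )
                u["n_occurrences"] += 1
    s.novel_analysed = {g: tuple(v) for g, v in novel.items()}
    s.truncating_indels = dict(trunc_indels)
    # sanity: analysed ⊆ raw cell-wise.  Reported is checked per class group
    # only: reported zygosity is re-confirmed by an orthogonal assay and can
    # legitimately disagree with the pileup estimate in individual cells.
    for grp in CLASS_GROUPS:
        for z in ZYGOSITIES:
            if s.counts["raw"][grp][z] and s.counts["analysed"][grp][z] > s.counts["raw"][grp][z]:
                raise ValueError(f"analysed exceeds raw for {grp}/{z}")
        if s.stage_total("reported", grp) > s.stage_total("analysed", grp):
            raise ValueError(f"reported exceeds analysed for {grp}")
    return s


def reported_consequence_counts(summary: CohortSummary) -> Counter:
    """Unique reported mutations by consequence term."""
    return Counter(u["term"] for u in summary.unique_reported.values())


def reported_novelty(summary: CohortSummary) -> dict[str, tuple[int, int]]:
    """(novel-in-databases, total) unique reported mutations, overall and by
    key consequence groups, plus literature novelty of truncating events."""
    uniq = list(summary.unique_reported.values())
    def split(pred):
        sel = [u for u in uniq if pred(u)]
        return (sum(1 for u in sel if u["novel_db"]), len(sel))

    # "truncating" here is the premature-termination class: nonsense SNVs
    # plus out-of-frame indels (start-loss disrupts initiation, not
    # termination, and is tallied separately)
    truncating = [u for u in uniq if u["term"] in ("stop_gained", "frameshift")]
    return {
        "all": split(lambda u: True),
        "missense": split(lambda u: u["term"] == "missense"),
        "stop_gained": split(lambda u: u["term"] == "stop_gained"),
        "frameshift": split(lambda u: u["term"] == "frameshift"),
        "truncating_novel_cause": (
            sum(1 for u in truncating if u["novel_cause"]),
            len(truncating),
        ),
    }


def yield_stats(cohort: list[PatientResult]) -> dict:
    """Diagnosis counts by status and mode; yield as a fraction of referrals."""
    n = len(cohort)
    by_mode = Counter()
    by_status = Counter()
    ar_detail = Counter()
    carrier_individuals = 0
    for pr in cohort:
        d = pr.diagnosis
        if pr.n_carrier_findings > 0:
            carrier_individuals += 1
        if d is None or d.status == "none":
            continue
        by_status[d.status] += 1
        by_mode[d.mode] += 1
        if d.mode == "AR":
            hom = any(cv.zygosity == "hom" for cv in d.causal_variants if cv.pathogenic)
            ar_detail["hom" if hom else "comphet"] += 1
    n_diag = sum(by_status.values())
    return {
        "n_patients": n,
        "n_diagnosed": n_diag,
        "yield": n_diag / n if n else 0.0,
        "by_status": dict(by_status),
        "by_mode": dict(by_mode),
        "ar_detail": dict(ar_detail),
        "carrier_individuals": carrier_individuals,
    }


def mean_per_patient(count: int, n_patients: int, decimals: int = 1) -> float:
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return round_half_up(count / n_patients, decimals)


@dataclass(slots=True)
class GeneYearSummary:
    eras: list[dict] = field(default_factory=list)
    total_diagnoses: int = 0


def discovery_year_rates(
    diagnoses_by_gene: dict[str, int],
    panel: Panel,
    era_bins: tuple = DEFAULT_ERA_BINS,
) -> GeneYearSummary:
    """Diagnoses per gene and share of diagnoses, binned by the diagnosed
    genes' discovery eras."""
    total = sum(diagnoses_by_gene.values())
    for gene in diagnoses_by_gene:
        if gene not in panel:
            raise KeyError(f"gene {gene} not in panel")
    out = GeneYearSummary(total_diagnoses=total)
    for label, lo, hi in era_bins:
        genes = [g for g in panel.symbols() if lo <= panel[g].discovery_year <= hi]
        n_diag = sum(diagnoses_by_gene.get(g, 0) for g in genes)
        out.eras.append(
            {
                "era": label,
                "n_genes": len(genes),
                "n_diagnoses": n_diag,
                "diagnoses_per_gene": round_half_up(n_diag / len(genes), 1) if genes else 0.0,
                "pct_of_diagnoses": pct(n_diag, total) if total else 0.0,
            }
        )
    if sum(e["n_diagnoses"] for e in out.eras) != total:
        raise ValueError("era bins do not cover every diagnosed gene's discovery year")
    return out


def gene_spectrum(cohort: list[PatientResult]) -> dict:
    """Partition diagnosed genes by how many distinct referral categories
    their diagnosed patients span."""
    per_gene_patients = Counter()
    per_gene_categories: dict[str, set] = {}
    for pr in cohort:
        d = pr.diagnosis
        if d is None or d.status == "none":
            continue
        per_gene_patients[d.gene] += 1
        per_gene_categories.setdefault(d.gene, set()).add(pr.referral_category)
    single = sorted(g for g, cats in per_gene_categories.items() if len(cats) == 1)
    multi = sorted(g for g, cats in per_gene_categories.items() if len(cats) > 1)
    return {
        "n_genes": len(per_gene_categories),
        "patients_per_gene": dict(per_gene_patients),
        "categories_per_gene": {g: sorted(c) for g, c in per_gene_categories.items()},
        "single_category_genes": single,
        "cross_category_genes": multi,
    }
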