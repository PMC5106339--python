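"""Inheritance-aware molecular diagnosis, carrier findings and segregation.

Per gene, variants on the pathogenic spectrum (clearly/likely pathogenic)
establish a *disease state* when they match the gene's inheritance mode:

* AR — homozygous pathogenic, or two heterozygous alleles
  (pathogenic + pathogenic → confirmed; pathogenic + VUS → provisional);
* AD — at least one het/hom pathogenic → confirmed;
* XL — hemizygous pathogenic in a male → confirmed.

A single heterozygous pathogenic allele in a recessive gene is a carrier
finding, as is a het pathogenic allele in an X-linked gene in a female.
Disease states in more than one gene trigger multidisciplinary-team (MDT)
review and no automatic status — the engine flags, it never arbitrates.
Phenotype concordance compares the diagnosed gene's associated referral
categories with the patient's referral.

Family genotypes resolve the phase of compound-het pairs (in-trans
supports the diagnosis; in-cis withdraws it, leaving two carrier findings)
and expose de novo alleles absent from both genotyped parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .classify import PATHOGENIC_SPECTRUM
from .regions import Panel
from .variants import PatientCase, Variant


@dataclass(slots=True)
class ClassifiedVariant:
    """A triage-retained call with its consequence and pathogenicity class."""

    variant: Variant
    gene: str
    zygosity: str
    pathogenicity: str
    consequence_term: str = ""
    truncating: bool = False
    novel_db: bool = False

    @property
    def pathogenic(self) -> bool:
        return self.pathogenicity in PATHOGENIC_SPECTRUM


@dataclass(slots=True)
class DiagnosisResult:
    status: str = "none"  # confirmed | provisional | none
    mode: str | None = None
    gene: str | None = None
    causal_variants: list[ClassifiedVariant] = field(default_factory=list)
    phase_confirmed: bool = False
    phenotype_concordant: bool = True
    mdt_review: bool = False
    carrier_findings: list[tuple[str, ClassifiedVariant]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("confirmed", "provisional", "none"):
            raise ValueError(f"bad status {self.status}")
        if self.status != "none" and (self.gene is None or self.mode is None):
            raise ValueError("a diagnosis requires gene and mode")


@dataclass(slots=True)
class FamilyGenotypes:
    """Zygosity of the proband's variants in genotyped relatives.

    ``relatives`` maps role ("mother", "father", ...) → {variant key →
    zygosity}; a variant key absent from a genotyped relative's map means
    the relative tested negative for it.
    """

    proband_id: str
    relatives: dict[str, dict[tuple[str, int, str, str], str]] = field(default_factory=dict)

    def carries(self, role: str, variant: Variant) -> bool | None:
        """True/False if the relative was genotyped, None otherwise."""
        if role not in self.relatives:
            return None
        return variant.key() in self.relatives[role]


def _gene_disease_state(
    mode_set: frozenset[str],
    sex: str,
    variants: list[ClassifiedVariant],
) -> tuple[str, str | None, list[ClassifiedVariant]]:
    """(status, mode, causal variants) for one gene's classified variants."""
    path = [v for v in variants if v.pathogenic]
    vus = [v for v in variants if v.pathogenicity == "vus"]

    if "AR" in mode_set:
        hom_path = [v for v in path if v.zygosity == "hom"]
        het_path = [v for v in path if v.zygosity == "het"]
        het_vus = [v for v in vus if v.zygosity == "het"]
        if hom_path or len(het_path) >= 2:
            return "confirmed", "AR", sorted(path, key=lambda v: v.variant.pos)
        if len(het_path) == 1 and het_vus:
            return "provisional", "AR", sorted(
                [het_path[0], min(het_vus, key=lambda v: v.variant.pos)],
                key=lambda v: v.variant.pos,
            )
    if "AD" in mode_set:
        ad_path = [v for v in path if v.zygosity in ("het", "hom")]
        if ad_path:
            return "confirmed", "AD", sorted(ad_path, key=lambda v: v.variant.pos)
    if "XL" in mode_set and sex == "M":
        hemi_path = [v for v in path if v.zygosity == "hemi"]
        if hemi_path:
            return "confirmed", "XL", sorted(hemi_path, key=lambda v: v.variant.pos)
    return "none", None, []


def call_diagnosis(
    case: PatientCase,
    classified: list[ClassifiedVariant],
    panel: Panel,
) -> DiagnosisResult:
    """Combine per-gene disease states into one patient-level result."""
    by_gene: dict[str, list[ClassifiedVariant]] = {}
    for cv in classified:
        if not cv.pathogenicity:
            raise ValueError(f"unclassified variant {cv.variant}")
        if cv.gene not in panel:
            raise KeyError(f"gene {cv.gene} not in panel")
        by_gene.setdefault(cv.gene, []).append(cv)

    disease_states: list[tuple[str, str, str, list[ClassifiedVariant]]] = []
    carriers: list[tuple[str, ClassifiedVariant]] = []
    for gene in sorted(by_gene):
        rec = panel[gene]
        status, mode, causal = _gene_disease_state(rec.inheritance_modes, case.sex, by_gene[gene])
        if status != "none":
            disease_states.append((gene, status, mode, causal))
            continue
        for cv in by_gene[gene]:
            if not cv.pathogenic:
                continue
            if "AR" in rec.inheritance_modes and cv.zygosity == "het":
                carriers.append((gene, cv))
            elif "XL" in rec.inheritance_modes and cv.zygosity in ("het", "hom") and case.sex == "F":
                carriers.append((gene, cv))

    result = DiagnosisResult(carrier_findings=carriers)
    if len(disease_states) > 1:
        result.mdt_review = True  # competing disease states: flag, never resolve
        return result
    if not disease_states:
        return result
    gene, status, mode, causal = disease_states[0]
    result.status = status
    result.mode = mode
    result.gene = gene
    result.causal_variants = causal
    result.phenotype_concordant = case.referral_category in panel[gene].phenotype_categories
    return result


def resolve_phase(
    pair: tuple[ClassifiedVariant, ClassifiedVariant] | tuple[Variant, Variant],
    fam: FamilyGenotypes,
) -> tuple[str, dict[tuple[str, int, str, str], bool]]:
    """Phase two proband-het variants from parental genotypes.

    Returns (phase, de_novo flags keyed by variant).  Phase is in_trans when
    each allele traces to a different parent, in_cis when both trace to the
    same parent, unresolved when either parent is ungenotyped.  An allele
    absent from both genotyped parents is flagged de novo.
    """
    variants = tuple(p.variant if isinstance(p, ClassifiedVariant) else p for p in pair)
    de_novo: dict[tuple[str, int, str, str], bool] = {}
    parent_of: dict[int, set[str]] = {0: set(), 1: set()}
    both_typed = all(fam.carries(role, variants[0]) is not None for role in ("mother", "father"))
    for i, v in enumerate(variants):
        carriers = set()
        statuses = {role: fam.carries(role, v) for role in ("mother", "father")}
        for role, st in statuses.items():
            if st:
                carriers.add(role)
        parent_of[i] = carriers
        de_novo[v.key()] = both_typed and not carriers
    if not both_typed:
        return "unresolved", de_novo
    if any(de_novo.values()):
        return "unresolved", de_novo
    if parent_of[0] and parent_of[1]:
        if parent_of[0] != parent_of[1]:
            return "in_trans", de_novo
        if len(parent_of[0]) == 1:  # both alleles from the same single parent
            return "in_cis", de_novo
        # both parents carry both alleles: exclusion logic cannot phase
        return "unresolved", de_novo
    return "unresolved", de_novo


def apply_segregation(result: DiagnosisResult, phase: str) -> DiagnosisResult:
    """Update a compound-het diagnosis after phasing.

    in_trans confirms the configuration; in_cis withdraws the recessive
    diagnosis and reclassifies both alleles as carrier findings.
    """
    if phase == "in_trans":
        return replace(result, phase_confirmed=True)
    if phase == "in_cis":
        gene = result.gene
        new_carriers = list(result.carrier_findings) + [
            (gene, cv) for cv in result.causal_variants
        ]
        return DiagnosisResult(
            status="none",
            mode=None,
            gene=None,
            causal_variants=[],
            phase_confirmed=False,
            phenotype_concordant=True,
            mdt_review=result.mdt_review,
            carrier_findings=new_carriers,
        )
    return result
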