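"""Rule-based pathogenicity classification, ACMG-aligned.

The cascade runs severity-first; the first matching rule decides:

a. common polymorphism (>1% with adequate database support) → benign;
b. truncating consequence in a gene with an established loss-of-function
   disease mechanism → clearly_pathogenic if previously reported,
   likely_pathogenic if novel;
c. functional evidence of protein disruption → clearly_pathogenic;
d. prior disease-segregation report in the literature → likely_pathogenic;
e. a different pathogenic substitution at the same residue, concordant
   damaging in-silico predictions and a matching phenotype →
   likely_pathogenic;
f. novel missense with concordant damaging in-silico predictions and a
   matching phenotype → VUS (awaiting segregation/functional work);
g. otherwise VUS, unless the in-silico predictions are concordantly
   benign → likely_benign.

Evidence flags are inputs (curated per variant), not literature lookups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .consequence import Consequence
from .regions import GeneRecord
from .triage import FrequencyRecord, is_common_polymorphism

PATHOGENICITY_ORDER = ("benign", "likely_benign", "vus", "likely_pathogenic", "clearly_pathogenic")
RANK = {c: i for i, c in enumerate(PATHOGENICITY_ORDER)}
PATHOGENIC_SPECTRUM = frozenset({"clearly_pathogenic", "likely_pathogenic"})
INSILICO_VALUES = ("concordant_damaging", "conflicting", "concordant_benign", "unavailable")


@dataclass(frozen=True, slots=True)
class EvidenceBundle:
    functional_support: bool = False
    prior_segregation_report: bool = False
    same_residue_alternative: bool = False
    insilico_damaging: str = "unavailable"
    phenotype_match: bool = False
    novel: bool = False

    def __post_init__(self) -> None:
        if self.insilico_damaging not in INSILICO_VALUES:
            raise ValueError(f"bad insilico value {self.insilico_damaging}")


def classify(
    cons: Consequence,
    gene: GeneRecord,
    freq: FrequencyRecord,
    ev: EvidenceBundle,
) -> str:
    """Assign one pathogenicity class; a pure function of its inputs."""
    if cons is None:
        raise ValueError("missing consequence")
    if is_common_polymorphism(freq):
        return "benign"
    if cons.truncating and gene.lof_mechanism:
        return "likely_pathogenic" if ev.novel else "clearly_pathogenic"
    if ev.functional_support:
        return "clearly_pathogenic"
    if ev.prior_segregation_report:
        return "likely_pathogenic"
    if (
        ev.same_residue_alternative
        and ev.insilico_damaging == "concordant_damaging"
        and ev.phenotype_match
    ):
        return "likely_pathogenic"
    if (
        ev.novel
        and cons.term == "missense"
        and ev.insilico_damaging == "concordant_damaging"
        and ev.phenotype_match
    ):
        return "vus"
    if ev.insilico_damaging == "concordant_benign":
        return "likely_benign"
    return "vus"


def load_evidence_tsv(path: str | Path) -> dict[tuple[str, int, str, str], EvidenceBundle]:
    """Evidence keyed by (chrom, pos 1-based in file → 0-based key, ref, alt).

    Columns: chrom, pos, ref, alt, functional_support,
    prior_segregation_report, same_residue_alternative, insilico_damaging,
    phenotype_match, novel.  Boolean columns accept 1/0, true/false, yes/no.
    """
    def flag(v: str) -> bool:
        return v.strip().lower() in ("1", "true", "yes")

    out: dict[tuple[str, int, str, str], EvidenceBundle] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["chrom"], int(row["pos"]) - 1, row["ref"], row["alt"])
            out[key] = EvidenceBundle(
                functional_support=flag(row["functional_support"]),
                prior_segregation_report=flag(row["prior_segregation_report"]),
                same_residue_alternative=flag(row["same_residue_alternative"]),
                insilico_damaging=row["insilico_damaging"].strip() or "unavailable",
                phenotype_match=flag(row["phenotype_match"]),
                novel=flag(row["novel"]),
            )
    return out
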