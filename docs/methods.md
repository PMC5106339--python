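# Methods

`retdx` re-implements the decision logic of a targeted-panel diagnostic
service for inherited retinal disease (IRD): a 105-gene capture assay whose
per-patient variant calls are triaged, annotated, classified and combined
into inheritance-aware molecular diagnoses. This note records the model,
its assumptions, the tunable parameters, what the synthetic data do and do
not emulate, and the numerical conventions.

## The pipeline model

A patient arrives as a single-sample VCF plus referral metadata (sex, one
of ten clinical referral classifications, sequencing platform). Each
alternate allele becomes one genotype call with a zygosity in
{hom, het, hemi, het–het} — hemi for a single allele on male chrX, het–het
for a site carrying two distinct alternate alleles — and the platform
quality metrics the service thresholds on (depth, mean quality value MQV,
alt-supporting reads).

**Triage** applies four filters in a fixed order, recording the first that
fires:

1. *Region.* Interpretation is restricted to coding exon segments ±5 bp
   per panel gene, plus configured special intronic sites (the CEP290
   deep-intronic hotspot that harbours the recurrent c.2991+1655A>G
   allele). The capture itself targets ±50 bp; the wider window is exposed
   as the enrichment region. Coordinates are 0-based half-open internally;
   VCF positions convert on ingest.
2. *Platform QC.* Two validated profiles ship as defaults. SOLiD: SNVs
   need depth ≥18 and MQV strictly >18; indels need strictly >5
   alt-supporting reads. HiSeq: SNVs need depth ≥50 and MQV ≥45
   (inclusive); indels need alt support from strictly >25% of reads.
   Missing metrics fail closed. Boundaries are asserted exactly in the
   acceptance suite.
3. *Population frequency.* An allele with frequency >1% in a control
   database is a benign polymorphism — for EVS-style evidence only when
   the cohort is adequately large/diverse (an input flag; no numeric
   criterion exists) and the database's mean read depth exceeds 18×.
   Absence from a database is represented as `None`, distinct from
   frequency zero, because novelty is defined on absence.
4. *In-house recurrence.* Rare-in-databases alleles recurring in more
   than a configurable fraction (default 0.10) of the local cohort are
   treated as run artefacts or unannotated local polymorphisms. The
   default is a judgement call; the service describes only a "high"
   recurrence rate.

QC-failed calls are never frequency-tested; the retained set is invariant
to filter order (only the recorded drop reasons depend on it), which the
suite checks against independently applied predicates.

**Consequence annotation** works against one designated transcript per
gene. Coding SNVs mutate the affected codon of the spliced CDS on the
coding strand and compare translations (synonymous / missense /
stop_gained / start_lost); intronic SNVs at ±1–2 are canonical splice-site
and at ±3–5 splice-region changes — the splice-region window is tied to
the ±5 bp analysis window, exonic splice-region terms are not used. Indels
overlapping the CDS are frameshift when the length change is not a
multiple of three, otherwise in-frame; length-preserving substitutions
(coding_delins) are truncating only if re-translation gains a premature
stop. Junction-spanning events take the more severe term
(stop_gained > frameshift > canonical_splice > …). The annotator carries
its own genetic-code table; the test oracle independently splices, mutates
and translates via Biopython.

**Classification** is an ACMG-aligned severity-first cascade over curated
evidence flags (functional support, prior segregation report, alternative
pathogenic substitution at the same residue, concordance of in-silico
predictions, phenotype match, literature novelty): common polymorphism →
benign; truncating consequence in a gene with an established
loss-of-function mechanism → clearly pathogenic if previously reported,
likely pathogenic if novel; functional support → clearly pathogenic;
segregation report → likely pathogenic; same-residue + concordant
damaging + phenotype match → likely pathogenic; novel damaging missense
with matching phenotype → VUS; otherwise VUS, or likely benign under
concordantly benign predictions. Synonymous and splice-region variants
therefore reach pathogenic classes only through functional or segregation
evidence. Evidence flags are inputs; the package performs no literature or
in-silico computation. Adding positive evidence can never demote a class
(property-tested).

**Diagnosis** collects pathogenic-spectrum variants per gene: AR — hom
pathogenic or two het alleles (pathogenic+pathogenic confirmed,
pathogenic+VUS provisional); AD — any het/hom pathogenic confirmed; XL —
hemi pathogenic in a male confirmed. A single het pathogenic allele in a
recessive gene (or a het pathogenic XL allele in a female) is a carrier
finding. Disease states in more than one gene raise an MDT-review flag
with no automatic status: the engine flags, it never arbitrates.
Compound-het diagnoses issued without family data carry
`phase_confirmed=False` rather than being demoted (the service reported
ahead of cascade testing). Parental genotypes resolve phase by exclusion:
alleles from different parents → in-trans (phase confirmed); both from one
parent → in-cis, which withdraws the recessive diagnosis and converts both
alleles to carrier findings; a missing parental genotype → unresolved; an
allele absent from both genotyped parents is flagged de novo (and the pair
left unresolved, since exclusion logic no longer applies). Phenotype
concordance compares the diagnosed gene's referral categories with the
patient's referral; a diagnosis stands even when discordant (the
choroideremia-in-an-RP-referral pattern) but is flagged.

**Coverage QC** computes the fraction of region bases at or above a depth
threshold and maximal sub-threshold runs of a minimum length — the
capillary-fallback trigger, exemplified by a 460-base <50× run inside a
76.20%-GC coding exon of GUCY2D. Both per-gene-mean and pooled fractions
are emitted because cohort summaries are quoted both ways.

## The synthetic panel

Real assay coordinates are not redistributable, so the canonical panel is
synthetic geometry under real gene symbols for the genes the findings
concern (ABCA4, CERKL, EYS, RHO, CHM, GUCY2D, CEP290, USH2A, PRPF31) plus
96 placeholder genes, with the assay's published discovery-era composition
(7 genes pre-1995, 65 in 1995–2004, 33 post-2005) and a mode mix
sufficient for every diagnosis pattern. All transcripts are plus-strand,
three-exon, with CDS covering the exons; reverse-strand correctness is
covered by dedicated toy-transcript tests instead. GUCY2D carries the
GC-rich 731-base central exon by construction (557 G/C bases).

## The simulator

`simulate_cohort` emits everything the pipeline reads (per-patient VCFs,
panel TSV + FASTA, frequency/evidence/family/depth TSVs) plus a truth
JSON. Defaults are the study conditions: 537 patients, 235:302
SOLiD:HiSeq, mean 268 raw calls/patient, planted causal genotype with
probability 0.505 (mode mix 88:120:50:13), carrier probability 0.287.
Background calls fall off-region with probability 0.05, fail QC with 0.01
and are common polymorphisms with 0.9706 — chosen once so that ≈8.4
variants per patient survive triage. Background alleles are drawn from
shared per-gene pools (common, rare, database-absent) so recurrence
behaves like a cohort; allele frequencies follow the rare/common mixture
(log-uniform 10⁻⁵–10⁻² / uniform 0.011–0.5). Per-patient substreams are
keyed by seed plus a CRC of the patient id, so a cohort subset reproduces
its patients exactly.

Deliberate departures from real data, and hence the limits of what passing
tests show: background consequences are never truncating (planted
genotypes are the only pathogenic signal); under the `definitive` evidence
profile, background variants also avoid each patient's planted genes, so
truth recovery is exact by design — a background VUS het landing in a
planted carrier's gene would legitimately upgrade to a provisional
diagnosis, which the `realistic` profile permits (it also grades some
comphet partner alleles as VUS, producing provisional diagnoses). No
read-level error model, no het–het sites, no multi-transcript genes, no
digenic signal.

## The worked-example cohort

The service's per-patient data are not public, so the reporting layer is
exercised on a deterministic 537-patient cohort that encodes the published
marginal totals (screening-table rows, diagnosis and carrier counts,
unique-mutation spectrum, novelty splits, coding/truncating indel counts,
era split, population re-annotation summaries — itemised in
`retdx/fixture.py`). Diagnoses are produced by running the real diagnosis
engine over the encoded classified variants, and every reported statistic
is recomputed by recounting; nothing is asserted that the code does not
itself tally. Where the source tallies are mutually inconsistent, the
self-consistent subset is encoded: the reported-variant zygosity row uses
assay-confirmed zygosity (four frameshift alleles are pileup-het but
confirmed hom, so the reported row is not a cell-wise subset of the
analysed row); the overall reported-novelty fraction implied by the
per-consequence splits (173/311) is used rather than the separately quoted
smaller figure; two derived means whose printed rounding is inconsistent
with round-half-up (total variants/patient, overall yield percentage) are
reported as raw counts instead.

Free choices below the printed precision: which patient carries which
allele; the recurrence histogram beyond the named recurrent alleles
(recurrent occurrences are absorbed by per-gene founder alleles, e.g. an
11-patient CERKL missense and 5-patient CERKL nonsense); the assignment of
the high ExAC frequencies (7 × 0.78 + 0.76 on reported alleles and a
solved constant ≈0.522 on 509 analysed occurrences, which jointly satisfy
the mean-0.12 / 517-above-1% / mean-0.02 / median-0 / max-0.78
constraints); undiagnosed patients' referral categories.

## Numerical conventions

* Printed percentages and rates use round-half-up (`decimal`): whole
  percents, one decimal for per-patient means and per-gene rates.
* Interval merging treats touching intervals as mergeable; merging is
  idempotent and order-independent (property-tested against a position-set
  oracle).
* Allele normalization right-trims shared trailing bases, left-extends
  from the reference through transiently empty alleles, then trims shared
  prefixes — the canonical left-alignment; it is idempotent and
  haplotype-preserving (checked against a string-splice oracle and
  exhaustive placement enumeration).
* Degenerate inputs: empty regions, zero-patient cohorts, zero in-house
  cohort sizes and missing QC metrics raise or fail closed rather than
  defaulting.

## Problem sizes

The default test run simulates 200 patients (≈54k raw calls) once,
session-scoped, and pushes them through the full pipeline; the
consequence-annotation oracle checks 1000 random coding SNVs across random
transcripts on both strands. The worked-example cohort builds in well
under a second, so the acceptance script completes in seconds.

## Known limitations

* One designated transcript per gene; no multi-transcript consequence
  sets, NMD prediction or full HGVS validation.
* The classifier consumes curated evidence flags; it does not mine
  literature or run SIFT/PolyPhen.
* MDT-flagged patients receive no automatic status; resolving competing
  disease states is out of scope by design.
* The two platform coverage percentages quoted for the real cohort
  (98.4%/97.3%) depend on real read data; the coverage module reproduces
  the computation, not those numbers.
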