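"""Synthetic-cohort simulator with known truth.

Emits exactly the file formats the pipeline consumes — per-patient VCFs,
panel TSV + CDS/genome FASTA, population-frequency TSV, curated-evidence
TSV, family genotype TSV, per-base depth TSV — plus a truth JSON so every
stage can be tested end-to-end without any external data.

The default configuration reproduces the service's study conditions: 537
referrals (235 SOLiD / 302 HiSeq), a mean of 268 raw calls per patient of
which ~8.4 survive triage, a 50.5% chance of a planted causal genotype
(mode mix 88 AR-hom : 120 AR-comphet : 50 AD : 13 XL) and a 28.7% carrier
rate.  Background variants are drawn from shared per-gene pools (common
>1%, rare, and database-absent novel alleles) so recurrence behaves like a
real cohort; background consequences are deliberately non-truncating so
that planted genotypes remain the only pathogenic signal.  Under the
``definitive`` evidence profile, background variants additionally avoid a
patient's planted genes, making truth recovery exact; the ``realistic``
profile allows collisions and grades some planted alleles as VUS
(yielding provisional diagnoses).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .consequence import annotate
from .panel_factory import default_panel, write_panel_files
from .regions import REFERRAL_CATEGORIES, Panel, clinical_region
from .variants import Variant

MODE_KEYS = ("AR_hom", "AR_comphet", "AD", "XL")


@dataclass(slots=True)
class SimConfig:
    seed: int = 0
    n_patients: int = 537
    platform_mix: dict = field(default_factory=lambda: {"SOLiD": 235 / 537, "HiSeq": 302 / 537})
    raw_rate: float = 268.0
    common_af_mix: float = 0.9706
    pathogenic_rate: float = 0.505
    mode_mix: dict = field(
        default_factory=lambda: {"AR_hom": 88 / 271, "AR_comphet": 120 / 271,
                                 "AD": 50 / 271, "XL": 13 / 271}
    )
    carrier_rate: float = 0.287
    evidence_profile: str = "definitive"   # definitive | realistic
    off_region_rate: float = 0.05
    qc_fail_rate: float = 0.01
    comphet_in_cis_rate: float = 0.0
    family_rate: float = 0.3
    male_fraction: float = 287 / 537

    def __post_init__(self) -> None:
        if abs(sum(self.platform_mix.values()) - 1.0) > 1e-9:
            raise ValueError("platform_mix must sum to 1")
        if abs(sum(self.mode_mix.values()) - 1.0) > 1e-9:
            raise ValueError("mode_mix must sum to 1")
        if self.evidence_profile not in ("definitive", "realistic"):
            raise ValueError(f"bad evidence_profile {self.evidence_profile}")
        for r in (self.raw_rate, self.pathogenic_rate, self.carrier_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")


@dataclass(slots=True)
class TruthRecord:
    patient_id: str
    sex: str
    referral_category: str
    platform: str
    status: str = "none"           # expected diagnosis status after the pipeline
    mode: str | None = None
    gene: str | None = None
    causal_variants: list = field(default_factory=list)   # variant uid strings
    carrier_variants: list = field(default_factory=list)  # (gene, uid)
    phase: str | None = None       # planted phase for comphet (in_trans/in_cis)
    family_available: bool = False


def _uid(v: Variant) -> str:
    return f"{v.chrom}:{v.pos + 1}:{v.ref}:{v.alt}"


# ---------------------------------------------------------------------------
# per-gene variant pools


@dataclass(slots=True)
class PoolEntry:
    gene: str
    variant: Variant
    zyg_hom_p: float
    dbsnp_af: float | None
    exac_af: float | None


def _coding_snv_candidates(panel: Panel, gene: str, want_terms, limit, rng):
    """Coding SNVs on ``gene`` whose consequence term is in ``want_terms``."""
    rec = panel[gene]
    tx = rec.transcript
    out = []
    segs = tx.cds_segments()
    positions = []
    for seg in segs:
        positions.extend(range(seg.start, seg.end))
    for pos in positions[3 : -3 : 7]:  # skip start/stop codons; stride the CDS
        ref = None
        # reconstruct the reference base from the CDS (plus strand throughout)
        off = 0
        for seg in segs:
            if seg.start <= pos < seg.end:
                ref = tx.cds_sequence[off + pos - seg.start]
                break
            off += len(seg)
        if ref is None:
            continue
        for alt in "ACGT":
            if alt == ref:
                continue
            try:
                cons = annotate(Variant(tx.chrom, pos, ref, alt), rec)
            except ValueError:
                continue
            if cons.term in want_terms:
                out.append(Variant(tx.chrom, pos, ref, alt))
                break
        if len(out) >= limit:
            break
    return out


def _splice_candidates(panel: Panel, gene: str, genome: dict[str, str], limit=2):
    tx = panel[gene].transcript
    out = []
    for seg in tx.cds_segments()[:-1]:
        pos = seg.end + 3  # intron +4 → splice_region
        ref = genome[tx.chrom][pos]
        out.append(Variant(tx.chrom, pos, ref, "G" if ref != "G" else "C"))
        if len(out) >= limit:
            break
    return out


def _offregion_candidates(panel: Panel, gene: str, genome: dict[str, str], limit=6):
    rec = panel[gene]
    tx = rec.transcript
    out = []
    for seg in tx.cds_segments():
        for off in (12, 22, 32, 42):
            pos = seg.end + off - 1
            ref = genome[tx.chrom][pos]
            alt = "A" if ref != "A" else "G"
            out.append(Variant(tx.chrom, pos, ref, alt))
            if len(out) >= limit:
                return out
    return out


def _build_pools(panel: Panel, genome: dict[str, str], rng: np.random.Generator):
    """Shared cohort-wide pools: common, rare, novel, off-region, and
    per-gene pathogenic (stop-gain) / missense candidates."""
    common: list[PoolEntry] = []
    rare: list[PoolEntry] = []
    novel: list[PoolEntry] = []
    off: list[PoolEntry] = []
    stops: dict[str, list[Variant]] = {}
    missense: dict[str, list[Variant]] = {}
    for gene in panel.symbols():
        benign = _coding_snv_candidates(panel, gene, {"missense", "synonymous"}, 22, rng)
        sp = _splice_candidates(panel, gene, genome)
        cand = benign[:20] + sp
        for i, v in enumerate(cand):
            if i < 11:
                af = float(rng.uniform(0.011, 0.5))
                common.append(PoolEntry(gene, v, 0.30, af, af))
            elif i < 17:
                af = float(10 ** rng.uniform(-5, -2.05))
                rare.append(PoolEntry(gene, v, 0.03, af, af))
            else:
                novel.append(PoolEntry(gene, v, 0.03, None, None))
        for v in _offregion_candidates(panel, gene, genome):
            off.append(PoolEntry(gene, v, 0.03, None, None))
        stops[gene] = _coding_snv_candidates(panel, gene, {"stop_gained"}, 8, rng)
        missense[gene] = benign[20:22] or benign[:2]
    return common, rare, novel, off, stops, missense


# ---------------------------------------------------------------------------
# VCF emission


def _vcf_line(pid, v: Variant, gt, depth, mqv, alt_reads):
    ad = f"{depth - alt_reads},{alt_reads}"
    return (
        f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
        f"GT:DP:MQV:AD\t{gt}:{depth}:{mqv:.0f}:{ad}"
    )


_VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=MQV,Number=1,Type=Float,Description="Mean quality value">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{pid}
"""


def _passing_metrics(platform, is_indel, rng):
    if platform == "SOLiD":
        depth = int(rng.integers(18, 180))
        mqv = float(rng.uniform(19, 40))
        alt = int(rng.integers(6, max(7, depth))) if is_indel else max(1, depth // 2)
    else:
        depth = int(rng.integers(50, 400))
        mqv = float(rng.uniform(45, 90))
        alt = int(rng.integers(int(0.26 * depth) + 1, depth + 1)) if is_indel else depth // 2
    return depth, mqv, min(alt, depth)


def _failing_metrics(platform, rng):
    if platform == "SOLiD":
        return int(rng.integers(1, 18)), float(rng.uniform(1, 18)), 1
    return int(rng.integers(1, 50)), float(rng.uniform(1, 44)), 1


def _genotype(zyg: str) -> str:
    return {"hom": "1/1", "het": "0/1", "hemi": "1"}[zyg]


def simulate_cohort(config: SimConfig, outdir: str | Path):
    """Write a full synthetic cohort; returns (paths dict, truth records).

    Deterministic given ``config.seed``: per-patient substreams are keyed by
    a stable hash of the patient id, so subsetting patients leaves each
    patient's data unchanged.
    """
    out = Path(outdir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    panel, genome = default_panel(with_genome=True)
    write_panel_files(panel, genome, out)

    contig_lines = "".join(
        f"##contig=<ID={c},length={len(genome[c])}>\n" for c in sorted(genome)
    )

    pool_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1])
    common, rare, novel, off, stops, missense = _build_pools(panel, genome, pool_rng)

    modes_of = {g: next(iter(panel[g].inheritance_modes)) for g in panel.symbols()}
    ar_genes = sorted(g for g, m in modes_of.items() if m == "AR" and len(stops[g]) >= 2)
    ad_genes = sorted(g for g, m in modes_of.items() if m == "AD" and stops[g])
    xl_genes = sorted(g for g, m in modes_of.items() if m == "XL" and stops[g])

    freq_rows: dict[tuple, tuple] = {}
    for entry in common + rare:
        key = entry.variant.key()
        freq_rows[key] = (entry.dbsnp_af, entry.dbsnp_af, 60.0, True, entry.exac_af)

    evidence_rows: dict[tuple, dict] = {}
    family_lines: list[str] = []
    patient_lines: list[str] = []
    truths: list[TruthRecord] = []

    mode_names = sorted(config.mode_mix)
    mode_probs = np.array([config.mode_mix[m] for m in mode_names])
    platforms = sorted(config.platform_mix)
    platform_probs = np.array([config.platform_mix[p] for p in platforms])

    def pick(rng, pool, exclude_genes, n):
        chosen = []
        seen = set()
        tries = 0
        while len(chosen) < n and tries < 50 * n + 50:
            tries += 1
            e = pool[int(rng.integers(0, len(pool)))]
            if e.gene in exclude_genes or e.variant.key() in seen:
                continue
            seen.add(e.variant.key())
            chosen.append(e)
        return chosen

    for i in range(config.n_patients):
        pid = f"S{i:04d}"
        rng = np.random.default_rng(
            [config.seed & 0x7FFFFFFF, zlib.crc32(pid.encode()) & 0x7FFFFFFF]
        )
        platform = platforms[int(rng.choice(len(platforms), p=platform_probs))]
        diagnosed = rng.random() < config.pathogenic_rate
        mode = mode_names[int(rng.choice(len(mode_names), p=mode_probs))] if diagnosed else None
        sex = "M" if mode == "XL" else ("M" if rng.random() < config.male_fraction else "F")

        truth = TruthRecord(pid, sex, "", platform)
        calls: list[tuple[Variant, str, tuple]] = []
        planted_genes: set[str] = set()
        vus_partner = False

        if diagnosed:
            if mode == "XL":
                gene = xl_genes[int(rng.integers(0, len(xl_genes)))]
                planted = [(stops[gene][int(rng.integers(0, len(stops[gene])))], "hemi", "path")]
            elif mode == "AD":
                gene = ad_genes[int(rng.integers(0, len(ad_genes)))]
                cands = stops[gene] if panel[gene].lof_mechanism else missense[gene]
                planted = [(cands[int(rng.integers(0, len(cands)))], "het", "path")]
            elif mode == "AR_hom":
                gene = ar_genes[int(rng.integers(0, len(ar_genes)))]
                planted = [(stops[gene][int(rng.integers(0, len(stops[gene])))], "hom", "path")]
            else:  # AR_comphet
                gene = ar_genes[int(rng.integers(0, len(ar_genes)))]
                idx = rng.choice(len(stops[gene]), size=2, replace=False)
                a1 = stops[gene][int(idx[0])]
                if config.evidence_profile == "realistic" and rng.random() < 0.3:
                    planted = [(a1, "het", "path"), (missense[gene][0], "het", "vus")]
                    vus_partner = True
                else:
                    planted = [(a1, "het", "path"),
                               (stops[gene][int(idx[1])], "het", "path")]
            planted_genes.add(gene)
            truth.gene = gene
            truth.mode = "AR" if mode in ("AR_hom", "AR_comphet") else mode
            truth.status = "provisional" if vus_partner else "confirmed"
            truth.referral_category = sorted(panel[gene].phenotype_categories)[
                int(rng.integers(0, len(panel[gene].phenotype_categories)))
            ]
            for v, zyg, kind in planted:
                calls.append((v, zyg, _passing_metrics(platform, v.is_indel, rng)))
                truth.causal_variants.append(_uid(v))
                evidence_rows[v.key()] = (
                    _definitive_evidence() if kind == "path" else _vus_evidence()
                )
            if mode == "AR_comphet":
                in_cis = rng.random() < config.comphet_in_cis_rate
                truth.phase = "in_cis" if in_cis else "in_trans"
                emit_family = in_cis or (rng.random() < config.family_rate)
                if emit_family:
                    truth.family_available = True
                    v1, v2 = planted[0][0], planted[1][0]
                    if in_cis:
                        # both alleles maternal; father genotyped negative
                        rows = [("mother", v1, "het"), ("mother", v2, "het"),
                                ("father", v1, "ref"), ("father", v2, "ref")]
                        truth.status = "none"
                        truth.carrier_variants = [(gene, _uid(v1)), (gene, _uid(v2))]
                        truth.causal_variants = []
                        truth.gene = None
                        truth.mode = None
                    else:
                        rows = [("mother", v1, "het"), ("mother", v2, "ref"),
                                ("father", v1, "ref"), ("father", v2, "het")]
                    for role, v, zyg in rows:
                        family_lines.append(
                            f"{pid}\t{role}\t{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{zyg}"
                        )
        else:
            truth.referral_category = REFERRAL_CATEGORIES[
                int(rng.integers(0, len(REFERRAL_CATEGORIES)))
            ]

        if rng.random() < config.carrier_rate:
            cand_genes = [g for g in ar_genes if g not in planted_genes]
            cgene = cand_genes[int(rng.integers(0, len(cand_genes)))]
            cv = stops[cgene][int(rng.integers(0, len(stops[cgene])))]
            planted_genes.add(cgene)
            evidence_rows[cv.key()] = _definitive_evidence()
            calls.append((cv, "het", _passing_metrics(platform, cv.is_indel, rng)))
            truth.carrier_variants.append((cgene, _uid(cv)))

        # background calls
        n_raw = int(rng.poisson(config.raw_rate))
        n_bg = max(0, n_raw - len(calls))
        p_off = config.off_region_rate
        p_qc = (1 - p_off) * config.qc_fail_rate
        p_common = (1 - p_off - p_qc) * config.common_af_mix
        p_rare_all = 1 - p_off - p_qc - p_common
        counts = rng.multinomial(n_bg, [p_off, p_qc, p_common, p_rare_all * 0.6,
                                        p_rare_all * 0.4])
        exclude = planted_genes if config.evidence_profile == "definitive" else set()
        groups = [
            (off, counts[0], True),
            (rare, counts[1], False),   # in-region but failing QC
            (common, counts[2], True),
            (rare, counts[3], True),
            (novel, counts[4], True),
        ]
        seen_keys = {v.key() for v, _, _ in calls}
        for gi, (pool, n, qc_pass) in enumerate(groups):
            for e in pick(rng, pool, exclude, int(n)):
                if e.variant.key() in seen_keys:
                    continue
                seen_keys.add(e.variant.key())
                if sex == "M" and e.variant.chrom == "chrX":
                    zyg = "hemi"
                else:
                    zyg = "hom" if rng.random() < e.zyg_hom_p else "het"
                metrics = (
                    _passing_metrics(platform, e.variant.is_indel, rng)
                    if qc_pass
                    else _failing_metrics(platform, rng)
                )
                calls.append((e.variant, zyg, metrics))

        calls.sort(key=lambda c: (c[0].chrom, c[0].pos, c[0].alt))
        vcf_path = out / "vcf" / f"{pid}.vcf"
        with open(vcf_path, "w") as fh:
            fh.write(_VCF_HEADER.format(pid=pid, contigs=contig_lines))
            for v, zyg, (depth, mqv, alt_reads) in calls:
                fh.write(_vcf_line(pid, v, _genotype(zyg), depth, mqv, alt_reads) + "\n")
        patient_lines.append(
            f"{pid}\t{sex}\t{truth.referral_category}\t{platform}\tvcf/{pid}.vcf"
        )
        truths.append(truth)

    _write_tables(out, freq_rows, evidence_rows, family_lines, patient_lines, panel)
    with open(out / "truth.json", "w") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1)
    paths = {name: out / name for name in
             ("panel.tsv", "cds.fasta", "genome.fasta", "special_sites.tsv",
              "freq.tsv", "evidence.tsv", "families.tsv", "patients.tsv",
              "depth.tsv", "truth.json")}
    return paths, truths


def _definitive_evidence() -> dict:
    return {"functional_support": 1, "prior_segregation_report": 0,
            "same_residue_alternative": 0, "insilico_damaging": "concordant_damaging",
            "phenotype_match": 1, "novel": 0}


def _vus_evidence() -> dict:
    return {"functional_support": 0, "prior_segregation_report": 0,
            "same_residue_alternative": 0, "insilico_damaging": "concordant_damaging",
            "phenotype_match": 1, "novel": 1}


def _write_tables(out, freq_rows, evidence_rows, family_lines, patient_lines, panel):
    with open(out / "freq.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdbsnp_af\tevs_af\tevs_mean_depth\tevs_cohort_ok\texac_af\n")
        for (chrom, pos, ref, alt), (db, evs, dpth, ok, exac) in sorted(freq_rows.items()):
            fh.write(
                f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{db:.6g}\t{evs:.6g}\t{dpth}\t"
                f"{int(ok)}\t{exac:.6g}\n"
            )
    with open(out / "evidence.tsv", "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tfunctional_support\tprior_segregation_report\t"
            "same_residue_alternative\tinsilico_damaging\tphenotype_match\tnovel\n"
        )
        for (chrom, pos, ref, alt), ev in sorted(evidence_rows.items()):
            fh.write(
                f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{ev['functional_support']}\t"
                f"{ev['prior_segregation_report']}\t{ev['same_residue_alternative']}\t"
                f"{ev['insilico_damaging']}\t{ev['phenotype_match']}\t{ev['novel']}\n"
            )
    with open(out / "families.tsv", "w") as fh:
        fh.write("proband_id\trole\tchrom\tpos\tref\talt\tzygosity\n")
        for line in family_lines:
            fh.write(line + "\n")
    with open(out / "patients.tsv", "w") as fh:
        fh.write("patient_id\tsex\treferral_category\tplatform\tvcf\n")
        for line in patient_lines:
            fh.write(line + "\n")
    # depth profile over the GUCY2D clinical region with a 460-base <50×
    # run inside the GC-rich exon (the capillary-fallback exemplar)
    tx = panel["GUCY2D"].transcript
    region = clinical_region(panel, "GUCY2D")
    low_start, low_end = 600, 1060
    with open(out / "depth.tsv", "w") as fh:
        fh.write("chrom\tpos\tdepth\n")
        lo = min(iv.start for iv in region)
        hi = max(iv.end for iv in region)
        for pos in range(lo, hi):
            depth = 30 if low_start <= pos < low_end else 100
            fh.write(f"{tx.chrom}\t{pos + 1}\t{depth}\n")
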