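"""Deterministic worked-example cohort.

The service's headline counts derive from patient data that cannot be
redistributed, so this module encodes the *published marginal totals* as a
synthetic 537-patient cohort: running the reporting layer over it
reproduces every derived statistic (per-patient means, novelty
percentages, coding-indel counts, discovery-year rates, population
re-annotation summaries) by recounting per-patient records, exactly as it
would over real results.

Encoded marginals (counts are variant occurrences unless noted):

* raw calls        SNV 46405/90981/338/82, indel 2182/3653/12/22 (hom/het/hemi/het-het)
* analysed         SNV 166/4172/20/0 = 4358, indel 27/150/7/0 = 184
* reported         SNV 58/252/9/0 = 319, indel 31/48/4/0 = 83 (confirmed zygosity;
                   four frameshift alleles are pileup-het but confirmed hom)
* 271 diagnoses: 88 AR-hom, 120 AR compound-het, 50 AD, 13 XL; 154 carrier
  individuals (48 with an AR diagnosis, 11 with an AD diagnosis)
* 311 unique reported mutations: 137 missense, 76 nonsense, 20 canonical
  splice, 54 frameshift, 7 in-frame deletions, 6 synonymous, 9 splice
  region, 1 start-loss, 1 deep-intronic (CEP290)
* database novelty: 1311/4358 analysed SNVs, 131/184 analysed indels,
  97/137 reported missense, 42/76 reported nonsense, 34/54 reported
  frameshifts; 66/130 truncating events (35 nonsense + 31 frameshift)
  novel as a cause of disease
* 147/184 analysed indels coding; 110 truncating (84 het + 26 hom)
* diagnoses by gene-discovery era: 16 pre-1995 (7 genes), 214 in 1995-2004
  (65 genes), 41 post-2005 (33 genes)
* gene spectrum: 62 diagnosed genes, 41 single-category, 21 cross-category
  (ABCA4 spanning five categories, CERKL four — including an 11-patient
  recurrent CERKL missense allele and a 5-patient recurrent CERKL nonsense)
* ExAC re-annotation: 2266 unique analysed SNVs with mean frequency 0.12,
  517/4358 occurrences above 1%; reported variants mean 0.02, median 0,
  max 0.78
* the GUCY2D capillary-fallback exemplar: a 460-base <50× run inside the
  76.20%-GC coding exon

Allocation below the printed precision (which patient carries which
allele; the recurrence histogram beyond the named recurrent alleles) is
fixture choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import DepthProfile
from .diagnose import ClassifiedVariant, call_diagnosis
from .panel_factory import default_panel, gene_roles
from .regions import GenomicInterval, Panel, clinical_region
from .report import AnalysedVariant, PatientResult
from .variants import PatientCase, Variant

N_PATIENTS = 537
N_MALES = 287

RAW_CELLS = {
    ("SNV", "hom"): 46405, ("SNV", "het"): 90981,
    ("SNV", "hemi"): 338, ("SNV", "het_het"): 82,
    ("indel", "hom"): 2182, ("indel", "het"): 3653,
    ("indel", "hemi"): 12, ("indel", "het_het"): 22,
}


@dataclass(slots=True)
class FixtureData:
    cohort: list[PatientResult]
    panel: Panel
    exac_by_uid: dict[str, float]
    analysed_snv_uids: list[str]          # one entry per occurrence
    unique_analysed_snv_uids: list[str]
    reported_unique_uids: list[str]
    depth_profile: DepthProfile
    gucy2d_region: list[GenomicInterval]
    gucy2d_exon_seq: str


# ---------------------------------------------------------------------------
# small allocation helpers


class _Mint:
    """Deterministic allele-identity factory (one locus counter per gene)."""

    def __init__(self, panel: Panel):
        self.panel = panel
        self.counters: dict[str, int] = {}

    def make(self, gene: str, vclass: str) -> tuple[str, Variant]:
        n = self.counters.get(gene, 0) + 1
        self.counters[gene] = n
        chrom = self.panel[gene].transcript.chrom if gene in self.panel else f"chr_{gene}"
        pos = 10_000 + 10 * n
        alleles = {"SNV": ("A", "C"), "deletion": ("AAT", "A"), "inframe": ("AAATG", "AA")}
        ref, alt = alleles[vclass]
        return f"{gene}:v{n}", Variant(chrom, pos, ref, alt)


class _TermQueue:
    """Consequence-term budget; each entry carries its database-novelty flag."""

    def __init__(self, spec: list[tuple[str, int, int]]):
        # rows: (term, n_novel, n_known); novel entries are drawn first
        self.items: dict[str, list[bool]] = {}
        for term, n_novel, n_known in spec:
            self.items[term] = [True] * n_novel + [False] * n_known

    def draw_any(self) -> tuple[str, bool]:
        for term, flags in self.items.items():
            if flags:
                return term, flags.pop(0)
        raise RuntimeError("term queue exhausted")

    def draw(self, term: str) -> tuple[str, bool]:
        return term, self.items[term].pop(0)

    def remaining(self) -> int:
        return sum(len(v) for v in self.items.values())


class _NovelCause:
    """Literature-novelty quotas per consequence term (144 in total; the
    graded slice is 35 nonsense + 31 frameshift = 66 of 130 truncating)."""

    QUOTA = {
        "missense": 52, "stop_gained": 35, "frameshift": 31, "canonical_splice": 12,
        "synonymous": 4, "splice_region": 5, "inframe_deletion": 3, "start_lost": 1,
        "intronic_special": 1,
    }

    def __init__(self):
        self.used: dict[str, int] = {}

    def grant(self, term: str, eligible: bool = True) -> bool:
        if not eligible:
            return False
        if self.used.get(term, 0) < self.QUOTA.get(term, 0):
            self.used[term] = self.used.get(term, 0) + 1
            return True
        return False


@dataclass(slots=True)
class _Occ:
    uid: str
    variant: Variant
    gene: str
    vclass: str
    zygosity: str              # pileup zygosity
    term: str
    truncating: bool
    novel_db: bool
    novel_cause: bool
    reported: bool
    pathogenicity: str
    coding_indel: bool
    reported_zygosity: str | None = None
    exac_af: float | None = None


def _pclass(truncating: bool, novel: bool) -> str:
    return "likely_pathogenic" if novel else "clearly_pathogenic"


# ---------------------------------------------------------------------------
# diagnosed-patient plan


def _diagnosed_plan(panel: Panel) -> list[dict]:
    """One row per diagnosed gene: patient counts by zygosity pattern plus
    per-patient referral categories and recurrence structure."""
    roles = gene_roles()

    def pick(role, mode, era=None):
        out = []
        for s in sorted(roles):
            if roles[s] != role or mode not in panel[s].inheritance_modes:
                continue
            y = panel[s].discovery_year
            if era == "mid" and not 1995 <= y <= 2004:
                continue
            if era == "post" and y < 2005:
                continue
            if era == "pre" and y >= 1995:
                continue
            out.append(s)
        return out

    rows: list[dict] = []

    def add(gene, mode, hom=0, comphet=0, het=0, hemi=0, cats=None,
            founder=False, fs2=0, fsu=0, inf=0):
        # fs2: shared-frameshift second alleles; fsu: unique frameshift
        # second alleles; inf: in-frame-deletion second alleles
        rows.append(dict(gene=gene, mode=mode, hom=hom, comphet=comphet, het=het,
                         hemi=hemi, cats=list(cats or []), founder=founder,
                         fs2=fs2, fsu=fsu, inf=inf))

    def cat_fill(gene, n, cross=False):
        cs = sorted(panel[gene].phenotype_categories)
        if cross and len(cs) >= 2:
            return [cs[0]] * (n - 1) + [cs[1]]
        return [cs[0]] * n

    # named genes
    add("ABCA4", "AR", hom=9, comphet=14, founder=True, fs2=6,
        cats=["MD/STGD"] * 12 + ["CRD"] * 5 + ["RCD/RP"] * 4 + ["CD", "Usher"])
    add("CERKL", "AR", comphet=11, founder=True,
        cats=["CD"] + ["CRD"] * 3 + ["RCD/RP"] * 4 + ["MD/STGD"] * 3)
    add("USH2A", "AR", hom=5, comphet=5, founder=True, fs2=2, cats=["Usher"] * 10)
    add("EYS", "AR", hom=4, comphet=3, founder=True, cats=["RCD/RP"] * 7)
    add("GUCY2D", "AR", comphet=1, fsu=1, cats=["EORD/LCA"])
    add("CEP290", "AR", comphet=2, cats=["EORD/LCA"] * 2)
    add("RHO", "AD", het=6, cats=["RCD/RP"] * 6)
    add("PRPF31", "AD", het=8, cats=["RCD/RP"] * 8)
    add("CHM", "XL", hemi=2, cats=["RCD/RP"] * 2)  # referred as RP → discordant

    # pre-era synthetic
    pre_ar_cross = pick("diag_cross", "AR", "pre")      # one gene
    pre_ar = pick("diag_single", "AR", "pre")
    pre_ad = pick("diag_single", "AD", "pre")
    add(pre_ar_cross[0], "AR", hom=2, comphet=2, cats=["RCD/RP"] * 3 + ["CSNB"])
    add(pre_ar[0], "AR", hom=2, comphet=1, cats=cat_fill(pre_ar[0], 3))
    add(pre_ad[0], "AD", het=1, cats=cat_fill(pre_ad[0], 1))

    # XL synthetic: 5 + 4 (mid; the 4-patient gene carries in-frame indels) + 2 (post)
    xl_mid = pick("diag_single", "XL", "mid")
    xl_post = pick("diag_single", "XL", "post")
    add(xl_mid[0], "XL", hemi=5, cats=cat_fill(xl_mid[0], 5))
    add(xl_mid[1], "XL", hemi=4, cats=cat_fill(xl_mid[1], 4))
    add(xl_post[0], "XL", hemi=2, cats=cat_fill(xl_post[0], 2))

    # AD synthetic: six mid genes × 5, post 3 + 2
    ad_mid = pick("diag_single", "AD", "mid")
    ad_post = pick("diag_single", "AD", "post")
    for g in ad_mid:
        add(g, "AD", het=5, cats=cat_fill(g, 5))
    add(ad_post[0], "AD", het=3, cats=cat_fill(ad_post[0], 3))
    add(ad_post[1], "AD", het=2, cats=cat_fill(ad_post[1], 2))

    # AR synthetic
    mid_cross = pick("diag_cross", "AR", "mid")
    post_cross = pick("diag_cross", "AR", "post")
    mid_single = pick("diag_single", "AR", "mid")
    post_single = pick("diag_single", "AR", "post")
    assert (len(mid_cross), len(post_cross), len(mid_single), len(post_single)) == (12, 6, 15, 6)

    for g in mid_cross[:9]:  # founder genes: all-comphet, shared fs second alleles
        add(g, "AR", comphet=5, founder=True, fs2=4, cats=cat_fill(g, 5, cross=True))

    rest = (
        [(g, 5, True) for g in mid_cross[9:]]
        + [(g, 5, False) for g in mid_single[:2]]
        + [(g, 4, False) for g in mid_single[2:]]
        + [(g, 2, True) for g in post_cross]
        + [(post_single[0], 3, False)]
        + [(g, 2, False) for g in post_single[1:]]
    )
    comphet_quota = 36
    first_rest = True
    for g, n, cross in rest:
        take = min(comphet_quota, n)
        comphet_quota -= take
        # the first all-comphet non-founder gene carries the one unique
        # frameshift and the two in-frame-deletion second alleles
        fsu, inf = (1, 2) if first_rest and take >= 3 else (0, 0)
        first_rest = first_rest and not fsu
        add(g, "AR", comphet=take, hom=n - take, cats=cat_fill(g, n, cross=cross),
            fsu=fsu, inf=inf)
    assert comphet_quota == 0
    assert sum(r["fsu"] for r in rows) == 2 and sum(r["inf"] for r in rows) == 2
    assert sum(r["hom"] for r in rows) == 88
    assert sum(r["comphet"] for r in rows) == 120
    assert sum(r["het"] for r in rows) == 50
    assert sum(r["hemi"] for r in rows) == 13
    assert len(rows) == 62
    return rows


# ---------------------------------------------------------------------------
# reported-occurrence materialisation


def _build_reported(panel: Panel, mint: _Mint):
    """Returns (patient dicts, per-patient reported occurrence lists)."""
    nc = _NovelCause()
    hom_q = _TermQueue([("missense", 21, 0), ("stop_gained", 20, 0),
                        ("canonical_splice", 0, 10), ("synonymous", 0, 3),
                        ("splice_region", 0, 4)])
    ad_q = _TermQueue([("missense", 30, 0), ("stop_gained", 0, 5), ("start_lost", 0, 1)])
    xl_q = _TermQueue([("missense", 5, 0), ("stop_gained", 4, 0)])
    ch_q = _TermQueue([("missense", 39, 19), ("stop_gained", 18, 22),
                       ("canonical_splice", 0, 10), ("synonymous", 0, 3),
                       ("splice_region", 0, 5)])
    prpf_q = _TermQueue([("stop_gained", 0, 4), ("missense", 1, 3)])

    plan = _diagnosed_plan(panel)

    def snv(gene, zyg, term, novel, *, pclass=None, shared=None, rz=None,
            nc_eligible=True):
        uid, var = shared if shared else mint.make(gene, "SNV")
        trunc = term in ("stop_gained", "start_lost")
        return _Occ(uid, var, gene, "SNV", zyg, term, trunc, novel,
                    nc.grant(term, nc_eligible and shared is None),
                    True, pclass or _pclass(trunc, novel), False, rz)

    def indel(gene, zyg, term, novel, *, shared=None, rz=None, nc_eligible=True):
        uid, var = shared if shared else mint.make(
            gene, "inframe" if term == "inframe_deletion" else "deletion")
        trunc = term == "frameshift"
        return _Occ(uid, var, gene, "deletion", zyg, term, trunc, novel,
                    nc.grant(term, nc_eligible and shared is None),
                    True, _pclass(trunc, novel), True, rz)

    patients: list[dict] = []
    occs: list[list[_Occ]] = []

    hom_specs, ch_specs, ad_specs, xl_specs = [], [], [], []
    for row in plan:
        cats = iter(row["cats"])
        for _ in range(row["hom"]):
            hom_specs.append((row["gene"], next(cats)))
        for j in range(row["comphet"]):
            ch_specs.append(dict(
                gene=row["gene"], cat=next(cats), founder=row["founder"],
                fs=j < row["fs2"],
                fsu=row["fs2"] <= j < row["fs2"] + row["fsu"],
                inf=row["fs2"] + row["fsu"] <= j < row["fs2"] + row["fsu"] + row["inf"],
            ))
        for _ in range(row["het"]):
            ad_specs.append((row["gene"], next(cats)))
        for _ in range(row["hemi"]):
            xl_specs.append((row["gene"], next(cats)))

    # ---- AR homozygotes: 57 SNV-causal (first carries a second hom allele),
    # then 26 pileup-hom frameshifts, 4 pileup-het/confirmed-hom frameshifts,
    # and one in-frame-deletion homozygote
    snv_homs, indel_homs = hom_specs[:57], hom_specs[57:]
    for i, (gene, cat) in enumerate(snv_homs):
        patients.append(dict(mode="AR", gene=gene, cat=cat))
        term, novel = hom_q.draw_any()
        lst = [snv(gene, "hom", term, novel)]
        if i == 0:
            t2, n2 = hom_q.draw_any()
            lst.append(snv(gene, "hom", t2, n2))
        occs.append(lst)
    for i, (gene, cat) in enumerate(indel_homs):
        patients.append(dict(mode="AR", gene=gene, cat=cat))
        if i < 26:
            occs.append([indel(gene, "hom", "frameshift", novel=i < 25)])
        elif i < 30:
            occs.append([indel(gene, "het", "frameshift", novel=False, rz="hom")])
        else:
            occs.append([indel(gene, "hom", "inframe_deletion", novel=False)])
    assert hom_q.remaining() == 0

    # ---- AR compound heterozygotes
    founder_allele: dict[str, tuple] = {}
    fs_pending: dict[str, tuple] = {}
    fs_shared_made = 0
    novel_fs_budget = 7          # seven shared frameshifts are database-novel
    cerkl_stop: tuple | None = None
    cerkl_i = 0
    extra_vus = 10
    cep290_first = True

    for spec in ch_specs:
        gene, cat = spec["gene"], spec["cat"]
        patients.append(dict(mode="AR", gene=gene, cat=cat))
        lst: list[_Occ] = []

        # allele 1
        if spec["founder"]:
            term1 = "stop_gained" if gene == "EYS" else "missense"
            if gene not in founder_allele:
                founder_allele[gene] = mint.make(gene, "SNV")
                trunc = term1 == "stop_gained"
                lst.append(_Occ(*founder_allele[gene], gene, "SNV", "het", term1,
                                trunc, False, nc.grant(term1, gene == "EYS"),
                                True, "clearly_pathogenic", False))
            else:
                trunc = term1 == "stop_gained"
                lst.append(_Occ(*founder_allele[gene], gene, "SNV", "het", term1,
                                trunc, False, False, True, "clearly_pathogenic", False))
        elif gene == "GUCY2D":
            lst.append(snv(gene, "het", "missense", True))
        elif gene == "CEP290" and cep290_first:
            lst.append(snv(gene, "het", "intronic_special", False,
                           pclass="clearly_pathogenic"))
        else:
            term, novel = ch_q.draw_any()
            lst.append(snv(gene, "het", term, novel))

        # allele 2
        if gene == "CERKL":
            cerkl_i += 1
            if cerkl_i <= 5:
                if cerkl_stop is None:
                    cerkl_stop = mint.make(gene, "SNV")
                    lst.append(_Occ(*cerkl_stop, gene, "SNV", "het", "stop_gained",
                                    True, False, nc.grant("stop_gained"), True,
                                    "clearly_pathogenic", False))
                else:
                    lst.append(_Occ(*cerkl_stop, gene, "SNV", "het", "stop_gained",
                                    True, False, False, True,
                                    "clearly_pathogenic", False))
            else:
                term, novel = ch_q.draw_any()
                lst.append(snv(gene, "het", term, novel))
        elif spec["fs"]:
            if gene in fs_pending:
                shared, novel = fs_pending.pop(gene)
                lst.append(indel(gene, "het", "frameshift", novel, shared=shared))
                fs_shared_made += 1
            else:
                novel = novel_fs_budget > 0
                novel_fs_budget -= 1 if novel else 0
                shared = mint.make(gene, "deletion")
                fs_pending[gene] = (shared, novel)
                lst.append(_Occ(*shared, gene, "deletion", "het", "frameshift",
                                True, novel, nc.grant("frameshift", novel), True,
                                _pclass(True, novel), True))
        elif spec["fsu"]:
            lst.append(indel(gene, "het", "frameshift", True))
        elif spec["inf"]:
            lst.append(indel(gene, "het", "inframe_deletion", False))
        elif gene == "CEP290" and cep290_first:
            cep290_first = False
            lst.append(snv(gene, "het", "stop_gained", False, nc_eligible=False))
        else:
            term, novel = ch_q.draw_any()
            lst.append(snv(gene, "het", term, novel))

        # the ten extra reported VUS alleles
        if extra_vus > 0 and not spec["founder"] and gene not in (
            "CERKL", "GUCY2D", "CEP290",
        ):
            term, novel = ch_q.draw_any()
            lst.append(snv(gene, "het", term, novel, pclass="vus"))
            extra_vus -= 1
        occs.append(lst)
    assert extra_vus == 0
    assert fs_shared_made == 22, fs_shared_made
    assert not fs_pending

    # ---- AD heterozygotes
    for gene, cat in ad_specs:
        patients.append(dict(mode="AD", gene=gene, cat=cat))
        if gene == "RHO":
            occs.append([snv(gene, "het", "missense", False,
                             pclass="clearly_pathogenic", nc_eligible=False)])
        elif gene == "PRPF31":
            term, novel = prpf_q.draw_any()
            occs.append([snv(gene, "het", term, novel, nc_eligible=False)])
        else:
            term, novel = ad_q.draw_any()
            occs.append([snv(gene, "het", term, novel)])
    assert ad_q.remaining() == 0 and prpf_q.remaining() == 0

    # ---- XL hemizygotes
    xl_indel_gene = None
    for gene, cat in xl_specs:
        patients.append(dict(mode="XL", gene=gene, cat=cat))
        row = next(r for r in plan if r["gene"] == gene)
        if row["hemi"] == 4:  # the designated in-frame-deletion XL gene
            xl_indel_gene = gene
            occs.append([indel(gene, "hemi", "inframe_deletion", False)])
        else:
            term, novel = xl_q.draw_any()
            occs.append([snv(gene, "hemi", term, novel)])
    assert xl_q.remaining() == 0
    assert xl_indel_gene is not None
    assert ch_q.remaining() == 0, ch_q.remaining()

    return patients, occs


# ---------------------------------------------------------------------------
# cohort assembly

_EXAC_MAX = 0.78


def paper_fixture() -> FixtureData:
    """Build the deterministic cohort; repeated calls are identical."""
    panel = default_panel()
    mint = _Mint(panel)
    roles = gene_roles()

    diag_patients, diag_occs = _build_reported(panel, mint)
    n_diag = len(diag_patients)
    assert n_diag == 271

    # undiagnosed patients fill the cohort; referral categories pad the
    # published category sizes loosely (RCD/RP dominating)
    patients = list(diag_patients)
    occs = [list(o) for o in diag_occs]
    pad_cats = (["RCD/RP"] * 150 + ["Usher"] * 20 + ["MD/STGD"] * 25 + ["CRD"] * 20
                + ["EORD/LCA"] * 15 + ["CD"] * 10 + ["CSNB"] * 10 + ["FEVR"] * 6
                + ["Ciliopathy"] * 5 + ["Other"] * 5)
    for i in range(N_PATIENTS - n_diag):
        patients.append(dict(mode=None, gene=None, cat=pad_cats[i]))
        occs.append([])

    # sexes: XL patients male; fill to 287 males from the top
    xl_idx = [i for i, p in enumerate(patients) if p["mode"] == "XL"]
    sexes = ["F"] * N_PATIENTS
    for i in xl_idx:
        sexes[i] = "M"
    need = N_MALES - len(xl_idx)
    for i in range(N_PATIENTS):
        if need == 0:
            break
        if sexes[i] == "F":
            sexes[i] = "M"
            need -= 1

    # ---- carriers: 48 AR-diagnosed, 11 AD-diagnosed, 95 undiagnosed
    carrier_genes = sorted(g for g, r in roles.items() if r == "carrier")
    ar_idx = [i for i, p in enumerate(patients) if p["mode"] == "AR"]
    ad_idx = [i for i, p in enumerate(patients) if p["mode"] == "AD"]
    none_idx = [i for i, p in enumerate(patients) if p["mode"] is None]
    carrier_targets = ar_idx[-48:] + ad_idx[:11] + none_idx[:95]
    assert len(carrier_targets) == 154
    for j, i in enumerate(carrier_targets):
        gene = carrier_genes[j % len(carrier_genes)]
        uid, var = mint.make(gene, "SNV")
        occs[i].append(_Occ(uid, var, gene, "SNV", "het", "missense", False, False,
                            False, False, "likely_pathogenic", False))

    # ---- background analysed variants ----------------------------------
    bg_genes = sorted(g for g, r in roles.items()
                      if r == "background" and "XL" not in panel[g].inheritance_modes)
    bg_xl = sorted(g for g, r in roles.items()
                   if r == "background" and "XL" in panel[g].inheritance_modes)
    assert bg_genes and len(bg_xl) == 2

    def bg_gene(k):
        return bg_genes[k % len(bg_genes)]

    bg_occurrences: list[_Occ] = []
    exac_common_af = (0.12 * 2266 - (7 * _EXAC_MAX + 0.76)) / 509

    def bg_snv(gene, term, novel, exac=None):
        uid, var = mint.make(gene, "SNV")
        trunc = term in ("stop_gained", "start_lost")
        return _Occ(uid, var, gene, "SNV", "het", term, trunc, novel, False,
                    False, "vus", False, exac_af=exac)

    k = 0
    # 509 ExAC-common singletons (rare in dbSNP/EVS, >1% in ExAC)
    for j in range(509):
        o = bg_snv(bg_gene(k), "missense" if j % 2 else "synonymous", False,
                   exac=exac_common_af)
        bg_occurrences.append(o)
        k += 1
    # 1172 database-novel singletons with the published consequence mix
    novel_terms = ([("missense", 714), ("stop_gained", 28), ("synonymous", 350),
                    ("start_lost", 2), ("canonical_splice", 32), ("splice_region", 46)])
    for term, n in novel_terms:
        for _ in range(n):
            bg_occurrences.append(bg_snv(bg_gene(k), term, True))
            k += 1
    # 11 hemizygous X-linked singletons
    xl_hemi_bg: list[_Occ] = []
    for j in range(11):
        gene = bg_xl[j % 2]
        uid, var = mint.make(gene, "SNV")
        xl_hemi_bg.append(_Occ(uid, var, gene, "SNV", "hemi", "missense", False,
                               False, False, False, "vus", False))
    # recurrent background alleles: 153×13 + 17×12 occurrences
    multi_occurrences: list[_Occ] = []
    for j in range(170):
        mult = 13 if j < 153 else 12
        gene = bg_gene(k)
        uid, var = mint.make(gene, "SNV")
        term = "missense" if j % 2 else "synonymous"
        for _ in range(mult):
            multi_occurrences.append(_Occ(uid, var, gene, "SNV", "het", term,
                                          False, False, False, False, "vus", False))
        k += 1
    for o in multi_occurrences[:108]:
        o.zygosity = "hom"
    bg_occurrences.extend(multi_occurrences)

    # background indels: 34 novel frameshift + 30 novel in-frame (coding),
    # 26 novel + 8 known splice-flank het, 3 known splice-flank hemi (XL)
    bg_indels: list[_Occ] = []

    def bg_indel(gene, term, novel, zyg="het", coding=True):
        uid, var = mint.make(gene, "inframe" if term == "inframe_deletion" else "deletion")
        return _Occ(uid, var, gene, "deletion", zyg, term, term == "frameshift",
                    novel, False, False, "vus", coding)

    for j in range(34):
        bg_indels.append(bg_indel(bg_gene(k), "frameshift", True)); k += 1
    for j in range(30):
        bg_indels.append(bg_indel(bg_gene(k), "inframe_deletion", True)); k += 1
    for j in range(26):
        bg_indels.append(bg_indel(bg_gene(k), "splice_region", True, coding=False)); k += 1
    for j in range(8):
        bg_indels.append(bg_indel(bg_gene(k), "splice_region", False, coding=False)); k += 1
    xl_hemi_indels = [bg_indel(bg_xl[j % 2], "splice_region", False, zyg="hemi",
                               coding=False) for j in range(3)]

    # distribute background over patients (hemi events go to XL males)
    for j, o in enumerate(bg_occurrences + bg_indels):
        occs[j % N_PATIENTS].append(o)
    for j, o in enumerate(xl_hemi_bg + xl_hemi_indels):
        occs[xl_idx[j % len(xl_idx)]].append(o)

    # ---- ExAC table over reported uniques: eight canonical-splice alleles
    # carry the high ExAC frequencies (7 × 0.78 + 1 × 0.76)
    reported_canonical = []
    seen = set()
    for row in occs:
        for o in row:
            if o.reported and o.term == "canonical_splice" and o.uid not in seen:
                seen.add(o.uid)
                reported_canonical.append(o)
    assert len(reported_canonical) == 20
    high = reported_canonical[:8]
    for o in high[:7]:
        o.exac_af = _EXAC_MAX
    high[7].exac_af = 0.76

    # ---- raw-call tallies ----------------------------------------------
    male_idx = [i for i in range(N_PATIENTS) if sexes[i] == "M"]
    raw_counts: list[dict] = [dict() for _ in range(N_PATIENTS)]
    for (grp, zyg), total in RAW_CELLS.items():
        targets = male_idx if zyg == "hemi" else list(range(N_PATIENTS))
        base, rem = divmod(total, len(targets))
        for j, i in enumerate(targets):
            n = base + (1 if j < rem else 0)
            if n:
                raw_counts[i][(grp, zyg)] = raw_counts[i].get((grp, zyg), 0) + n

    # ---- materialise PatientResults -------------------------------------
    cohort: list[PatientResult] = []
    exac_by_uid: dict[str, float] = {}
    analysed_snv_uids: list[str] = []
    for i in range(N_PATIENTS):
        pid = f"P{i + 1:04d}"
        cat = patients[i]["cat"]
        case = PatientCase(pid, sexes[i], cat, "HiSeq" if i % 2 else "SOLiD")
        analysed: list[AnalysedVariant] = []
        classified: list[ClassifiedVariant] = []
        for o in occs[i]:
            analysed.append(AnalysedVariant(
                uid=o.uid, gene=o.gene, vclass=o.vclass, zygosity=o.zygosity,
                term=o.term, truncating=o.truncating, novel_db=o.novel_db,
                novel_cause=o.novel_cause, reported=o.reported,
                pathogenicity=o.pathogenicity, coding_indel=o.coding_indel,
                exac_af=o.exac_af, reported_zygosity=o.reported_zygosity,
            ))
            classified.append(ClassifiedVariant(
                variant=o.variant, gene=o.gene,
                zygosity=o.reported_zygosity or o.zygosity,
                pathogenicity=o.pathogenicity, consequence_term=o.term,
                truncating=o.truncating, novel_db=o.novel_db,
            ))
            if o.vclass == "SNV":
                analysed_snv_uids.append(o.uid)
            if o.exac_af is not None:
                exac_by_uid[o.uid] = o.exac_af
        diagnosis = call_diagnosis(case, classified, panel)
        expected = patients[i]["mode"]
        assert diagnosis.mode == expected and (
            (expected is None) == (diagnosis.status == "none")
        ), (pid, expected, diagnosis.status, diagnosis.mode)
        if expected is not None:
            assert diagnosis.gene == patients[i]["gene"]
        cohort.append(PatientResult(
            patient_id=pid, referral_category=cat, raw_counts=raw_counts[i],
            analysed=analysed, diagnosis=diagnosis,
            n_carrier_findings=len(diagnosis.carrier_findings),
        ))

    unique_uids = sorted(set(analysed_snv_uids))
    assert len(analysed_snv_uids) == 4358, len(analysed_snv_uids)
    assert len(unique_uids) == 2266, len(unique_uids)

    reported_unique = sorted({o.uid for row in occs for o in row if o.reported})
    assert len(reported_unique) == 311, len(reported_unique)

    # ---- GUCY2D coverage exemplar ---------------------------------------
    tx = panel["GUCY2D"].transcript
    region = clinical_region(panel, "GUCY2D")
    lo = min(iv.start for iv in region)
    hi = max(iv.end for iv in region)
    depths = np.full(hi - lo, 100, dtype=np.int64)
    depths[600 - lo : 1060 - lo] = 30
    profile = DepthProfile(tx.chrom, lo, depths)
    exon_seq = tx.cds_sequence[240:971]

    return FixtureData(
        cohort=cohort,
        panel=panel,
        exac_by_uid=exac_by_uid,
        analysed_snv_uids=analysed_snv_uids,
        unique_analysed_snv_uids=unique_uids,
        reported_unique_uids=reported_unique,
        depth_profile=profile,
        gucy2d_region=region,
        gucy2d_exon_seq=exon_seq,
    )
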