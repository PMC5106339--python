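"""Cohort reporting: rounding conventions, tallies vs recount oracle,
yield and discovery-era statistics."""

from collections import Counter

import pytest

from retdx.diagnose import DiagnosisResult
from retdx.panel_factory import default_panel
from retdx.report import (
    AnalysedVariant,
    PatientResult,
    discovery_year_rates,
    gene_spectrum,
    mean_per_patient,
    pct,
    round_half_up,
    tabulate,
    yield_stats,
)


class TestRounding:
    @pytest.mark.parametrize("x,d,expected", [
        (8.45, 1, 8.5),      # ties round up, not to even
        (8.44, 1, 8.4),
        (0.5, 0, 1.0),
        (1.25, 1, 1.3),
        (3.2923, 1, 3.3),
    ])
    def test_round_half_up(self, x, d, expected):
        assert round_half_up(x, d) == expected

    def test_mean_per_patient_printed_precision(self):
        assert mean_per_patient(4358, 537) == 8.1
        assert mean_per_patient(4172, 537) == 7.8
        assert mean_per_patient(0, 10) == 0.0

    def test_mean_per_patient_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            mean_per_patient(10, 0)

    def test_pct(self):
        assert pct(1311, 4358) == 30
        assert pct(131, 184) == 71
        with pytest.raises(ZeroDivisionError):
            pct(1, 0)


def make_patient(pid, analysed, diagnosis=None, cat="RCD/RP", raw=None):
    return PatientResult(patient_id=pid, referral_category=cat,
                         raw_counts=raw or {}, analysed=analysed,
                         diagnosis=diagnosis or DiagnosisResult())


def av(uid, vclass="SNV", zyg="het", term="missense", **kw):
    return AnalysedVariant(uid=uid, gene="G1", vclass=vclass, zygosity=zyg,
                           term=term, **kw)


class TestTabulate:
    def test_empty_cohort_all_zeros(self):
        s = tabulate([])
        assert s.stage_total("raw") == 0
        assert s.stage_total("analysed") == 0
        assert s.row("reported") == (0, 0, 0, 0, 0)

    def test_cells_match_nested_loop_recount(self):
        import numpy as np

        rng = np.random.default_rng(21)
        cohort = []
        for i in range(25):
            analysed = []
            for j in range(int(rng.integers(0, 12))):
                analysed.append(av(
                    uid=f"v{i}-{j}",
                    vclass=["SNV", "deletion", "insertion"][int(rng.integers(0, 3))],
                    zyg=["hom", "het", "hemi"][int(rng.integers(0, 3))],
                    novel_db=bool(rng.random() < 0.3),
                    reported=bool(rng.random() < 0.2),
                    coding_indel=bool(rng.random() < 0.5),
                ))
            raw = {("SNV", "het"): int(rng.integers(20, 50)),
                   ("indel", "hom"): int(rng.integers(0, 5))}
            cohort.append(make_patient(f"P{i}", analysed, raw=raw))
        s = tabulate(cohort)
        # independent recount
        recount = Counter()
        for pr in cohort:
            for a in pr.analysed:
                grp = "SNV" if a.vclass == "SNV" else "indel"
                recount[("analysed", grp, a.zygosity)] += 1
                if a.reported:
                    recount[("reported", grp, a.zygosity)] += 1
        for grp in ("SNV", "indel"):
            for zyg in ("hom", "het", "hemi", "het_het"):
                assert s.counts["analysed"][grp][zyg] == recount[("analysed", grp, zyg)]
                assert s.counts["reported"][grp][zyg] == recount[("reported", grp, zyg)]
        assert s.stage_total("raw") == sum(
            sum(pr.raw_counts.values()) for pr in cohort)

    def test_row_cells_sum_to_total(self):
        cohort = [make_patient("P1", [av("a"), av("b", zyg="hom"),
                                      av("c", vclass="deletion", zyg="hemi")])]
        s = tabulate(cohort)
        hom, het, hemi, hh, total = s.row("analysed")
        assert hom + het + hemi + hh == total == 3

    def test_analysed_exceeding_raw_rejected(self):
        pr = make_patient("P1", [av("a"), av("b")],
                          raw={("SNV", "het"): 1})
        with pytest.raises(ValueError, match="exceeds raw"):
            tabulate([pr])


class TestYieldStats:
    def test_counts_by_mode_and_ar_detail(self):
        from retdx.diagnose import ClassifiedVariant
        from retdx.variants import Variant

        def diag(mode, zygs):
            cvs = [ClassifiedVariant(Variant("c", i, "A", "C"), "G1", z,
                                     "clearly_pathogenic")
                   for i, z in enumerate(zygs)]
            return DiagnosisResult(status="confirmed", mode=mode, gene="G1",
                                   causal_variants=cvs)

        cohort = [
            make_patient("P1", [], diag("AR", ["hom"])),
            make_patient("P2", [], diag("AR", ["het", "het"])),
            make_patient("P3", [], diag("AD", ["het"])),
            make_patient("P4", [], diag("XL", ["hemi"])),
            make_patient("P5", []),
        ]
        ys = yield_stats(cohort)
        assert ys["n_diagnosed"] == 4
        assert ys["by_mode"] == {"AR": 2, "AD": 1, "XL": 1}
        assert ys["ar_detail"] == {"hom": 1, "comphet": 1}
        assert ys["yield"] == pytest.approx(4 / 5)

    def test_nobody_diagnosed(self):
        ys = yield_stats([make_patient("P1", []), make_patient("P2", [])])
        assert ys["n_diagnosed"] == 0 and ys["yield"] == 0.0


class TestDiscoveryYearRates:
    def test_published_era_rates(self):
        panel = default_panel()
        # distribute 271 diagnoses over the panel matching the published eras
        diag = {}
        eras = {"pre": [], "mid": [], "post": []}
        for g in panel.symbols():
            y = panel[g].discovery_year
            eras["pre" if y < 1995 else "mid" if y < 2005 else "post"].append(g)
        for g, n in zip(eras["mid"], [4] * 19 + [3] * 46):
            diag[g] = n                      # 214 over 65 genes
        for g, n in zip(eras["post"], [2] * 8 + [1] * 25):
            diag[g] = n                      # 41 over 33 genes
        for g, n in zip(eras["pre"], [3, 3, 3, 3, 2, 1, 1]):
            diag[g] = n                      # 16 over 7 genes
        gy = discovery_year_rates(diag, panel)
        by_era = {e["era"]: e for e in gy.eras}
        assert by_era["1995-2004"]["n_genes"] == 65
        assert by_era["1995-2004"]["diagnoses_per_gene"] == 3.3
        assert by_era["1995-2004"]["pct_of_diagnoses"] == 79
        assert by_era["post-2005"]["n_genes"] == 33
        assert by_era["post-2005"]["diagnoses_per_gene"] == 1.2
        assert by_era["post-2005"]["pct_of_diagnoses"] == 15

    def test_single_gene_single_diagnosis(self):
        panel = default_panel()
        gy = discovery_year_rates({"ABCA4": 1}, panel)
        mid = next(e for e in gy.eras if e["era"] == "1995-2004")
        assert mid["n_diagnoses"] == 1 and mid["pct_of_diagnoses"] == 100

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            discovery_year_rates({"NOPE": 1}, default_panel())


class TestGeneSpectrum:
    def test_partition_matches_recount(self):
        def diag(gene):
            return DiagnosisResult(status="confirmed", mode="AR", gene=gene)

        cohort = [
            make_patient("P1", [], diag("ABCA4"), cat="MD/STGD"),
            make_patient("P2", [], diag("ABCA4"), cat="CRD"),
            make_patient("P3", [], diag("ABCA4"), cat="RCD/RP"),
            make_patient("P4", [], diag("EYS"), cat="RCD/RP"),
            make_patient("P5", [], diag("EYS"), cat="RCD/RP"),
            make_patient("P6", []),
        ]
        gs = gene_spectrum(cohort)
        assert gs["n_genes"] == 2
        assert gs["cross_category_genes"] == ["ABCA4"]
        assert gs["single_category_genes"] == ["EYS"]
        assert gs["patients_per_gene"] == {"ABCA4": 3, "EYS": 2}
        assert gs["categories_per_gene"]["ABCA4"] == ["CRD", "MD/STGD", "RCD/RP"]
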