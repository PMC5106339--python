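"""Triage: platform QC boundaries, frequency filters, conservation and
monotonicity properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retdx.regions import GenomicInterval
from retdx.triage import (
    DEFAULT_QC,
    FrequencyRecord,
    FrequencyTable,
    PlatformQC,
    apply_qc,
    is_common_polymorphism,
    recurrence_flag,
    retrospective_af_summary,
    triage_patient,
)
from retdx.variants import GenotypeCall, PatientCase, Variant

from conftest import make_toy_gene, toy_panel


def snv_call(depth, mqv, platform="SOLiD", pos=120, chrom="chrT", alt_reads=None):
    return GenotypeCall(Variant(chrom, pos, "A", "T"), "het", depth, mqv,
                        alt_reads if alt_reads is not None else max(1, depth // 2),
                        platform)


def indel_call(depth, alt_reads, platform="SOLiD", pos=120, chrom="chrT", mqv=60.0):
    return GenotypeCall(Variant(chrom, pos, "AT", "A"), "het", depth, mqv,
                        alt_reads, platform)


class TestPlatformQC:
    @pytest.mark.parametrize(
        "call,platform,expected",
        [
            # first-platform SNV rule: depth ≥18 and MQV strictly >18
            (snv_call(18, 19.0), "SOLiD", True),
            (snv_call(18, 18.0), "SOLiD", False),
            (snv_call(17, 40.0), "SOLiD", False),
            (snv_call(200, 18.01), "SOLiD", True),
            # second-platform SNV rule: depth ≥50 and MQV ≥45 (inclusive)
            (snv_call(50, 45.0, "HiSeq"), "HiSeq", True),
            (snv_call(49, 60.0, "HiSeq"), "HiSeq", False),
            (snv_call(50, 44.9, "HiSeq"), "HiSeq", False),
            # indel rules: strictly >5 supporting reads / strictly >25% of reads
            (indel_call(60, 6), "SOLiD", True),
            (indel_call(60, 5), "SOLiD", False),
            (indel_call(50, 13, "HiSeq"), "HiSeq", True),   # 26%
            (indel_call(50, 12, "HiSeq"), "HiSeq", False),  # 24%
            (indel_call(100, 25, "HiSeq"), "HiSeq", False), # exactly 25%
        ],
    )
    def test_boundary_semantics(self, call, platform, expected):
        ok, _ = apply_qc(call, DEFAULT_QC[platform])
        assert ok is expected

    def test_missing_mqv_fails_closed(self):
        call = snv_call(60, math.nan)
        ok, reason = apply_qc(call, DEFAULT_QC["SOLiD"])
        assert not ok and "missing_metric" in reason

    def test_exactly_one_indel_rule_required(self):
        with pytest.raises(ValueError):
            PlatformQC("X", 10, 10.0, False)
        with pytest.raises(ValueError):
            PlatformQC("X", 10, 10.0, False, min_alt_reads=5, min_alt_fraction=0.2)

    @settings(deadline=None, derandomize=True)
    @given(depth=st.integers(1, 300), mqv=st.floats(1, 99),
           d2=st.integers(0, 50), m2=st.floats(0, 20))
    def test_monotone_in_depth_and_quality(self, depth, mqv, d2, m2):
        base = snv_call(depth, mqv)
        better = snv_call(depth + d2, mqv + m2)
        for qc in DEFAULT_QC.values():
            if apply_qc(base, qc)[0]:
                assert apply_qc(better, qc)[0]


class TestFrequencyRules:
    def test_dbsnp_above_one_percent_is_common(self):
        assert is_common_polymorphism(FrequencyRecord(dbsnp_af=0.02))

    def test_evs_needs_cohort_and_depth_support(self):
        assert is_common_polymorphism(
            FrequencyRecord(evs_af=0.02, evs_mean_depth=20.0, evs_cohort_ok=True))
        assert not is_common_polymorphism(
            FrequencyRecord(evs_af=0.02, evs_mean_depth=10.0, evs_cohort_ok=True))
        assert not is_common_polymorphism(
            FrequencyRecord(evs_af=0.02, evs_mean_depth=20.0, evs_cohort_ok=False))

    def test_below_one_percent_not_common(self):
        assert not is_common_polymorphism(FrequencyRecord(dbsnp_af=0.005, evs_af=0.005,
                                                          evs_mean_depth=60,
                                                          evs_cohort_ok=True))
        assert not is_common_polymorphism(FrequencyRecord())

    def test_exactly_one_percent_not_common(self):
        assert not is_common_polymorphism(FrequencyRecord(dbsnp_af=0.01))

    def test_recurrence_threshold_strict(self):
        rec = FrequencyRecord(inhouse_count=200, inhouse_cohort_size=537)
        assert recurrence_flag(rec, 0.10)
        assert not recurrence_flag(FrequencyRecord(inhouse_count=1,
                                                   inhouse_cohort_size=537), 0.10)
        # exactly at threshold → not flagged
        at = FrequencyRecord(inhouse_count=10, inhouse_cohort_size=100)
        assert not recurrence_flag(at, 0.10)

    def test_zero_cohort_raises(self):
        with pytest.raises(ValueError):
            recurrence_flag(FrequencyRecord(inhouse_count=1, inhouse_cohort_size=0))


def build_case_and_panel():
    """A toy patient with one call in each triage fate."""
    cds = "ATG" + "AAA" * 30 + "TAA"
    rec, _ = make_toy_gene(cds)          # CDS [100, 196) on chrT
    panel = toy_panel([rec])
    calls = [
        snv_call(60, 50.0, pos=120),                       # retained (rare)
        snv_call(60, 50.0, pos=300),                       # off_region
        snv_call(10, 50.0, pos=125),                       # qc_fail (depth)
        snv_call(60, 50.0, pos=130),                       # common polymorphism
        snv_call(60, 50.0, pos=135),                       # recurrent artefact
    ]
    case = PatientCase("P1", "F", "RCD/RP", "SOLiD", calls)
    freqs = FrequencyTable(
        {
            ("chrT", 130, "A", "T"): FrequencyRecord(dbsnp_af=0.2,
                                                     inhouse_cohort_size=537),
            ("chrT", 135, "A", "T"): FrequencyRecord(inhouse_count=100,
                                                     inhouse_cohort_size=537),
        },
        inhouse_cohort_size=537,
    )
    return case, panel, freqs


class TestTriagePatient:
    def test_each_filter_fires_with_recorded_reason(self):
        case, panel, freqs = build_case_and_panel()
        res = triage_patient(case, panel, freqs)
        assert len(res.retained) == 1
        assert res.retained[0].variant.pos == 120
        reasons = {c.variant.pos: r for c, r in res.dropped}
        assert reasons == {300: "off_region", 125: "qc_fail",
                           130: "common_polymorphism", 135: "recurrent_artefact"}

    def test_partition_conserved(self):
        case, panel, freqs = build_case_and_panel()
        res = triage_patient(case, panel, freqs)
        assert len(res) == len(case.calls)

    def test_empty_call_list(self):
        case, panel, freqs = build_case_and_panel()
        empty = PatientCase("P2", "F", "RCD/RP", "SOLiD", [])
        res = triage_patient(empty, panel, freqs)
        assert res.retained == [] and res.dropped == []

    def test_retained_set_matches_independent_predicates(self):
        """Filter-order independence: the retained set equals the
        intersection of each predicate applied independently."""
        case, panel, freqs = build_case_and_panel()
        from retdx.triage import build_clinical_lookup, in_clinical_region

        lookup = build_clinical_lookup(panel)
        expected = [
            c for c in case.calls
            if in_clinical_region(c.variant, lookup)
            and apply_qc(c, DEFAULT_QC["SOLiD"])[0]
            and not is_common_polymorphism(freqs.lookup(c.variant))
            and not recurrence_flag(freqs.lookup(c.variant), 0.10)
        ]
        res = triage_patient(case, panel, freqs)
        assert [c.variant.key() for c in res.retained] == [
            c.variant.key() for c in expected
        ]

    def test_qc_failed_calls_never_frequency_tested(self):
        # a low-depth common variant drops as qc_fail, not common_polymorphism
        case, panel, freqs = build_case_and_panel()
        case.calls[2] = snv_call(10, 50.0, pos=130)
        del case.calls[3]
        res = triage_patient(case, panel, freqs)
        reasons = {c.variant.pos: r for c, r in res.dropped}
        assert reasons[130] == "qc_fail"

    def test_raising_population_af_never_rescues(self):
        case, panel, freqs = build_case_and_panel()
        base = len(triage_patient(case, panel, freqs).retained)
        freqs.records[("chrT", 120, "A", "T")] = FrequencyRecord(dbsnp_af=0.5)
        assert len(triage_patient(case, panel, freqs).retained) <= base


class TestRetrospectiveSummary:
    def test_absent_variants_count_zero(self):
        variants = [Variant("chr1", i, "A", "T") for i in range(5)]
        mean, med, mx, frac = retrospective_af_summary(variants, {})
        assert (mean, med, mx, frac) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_summed_mean(self):
        variants = [Variant("chr1", i, "A", "T") for i in range(10)]
        table = {v.key(): af for v, af in zip(variants, [0.1, 0.3, 0.0, 0.02, 0.0,
                                                         0.0, 0.0, 0.0, 0.0, 0.78])}
        mean, med, mx, frac = retrospective_af_summary(variants, table)
        assert mean == pytest.approx(sum(table.values()) / 10)
        assert mx == 0.78
        assert med == 0.0
        assert frac == pytest.approx(4 / 10)
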