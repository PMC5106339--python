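"""Allele normalization and VCF ingest."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retdx.variants import (
    PatientCase,
    Variant,
    allele_class,
    normalize,
    read_vcf,
    spliced_haplotype,
    trim_alleles,
)


class TestAlleleClass:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "T", "SNV"),
            ("A", "AT", "insertion"),
            ("AT", "A", "deletion"),
            ("AT", "GC", "delins"),
            ("A", "TG", "delins"),
        ],
    )
    def test_classification(self, ref, alt, expected):
        assert allele_class(ref, alt) == expected


def _exhaustive_leftmost_pos(window: str, start: int, normalized: Variant) -> int:
    """Oracle: enumerate every anchored placement with the normalized allele
    lengths that spells the same haplotype; return the smallest position."""
    target = spliced_haplotype(window, start, normalized)
    rl, al = len(normalized.ref), len(normalized.alt)
    positions = []
    from itertools import product

    for p in range(start, start + len(window) - rl + 1):
        r = window[p - start : p - start + rl]
        for a in ("".join(t) for t in product("ACGT", repeat=al)):
            if r == a:
                continue
            hap = window[: p - start] + a + window[p - start + rl :]
            if hap == target:
                positions.append(p)
                break
    return min(positions)


class TestNormalize:
    def test_snv_unchanged(self):
        v = Variant("chr1", 10, "A", "T")
        assert normalize(v, "CCAGG", 8) == v

    def test_shared_flank_trim(self):
        # CAT>CAG at pos 5 → T>G at pos 7
        window = "GGCCATGG"
        v = Variant("chr1", 5, "CAT", "CAG")
        n = normalize(v, window, 2)
        assert (n.pos, n.ref, n.alt) == (7, "T", "G")

    def test_homopolymer_deletion_left_aligned(self):
        # one-T deletion given in right-shifted form inside GTTTTA
        window = "GTTTTA"
        v = Variant("chr1", 3, "TT", "T")
        n = normalize(v, window, 0)
        assert (n.pos, n.ref, n.alt) == (0, "GT", "G")

    def test_ref_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            normalize(Variant("chr1", 2, "A", "T"), "GGGGG", 0)

    def test_identical_alleles_raise(self):
        with pytest.raises(ValueError):
            Variant("chr1", 2, "A", "A")

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        window=st.text(alphabet="AT", min_size=6, max_size=12),
        pos_off=st.integers(0, 4),
        dlen=st.integers(1, 2),
    )
    def test_deletion_agrees_with_exhaustive_oracle(self, window, pos_off, dlen):
        # deletions placed anywhere in a low-complexity window normalize to
        # the representation found by brute-force enumeration
        start = 100
        if pos_off + dlen + 1 >= len(window):
            return
        ref = window[pos_off : pos_off + dlen + 1]
        alt = window[pos_off]
        if ref == alt:
            return
        v = Variant("chr1", start + pos_off, ref, alt)
        n = normalize(v, window, start)
        # haplotype preserved
        assert spliced_haplotype(window, start, n) == spliced_haplotype(window, start, v)
        # idempotent
        assert normalize(n, window, start) == n
        # leftmost among anchored equivalents of the same shape
        assert n.pos == _exhaustive_leftmost_pos(window, start, n)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        window=st.text(alphabet="ACGT", min_size=8, max_size=14),
        pos_off=st.integers(1, 5),
        kind=st.sampled_from(["snv", "del", "ins"]),
    )
    def test_haplotype_invariant_and_idempotent(self, window, pos_off, kind):
        start = 50
        if kind == "snv":
            ref = window[pos_off]
            alt = "A" if ref != "A" else "G"
            v = Variant("chr1", start + pos_off, ref, alt)
        elif kind == "del":
            if pos_off + 2 >= len(window):
                return
            v = Variant("chr1", start + pos_off, window[pos_off : pos_off + 2],
                        window[pos_off])
        else:
            v = Variant("chr1", start + pos_off, window[pos_off],
                        window[pos_off] + "C")
        n = normalize(v, window, start)
        assert spliced_haplotype(window, start, n) == spliced_haplotype(window, start, v)
        assert normalize(n, window, start) == n


VCF_TEMPLATE = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##contig=<ID=chrX,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=MQV,Number=1,Type=Float,Description="Mean quality value">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
{rows}
"""


def write_vcf(path, rows):
    path.write_text(VCF_TEMPLATE.format(rows="\n".join(rows)))
    return path


class TestReadVcf:
    def test_simple_het_snv(self, tmp_path):
        p = write_vcf(tmp_path / "a.vcf",
                      ["chr1\t101\t.\tA\tT\t.\tPASS\t.\tGT:DP:MQV:AD\t0/1:60:50:30,30"])
        case = read_vcf(p, "S1", "F", "RCD/RP", "HiSeq")
        assert len(case.calls) == 1
        call = case.calls[0]
        assert call.zygosity == "het"
        assert (call.variant.pos, call.variant.ref, call.variant.alt) == (100, "A", "T")
        assert call.depth == 60 and call.mqv == 50.0 and call.alt_reads == 30

    def test_biallelic_site_yields_two_het_het_calls(self, tmp_path):
        p = write_vcf(tmp_path / "b.vcf",
                      ["chr1\t101\t.\tA\tT,G\t.\tPASS\t.\tGT:DP:MQV:AD\t1/2:80:50:2,40,38"])
        case = read_vcf(p, "S1", "F", "RCD/RP", "HiSeq")
        assert [c.zygosity for c in case.calls] == ["het_het", "het_het"]
        assert sorted(c.variant.alt for c in case.calls) == ["G", "T"]

    def test_male_chrx_haploid_is_hemi(self, tmp_path):
        p = write_vcf(tmp_path / "c.vcf",
                      ["chrX\t501\t.\tG\tA\t.\tPASS\t.\tGT:DP:MQV:AD\t1:70:60:5,65"])
        case = read_vcf(p, "S1", "M", "RCD/RP", "HiSeq")
        assert case.calls[0].zygosity == "hemi"

    def test_male_chrx_diploid_het_genotype_is_hemi(self, tmp_path):
        p = write_vcf(tmp_path / "d.vcf",
                      ["chrX\t501\t.\tG\tA\t.\tPASS\t.\tGT:DP:MQV:AD\t0/1:70:60:5,65"])
        case = read_vcf(p, "S1", "M", "RCD/RP", "HiSeq")
        assert case.calls[0].zygosity == "hemi"

    def test_hom_alt(self, tmp_path):
        p = write_vcf(tmp_path / "e.vcf",
                      ["chr1\t101\t.\tA\tT\t.\tPASS\t.\tGT:DP:MQV:AD\t1/1:60:50:1,59"])
        case = read_vcf(p, "S1", "F", "RCD/RP", "SOLiD")
        assert case.calls[0].zygosity == "hom"

    def test_missing_gt_raises(self, tmp_path):
        p = write_vcf(tmp_path / "f.vcf",
                      ["chr1\t101\t.\tA\tT\t.\tPASS\t.\tGT:DP:MQV:AD\t./.:60:50:30,30"])
        with pytest.raises(ValueError, match="missing GT"):
            read_vcf(p, "S1", "F", "RCD/RP", "HiSeq")

    def test_indel_alleles_trimmed_on_ingest(self, tmp_path):
        p = write_vcf(tmp_path / "g.vcf",
                      ["chr1\t101\t.\tATT\tAT\t.\tPASS\t.\tGT:DP:MQV:AD\t0/1:60:50:30,30"])
        case = read_vcf(p, "S1", "F", "RCD/RP", "HiSeq")
        v = case.calls[0].variant
        assert (v.ref, v.alt) == ("AT", "A") and v.vclass == "deletion"


class TestPatientCase:
    def test_platform_uniformity_enforced(self):
        from retdx.variants import GenotypeCall

        call = GenotypeCall(Variant("chr1", 5, "A", "T"), "het", 60, 50.0, 30, "SOLiD")
        with pytest.raises(ValueError, match="platform"):
            PatientCase("P1", "F", "RCD/RP", "HiSeq", [call])

    def test_unknown_referral_category_rejected(self):
        with pytest.raises(ValueError, match="referral"):
            PatientCase("P1", "F", "bad-category", "HiSeq")
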