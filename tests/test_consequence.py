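"""Consequence annotation against an independent splice-mutate-translate
oracle, splice-window conventions, indel frame logic, strand symmetry."""

import numpy as np
import pytest

from retdx.consequence import annotate, genomic_to_cds_index, is_novel, revcomp
from retdx.regions import GenomicInterval
from retdx.triage import FrequencyRecord
from retdx.variants import Variant

from conftest import make_toy_gene, oracle_snv_term, random_cds


class TestCodingSnvs:
    def test_stop_gain_in_tiny_cds(self):
        # ATG AAA TGG TAA; codon 2 AAA → TAA is a nonsense change
        rec, _ = make_toy_gene("ATGAAATGGTAA")
        cons = annotate(Variant("chrT", 103, "A", "T"), rec)
        assert cons.term == "stop_gained" and cons.truncating
        assert oracle_snv_term(rec, 103, "T") == "stop_gained"
        assert cons.protein_change == "p.(Lys2Ter)"

    def test_synonymous_and_missense(self):
        rec, _ = make_toy_gene("ATGAAATGGTAA")
        syn = annotate(Variant("chrT", 105, "A", "G"), rec)   # AAA→AAG (Lys)
        assert syn.term == "synonymous" and not syn.truncating
        mis = annotate(Variant("chrT", 104, "A", "G"), rec)   # AAA→AGA (Arg)
        assert mis.term == "missense"
        assert mis.protein_change == "p.(Lys2Arg)"

    def test_start_lost(self):
        rec, _ = make_toy_gene("ATGAAATGGTAA")
        cons = annotate(Variant("chrT", 100, "A", "C"), rec)
        assert cons.term == "start_lost" and cons.truncating

    def test_reference_base_mismatch_raises(self):
        rec, _ = make_toy_gene("ATGAAATGGTAA")
        with pytest.raises(ValueError, match="does not match"):
            annotate(Variant("chrT", 103, "C", "T"), rec)

    def test_thousand_random_snvs_match_translate_oracle(self):
        """Across random multi-exon transcripts on both strands, the
        annotator's coding-SNV terms equal the Biopython-translation oracle."""
        rng = np.random.default_rng(2016)
        checked = 0
        while checked < 1000:
            n_codons = int(rng.integers(4, 40))
            cds = random_cds(rng, n_codons)
            n_exons = int(rng.integers(1, 4))
            cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                                     replace=False)) if n_exons > 1 else []
            lens, prev = [], 0
            for c in list(cuts) + [len(cds)]:
                lens.append(int(c) - prev)
                prev = int(c)
            strand = "+" if rng.random() < 0.5 else "-"
            rec, _ = make_toy_gene(cds, exon_lens=lens, strand=strand)
            tx = rec.transcript
            seg = tx.cds_segments()[int(rng.integers(0, len(tx.cds_segments())))]
            pos = int(rng.integers(seg.start, seg.end))
            idx = genomic_to_cds_index(tx, pos)
            ref_coding = cds[idx]
            ref = ref_coding if strand == "+" else revcomp(ref_coding)
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            cons = annotate(Variant("chrT", pos, ref, alt), rec)
            expected = oracle_snv_term(rec, pos, alt)  # genomic-strand alt
            assert cons.term == expected, (cds, pos, ref, alt, strand)
            checked += 1

    def test_reverse_strand_twin_produces_identical_terms(self):
        rng = np.random.default_rng(7)
        cds = random_cds(rng, 20)
        fwd, _ = make_toy_gene(cds, exon_lens=[30, 30], strand="+")
        rev, _ = make_toy_gene(cds, exon_lens=[30, 30], strand="-")
        # the reverse twin lays revcomp(cds) on the genome; a forward-gene
        # variant at CDS index i maps to the mirrored genomic position
        for pos in range(100, 130):
            i = genomic_to_cds_index(fwd.transcript, pos)
            ref = cds[i]
            alt = "A" if ref != "A" else "G"
            f = annotate(Variant("chrT", pos, ref, alt), fwd)
            # find the reverse gene's genomic position with the same CDS index
            rpos = next(p for seg in rev.transcript.cds_segments()
                        for p in range(seg.start, seg.end)
                        if genomic_to_cds_index(rev.transcript, p) == i)
            r = annotate(Variant("chrT", rpos, revcomp(ref), revcomp(alt)), rev)
            assert f.term == r.term


class TestSpliceWindow:
    @pytest.fixture()
    def two_exon_gene(self):
        rec, _ = make_toy_gene(random_cds(np.random.default_rng(1), 20),
                               exon_lens=[30, 30], intron=30)
        return rec  # exon1 [100,130), intron [130,160), exon2 [160,190)

    @pytest.mark.parametrize("offset,term", [
        (0, "canonical_splice"),   # intron +1
        (1, "canonical_splice"),   # intron +2
        (2, "splice_region"),      # intron +3
        (4, "splice_region"),      # intron +5
    ])
    def test_donor_side_positions(self, two_exon_gene, offset, term):
        cons = annotate(Variant("chrT", 130 + offset, "A", "G"), two_exon_gene)
        assert cons.term == term and not cons.truncating

    @pytest.mark.parametrize("offset,term", [
        (1, "canonical_splice"),   # intron -1
        (2, "canonical_splice"),
        (3, "splice_region"),
        (5, "splice_region"),
    ])
    def test_acceptor_side_positions(self, two_exon_gene, offset, term):
        cons = annotate(Variant("chrT", 160 - offset, "A", "G"), two_exon_gene)
        assert cons.term == term

    def test_deep_intronic_position_rejected(self, two_exon_gene):
        with pytest.raises(ValueError, match="outside"):
            annotate(Variant("chrT", 145, "A", "G"), two_exon_gene)


class TestIndels:
    @pytest.fixture()
    def gene(self):
        rec, _ = make_toy_gene(random_cds(np.random.default_rng(3), 30))
        return rec  # single exon CDS [100, 190)

    def test_two_base_deletion_is_frameshift(self, gene):
        cds = gene.transcript.cds_sequence
        cons = annotate(Variant("chrT", 110, cds[10:13], cds[10]), gene)
        assert cons.term == "frameshift" and cons.truncating

    def test_codon_aligned_deletion_is_inframe(self, gene):
        cds = gene.transcript.cds_sequence
        cons = annotate(Variant("chrT", 109, cds[9:13], cds[9]), gene)
        assert cons.term == "inframe_deletion" and not cons.truncating

    def test_insertion_in_cds(self, gene):
        cds = gene.transcript.cds_sequence
        ins1 = annotate(Variant("chrT", 110, cds[10], cds[10] + "G"), gene)
        assert ins1.term == "frameshift"
        ins3 = annotate(Variant("chrT", 110, cds[10], cds[10] + "GGG"), gene)
        assert ins3.term == "inframe_insertion"

    def test_splice_flank_indel(self):
        rec, _ = make_toy_gene(random_cds(np.random.default_rng(4), 20),
                               exon_lens=[30, 30], intron=30)
        cons = annotate(Variant("chrT", 132, "AT", "A"), rec)  # intron +3/+4
        assert cons.term == "splice_region"

    def test_length_preserving_delins_truncating_when_stop_introduced(self, gene):
        cds = gene.transcript.cds_sequence
        # replace codon 2 with TAA in place → premature stop via delins
        cons = annotate(Variant("chrT", 103, cds[3:6], "TAA"), gene)
        assert cons.term == "coding_delins" and cons.truncating

    def test_length_preserving_delins_non_truncating(self, gene):
        cds = gene.transcript.cds_sequence
        target = "AAA" if cds[3:6] != "AAA" else "CCC"
        cons = annotate(Variant("chrT", 103, cds[3:6], target), gene)
        assert cons.term == "coding_delins" and not cons.truncating


class TestSpecialSite:
    def test_cep290_style_hotspot(self):
        rec, _ = make_toy_gene(random_cds(np.random.default_rng(5), 20),
                               exon_lens=[30, 30], intron=30)
        site = GenomicInterval("chrT", 140, 150)
        cons = annotate(Variant("chrT", 144, "A", "G"), rec, special_sites=[site])
        assert cons.term == "intronic_special"


class TestNovelty:
    def test_absent_from_both_databases_is_novel(self):
        v = Variant("chr1", 5, "A", "T")
        assert is_novel(v, FrequencyRecord())

    def test_presence_at_any_frequency_defeats_novelty(self):
        v = Variant("chr1", 5, "A", "T")
        assert not is_novel(v, FrequencyRecord(dbsnp_af=0.0001))
        assert not is_novel(v, FrequencyRecord(evs_af=0.0001))
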