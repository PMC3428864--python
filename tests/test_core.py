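import numpy as np
import pytest

from clonehistory.core import (
    SampleMeta,
    MutationCall,
    CNSegment,
    PhasedSNP,
    ReadPairEvidence,
    ParseError,
    substitution_class,
    read_mutations,
    write_mutations,
    read_segments,
    write_segments,
    read_phased_snps,
    write_phased_snps,
    read_read_pairs,
    write_read_pairs,
    attach_copy_number,
)


class TestDomainTypes:
    def test_sample_meta_invariants(self):
        with pytest.raises(ValueError):
            SampleMeta(purity=0.0)
        with pytest.raises(ValueError):
            SampleMeta(purity=1.2)
        with pytest.raises(ValueError):
            SampleMeta(purity=0.5, ploidy=-1.0)

    def test_mutation_rejects_more_alt_than_depth(self):
        with pytest.raises(ValueError):
            MutationCall("chr1", 100, "A", "T", depth=210, alt_reads=300)

    def test_subclonal_segment_states_must_differ_by_one_copy(self):
        with pytest.raises(ValueError):
            CNSegment(
                "chr1", 0, 100, subclonal=True, nA1=2, nB1=0, nA2=1, nB2=1, tau=0.5
            )
        seg = CNSegment(
            "chr13", 0, 100, subclonal=True, nA1=1, nB1=0, nA2=1, nB2=1, tau=0.68
        )
        assert seg.total_cn == pytest.approx(0.68 * 1 + 0.32 * 2)

    def test_read_pair_counts_nonnegative(self):
        with pytest.raises(ValueError):
            ReadPairEvidence(locus_a=1, locus_b=2, n_both=-1, n_a_only=0, n_b_only=0)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("C", "T", "C>T"),
        ("G", "A", "C>T"),  # purine strand complemented
        ("A", "C", "T>G"),
        ("T", "A", "T>A"),
    ],
)
def test_substitution_class_pyrimidine_normalization(ref, alt, expected):
    assert substitution_class(ref, alt) == expected


class TestMutationIO:
    def test_tsv_row_maps_directly(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tdepth\talt_reads\ttumor_cn\tnormal_cn\n"
            "chr1\t1000\tA\tT\t210\t74\t2\t2\n"
        )
        (m,) = read_mutations(p)
        assert (m.depth, m.alt_reads, m.pos) == (210, 74, 1000)

    def test_alt_exceeding_depth_rejected_with_line(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tdepth\talt_reads\nchr1\t1\tA\tT\t210\t300\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_mutations(p)

    def test_missing_depth_column_is_explicit_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tpos\tref\talt\nchr1\t1\tA\tT\n")
        with pytest.raises(ParseError, match="depth"):
            read_mutations(p)

    def test_vcf_roundtrip_preserves_ad_convention(self, tmp_path):
        muts = [
            MutationCall("chr1", 1000, "A", "T", depth=210, alt_reads=74),
            MutationCall("chr2", 55, "G", "C", depth=60, alt_reads=12, context="TCA"),
        ]
        p = tmp_path / "m.vcf"
        write_mutations(muts, p, format="vcf")
        back = read_mutations(p, format="vcf")
        assert [(m.chrom, m.pos, m.ref, m.alt, m.depth, m.alt_reads) for m in back] == [
            (m.chrom, m.pos, m.ref, m.alt, m.depth, m.alt_reads) for m in muts
        ]
        assert back[1].context == "TCA"

    def test_tsv_roundtrip_identity(self, tmp_path):
        muts = [
            MutationCall(
                "chr1", 5, "C", "G", depth=100, alt_reads=0, tumor_cn=3.0, context="ACA"
            )
        ]
        p = tmp_path / "m.tsv"
        write_mutations(muts, p)
        (m,) = read_mutations(p)
        assert (m.tumor_cn, m.alt_reads, m.context) == (3.0, 0, "ACA")


class TestSegmentIO:
    def test_roundtrip_including_subclonal_fields(self, tmp_path):
        segs = [
            CNSegment("chr3", 0, 10_000, logr=0.0, nA=1, nB=1),
            CNSegment(
                "chr13",
                0,
                114_000_000,
                logr=-0.39,
                nA=1.0,
                nB=0.32,
                subclonal=True,
                nA1=1,
                nB1=0,
                nA2=1,
                nB2=1,
                tau=0.68,
                tau_ci=(0.67, 0.69),
            ),
        ]
        p = tmp_path / "s.tsv"
        write_segments(segs, p)
        back = read_segments(p)
        assert back[1].state1 == (1, 0) and back[1].state2 == (1, 1)
        assert back[1].tau == pytest.approx(0.68)
        assert back[1].tau_ci == (0.67, 0.69)
        assert not back[0].subclonal

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("")
        assert read_segments(p) == []

    def test_overlapping_segments_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "chrom\tstart\tend\nchr1\t0\t1000\nchr1\t500\t2000\n"
        )
        with pytest.raises(ParseError, match="overlap"):
            read_segments(p)

    def test_phased_snp_and_read_pair_roundtrip(self, tmp_path):
        snps = [PhasedSNP("chr13", 100, 30, 70, block_id=2)]
        pairs = [ReadPairEvidence(chrom="chr1", locus_a=10, locus_b=500, n_both=1, n_a_only=2, n_b_only=0, n_neither=9)]
        p1, p2 = tmp_path / "snp.tsv", tmp_path / "rp.tsv"
        write_phased_snps(snps, p1)
        write_read_pairs(pairs, p2)
        (s,) = read_phased_snps(p1)
        (r,) = read_read_pairs(p2)
        assert (s.hap1_reads, s.hap2_reads, s.block_id) == (30, 70, 2)
        assert (r.n_both, r.n_a_only, r.n_neither) == (1, 2, 9)


def test_attach_copy_number_fills_and_drops():
    segs = [CNSegment("chr1", 0, 1000, nA=2, nB=1)]
    inside = MutationCall("chr1", 500, "C", "T", 100, 30)
    outside = MutationCall("chr2", 500, "C", "T", 100, 30)
    kept = attach_copy_number([inside, outside], segs)
    assert len(kept) == 1 and kept[0].tumor_cn == 3.0
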