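"""I/O layer: FASTA/FASTQ normalization, SAM/PAF parsing, round trips."""

import pytest
from hypothesis import given, strategies as st

from telocap.errors import FormatError
from telocap.seqio import (
    AlnRecord,
    SeqRecord,
    parse_cigar,
    read_alignments,
    read_fasta,
    read_fastq,
    revcomp,
    write_fasta,
    write_sam,
)

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:2000\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_case_and_ambiguity_normalization(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\nacgt\n>c2\nACRT\n>c3\nACGU\n")
        recs = read_fasta(p)
        assert [(r.id, r.sequence) for r in recs] == [
            ("c1", "ACGT"),
            ("c2", "ACNT"),
            ("c3", "ACGT"),
        ]

    def test_empty_sequence_is_format_error(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\n")
        with pytest.raises(FormatError, match="c1"):
            read_fasta(p)

    def test_non_fasta_content_rejected(self, tmp_path):
        p = _write(tmp_path, "a.fa", "ACGT\n")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_wrapping_arithmetic(self, tmp_path):
        p = tmp_path / "w.fa"
        write_fasta([SeqRecord("c1", "A" * 130)], p, line_width=60)
        lines = p.read_text().splitlines()
        assert lines[0] == ">c1"
        assert [len(l) for l in lines[1:]] == [60, 60, 10]

    @given(
        st.lists(
            st.tuples(
                st.from_regex(r"[A-Za-z0-9_.]{1,12}", fullmatch=True),
                st.text(alphabet="ACGTN", min_size=1, max_size=200),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_identity(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("fa") / "rt.fa"
        recs = [SeqRecord(i, s) for i, s in records]
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in recs]


class TestFastq:
    def test_lookup_and_normalization(self, tmp_path):
        p = _write(tmp_path, "r.fq", "@r1\nacgt\n+\nIIII\n@r2\nTTTT\n+\nIIII\n")
        assert read_fastq(p) == {"r1": "ACGT", "r2": "TTTT"}


class TestSam:
    def test_coordinate_conversion_and_clip_arithmetic(self, tmp_path):
        # POS=901 1-based with 100M50S on a 150-base read
        sam = SAM_HEADER + "r1\t0\tc1\t901\t60\t100M50S\t*\t0\t0\t" + "A" * 150 + "\t*\n"
        recs = read_alignments(_write(tmp_path, "a.sam", sam), "sam")
        (r,) = recs
        assert (r.ref_start, r.ref_end) == (900, 1000)
        assert (r.read_start, r.read_end) == (0, 100)
        assert r.aligned_read_bases == 100
        assert r.read_length == 150

    def test_unmapped_and_secondary_dropped_supplementary_kept(self, tmp_path):
        rows = [
            "u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*",
            "s1\t256\tc1\t1\t60\t4M\t*\t0\t0\tACGT\t*",
            "p1\t2048\tc1\t1\t60\t4M146H\t*\t0\t0\tACGT\t*",
        ]
        recs = read_alignments(_write(tmp_path, "a.sam", SAM_HEADER + "\n".join(rows) + "\n"), "sam")
        assert [r.read_id for r in recs] == ["p1"]
        assert recs[0].is_supplementary and recs[0].has_hard_clip
        assert recs[0].read_length == 150

    def test_missing_cigar_skipped_and_counted(self, tmp_path):
        sam = SAM_HEADER + "r1\t0\tc1\t1\t60\t*\t*\t0\t0\tACGT\t*\n"
        summary = {}
        recs = read_alignments(_write(tmp_path, "a.sam", sam), "sam", summary=summary)
        assert recs == []
        assert summary["skipped_no_cigar"] == 1

    def test_write_sam_round_trip(self, tmp_path, small_scenario):
        path = tmp_path / "sim.sam"
        chrom_lengths = {r.id: len(r.sequence) for r in small_scenario.truncated_genome}
        write_sam(small_scenario.alignments, chrom_lengths, path)
        back = read_alignments(path, "sam")
        orig = small_scenario.alignments
        assert len(back) == len(orig)
        for a, b in zip(sorted(orig, key=lambda r: r.read_id), sorted(back, key=lambda r: r.read_id)):
            assert (a.read_id, a.ref_id, a.ref_start, a.ref_end) == (
                b.read_id, b.ref_id, b.ref_start, b.ref_end,
            )
            assert (a.read_start, a.read_end, a.strand, a.aligned_read_bases) == (
                b.read_start, b.read_end, b.strand, b.aligned_read_bases,
            )
            assert a.seq == b.seq


class TestPaf:
    PAF = (
        "r1\t150\t0\t50\t+\tc1\t2000\t100\t150\t50\t50\t60\tcg:Z:50M\n"
        "r2\t150\t0\t50\t-\tc1\t2000\t100\t150\t50\t50\t60\tcg:Z:50M\n"
        "r3\t150\t0\t50\t+\tc1\t2000\t100\t150\t50\t50\t60\n"
        "r4\t150\t0\t50\t+\tc1\t2000\t100\t150\t50\t50\t60\ttp:A:S\tcg:Z:50M\n"
    )

    def test_cigar_arithmetic_and_strand_conversion(self, tmp_path):
        summary = {}
        recs = read_alignments(_write(tmp_path, "a.paf", self.PAF), "paf", summary=summary)
        assert [r.read_id for r in recs] == ["r1", "r2"]
        assert recs[0].aligned_read_bases == 50
        # minus strand: read interval flips into stored orientation
        assert (recs[1].read_start, recs[1].read_end) == (100, 150)
        # r3 lacks cg, r4 is secondary
        assert summary["skipped_no_cigar"] == 1


class TestCigar:
    @given(
        st.lists(
            st.tuples(st.sampled_from("MIDNSH=X"), st.integers(1, 99)),
            min_size=1,
            max_size=12,
        )
    )
    def test_aligned_bases_match_naive_reparse(self, ops):
        cigar = "".join(f"{n}{op}" for op, n in ops)
        parsed = parse_cigar(cigar)
        # naive oracle: scan character runs directly
        naive = sum(n for op, n in ops if op in "M=X")
        assert sum(n for op, n in parsed if op in "M=X") == naive

    def test_malformed_cigar_rejected(self):
        with pytest.raises(FormatError):
            parse_cigar("12Q")


def test_revcomp_involution():
    s = "ACGTNNACGT"
    assert revcomp(revcomp(s)) == s
    assert revcomp("TTTAGGG") == "CCCTAAA"
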