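"""Terminal-read selection: gates, orientation, truth equality, monotonicity."""

import pytest

from telocap.errors import DataError
from telocap.seqio import AlnRecord, revcomp
from telocap.terminal_reads import FilterParams, TerminalRead, downsample_support, extract_terminal_reads

CHROMS = {"c1": 1000}


def aln(read_id="r1", ref_start=900, ref_end=1000, read_start=0, read_end=100,
        read_length=250, mapq=60, strand="+", seq=None, aligned=None, **kw):
    return AlnRecord(
        read_id=read_id, ref_id="c1", ref_start=ref_start, ref_end=ref_end,
        read_start=read_start, read_end=read_end, strand=strand, mapq=mapq,
        aligned_read_bases=aligned if aligned is not None else read_end - read_start,
        read_length=read_length, seq=seq or "A" * read_length, **kw,
    )


class TestGates:
    def test_right_terminal_read_passes_all_gates(self):
        groups = extract_terminal_reads([aln()], None, CHROMS, FilterParams(min_overhang=150))
        (tr,) = groups[("c1", "R")]
        assert tr.side == "R" and len(tr.overhang_seq) == 150

    def test_internal_alignment_ignored(self):
        rec = aln(ref_start=400, ref_end=600, read_end=200, read_length=250)
        assert extract_terminal_reads([rec], None, CHROMS, FilterParams()) == {}

    def test_align_ratio_gate(self):
        rec = aln(aligned=70)  # ratio 0.28 < 0.4
        assert extract_terminal_reads([rec], None, CHROMS, FilterParams()) == {}

    def test_mapq_gate(self):
        rec = aln(mapq=5)
        assert extract_terminal_reads([rec], None, CHROMS, FilterParams()) == {}

    def test_short_overhang_gate(self):
        rec = aln(read_end=200, read_length=250)  # 50 bp clip < 200
        assert extract_terminal_reads([rec], None, CHROMS, FilterParams()) == {}

    def test_left_overhang_reverse_complemented_outward(self):
        seq = "G" * 150 + "A" * 100  # clip then anchor, ref-forward
        rec = aln(ref_start=0, ref_end=100, read_start=150, read_end=250, seq=seq)
        groups = extract_terminal_reads([rec], None, CHROMS, FilterParams(min_overhang=150))
        (tr,) = groups[("c1", "L")]
        assert tr.side == "L"
        assert tr.overhang_seq == revcomp("G" * 150) == "C" * 150

    def test_duplicate_read_keeps_most_aligned_record(self):
        a = aln(read_id="r1", aligned=100)
        b = aln(read_id="r1", ref_start=850, read_end=160, read_length=360, aligned=160)
        groups = extract_terminal_reads([a, b], None, CHROMS, FilterParams(min_overhang=150))
        (tr,) = groups[("c1", "R")]
        assert len(tr.overhang_seq) == 200  # from the 160-bases-aligned record

    def test_hard_clip_requires_read_lookup(self):
        rec = aln(seq="A" * 100, has_hard_clip=True, cigar="100M150H")
        params = FilterParams(min_overhang=150)
        summary = {}
        groups = extract_terminal_reads([rec], None, CHROMS, params, summary=summary)
        assert groups == {} and summary["skipped_no_sequence"] == 1
        lookup = {"r1": "A" * 100 + "T" * 150}
        groups = extract_terminal_reads([rec], lookup, CHROMS, params)
        (tr,) = groups[("c1", "R")]
        assert tr.overhang_seq == "T" * 150

    def test_unknown_contig_is_data_error(self):
        with pytest.raises(DataError):
            extract_terminal_reads([aln()], None, {"other": 500}, FilterParams())


class TestTruthEquality:
    @pytest.mark.parametrize("end", [("chr1", "R"), ("chr2", "L")])
    def test_emitted_reads_equal_truth_spanning_set(self, small_scenario, end):
        params = FilterParams()
        groups = extract_terminal_reads(
            small_scenario.alignments,
            small_scenario.lookup,
            {r.id: len(r.sequence) for r in small_scenario.truncated_genome},
            params,
        )
        emitted = {tr.read_id for tr in groups.get(end, [])}
        expected = set()
        for read_id, (ov, anchored) in small_scenario.truth.spanning(*end).items():
            rt = small_scenario.truth.reads[read_id]
            read_len = rt.end - rt.start  # error-free: read bases = truth bases
            if ov >= params.min_overhang and anchored / read_len >= params.min_align_ratio:
                expected.add(read_id)
        assert emitted == expected and emitted

    def test_overhangs_match_truth_sequence(self, small_scenario):
        """Error-free overhangs are exact prefixes of the removed sequence."""
        groups = extract_terminal_reads(
            small_scenario.alignments,
            small_scenario.lookup,
            {r.id: len(r.sequence) for r in small_scenario.truncated_genome},
            FilterParams(),
        )
        for end, trs in groups.items():
            removed = small_scenario.truth.ends[end].removed_outward
            for tr in trs:
                assert removed.startswith(tr.overhang_seq)

    def test_gate_tightening_yields_subset(self, small_scenario):
        chrom_lengths = {r.id: len(r.sequence) for r in small_scenario.truncated_genome}
        base = extract_terminal_reads(
            small_scenario.alignments, small_scenario.lookup, chrom_lengths, FilterParams()
        )
        tighter = [
            FilterParams(min_mapq=61),
            FilterParams(min_overhang=400),
            FilterParams(min_align_ratio=0.8),
        ]
        for params in tighter:
            sub = extract_terminal_reads(
                small_scenario.alignments, small_scenario.lookup, chrom_lengths, params
            )
            for end, trs in sub.items():
                assert {t.read_id for t in trs} <= {t.read_id for t in base[end]}


class TestDownsample:
    def _mk(self, read_id, n):
        return TerminalRead(
            read_id=read_id, chrom="c1", side="R", anchor_ref_start=0,
            anchor_ref_end=100, overhang_seq="A" * n, anchor_identity=1.0,
            align_ratio=0.5, mapq=60,
        )

    def test_identity_when_under_cap(self):
        group = [self._mk(f"r{i}", 100 + i) for i in range(5)]
        assert downsample_support(group, 60) == group

    def test_longest_overhangs_kept(self):
        group = [self._mk(f"r{i:03d}", 100 + i) for i in range(100)]
        kept = downsample_support(group, 60, seed=1)
        assert len(kept) == 60
        assert min(len(t.overhang_seq) for t in kept) == 140

    def test_tie_broken_by_read_id(self):
        group = [self._mk("zz", 100), self._mk("aa", 100), self._mk("mm", 100)]
        kept = downsample_support(group, 2)
        assert [t.read_id for t in kept] == ["aa", "mm"]
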