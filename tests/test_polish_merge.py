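"""Polishing behaviour, merge contracts, and the in-memory pipeline."""

import pytest

from telocap._align import identity
from telocap.end_assembly import DraftExtension, anchored_consensus
from telocap.errors import DataError
from telocap.polish_merge import (
    MergeParams,
    PolishParams,
    STATUS_ANCHOR_MISMATCH,
    STATUS_INSUFFICIENT,
    merge_extension,
    polish,
    run_pipeline,
)
from telocap.seqio import SeqRecord, revcomp
from telocap.telomotif import TelomereMotif, count_motif
from telocap.terminal_reads import FilterParams, TerminalRead, extract_terminal_reads

MOTIF = TelomereMotif("TTTAGGG")


def tread(seq, read_id="r1", side="R", chrom="c1", anchor=""):
    return TerminalRead(
        read_id=read_id, chrom=chrom, side=side, anchor_ref_start=0,
        anchor_ref_end=100, overhang_seq=seq, anchor_identity=1.0,
        align_ratio=0.5, mapq=60, anchor_seq=anchor,
    )


def draft_of(seq, side="R", chrom="c1", anchor=None, support=None):
    return DraftExtension(
        chrom=chrom, side=side, sequence=seq,
        support=support or (10,) * len(seq), n_reads=10, anchor_seq=anchor,
    )


class TestPolish:
    def test_error_free_truth_is_fixed_point(self, small_scenario):
        end = ("chr1", "R")
        truth_seq = small_scenario.truth.ends[end].removed_outward
        group = self._group(small_scenario, end)
        draft = draft_of(truth_seq, side="R", chrom="chr1")
        polished = polish(draft, group)
        assert polished.sequence == truth_seq

    def test_seeded_error_corrected_in_one_round(self, small_scenario):
        end = ("chr1", "R")
        truth_seq = small_scenario.truth.ends[end].removed_outward
        corrupted = truth_seq[:50] + "C" + truth_seq[51:]
        corrupted = corrupted[:300] + corrupted[301:]  # plus one deletion
        group = self._group(small_scenario, end)
        polished = polish(draft_of(corrupted, chrom="chr1"), group, PolishParams(max_rounds=1))
        assert polished.sequence == truth_seq

    def test_noisy_polish_never_worse(self, noisy_scenario):
        for end in [("chr1", "R"), ("chr2", "L")]:
            truth_seq = noisy_scenario.truth.ends[end].removed_outward
            group = self._group(noisy_scenario, end)
            draft = anchored_consensus(group)
            before = identity(draft.sequence, truth_seq[: len(draft.sequence)])
            polished = polish(draft, group)
            after = identity(polished.sequence, truth_seq[: len(polished.sequence)])
            assert after >= before

    def test_zero_length_draft_returned_unchanged(self):
        d = DraftExtension("c1", "R", "", (), 3)
        assert polish(d, []) is d

    @staticmethod
    def _group(scenario, end):
        groups = extract_terminal_reads(
            scenario.alignments,
            scenario.lookup,
            {r.id: len(r.sequence) for r in scenario.truncated_genome},
            FilterParams(),
        )
        return groups[end]


class TestMerge:
    GENOME = [SeqRecord("c1", "ACGT" * 250)]

    def test_right_append_preserves_original(self):
        ext = "TTTAGGG" * 100
        anchor = self.GENOME[0].sequence[-600:]
        out, audit = merge_extension(self.GENOME, draft_of(ext, anchor=anchor))
        assert audit.status == "merged" and audit.added_bp == 700
        assert out[0].sequence[:1000] == self.GENOME[0].sequence
        assert out[0].sequence[1000:] == ext

    def test_left_prepend_reverse_complements(self):
        ext = "TTTAGGG" * 100  # outward orientation at an L end
        anchor = self.GENOME[0].sequence[:600]
        out, audit = merge_extension(self.GENOME, draft_of(ext, side="L", anchor=anchor))
        assert audit.status == "merged"
        assert out[0].sequence[:700] == revcomp(ext)
        assert out[0].sequence[700:] == self.GENOME[0].sequence
        # forward strand begins with C-rich copies
        assert out[0].sequence.startswith("CCCTAAA")

    def test_corrupted_anchor_refused_genome_untouched(self):
        good = self.GENOME[0].sequence[-500:]
        # corrupt 20% of anchor positions -> identity ~0.80 < 0.95
        bad = "".join(
            ("A" if c != "A" else "C") if i % 5 == 0 else c for i, c in enumerate(good)
        )
        out, audit = merge_extension(self.GENOME, draft_of("TTTAGGG" * 100, anchor=bad))
        assert audit.status == STATUS_ANCHOR_MISMATCH
        assert audit.added_bp == 0
        assert out[0].sequence == self.GENOME[0].sequence
        assert audit.anchor_identity < 0.95

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(DataError):
            merge_extension(self.GENOME, draft_of("A" * 200, chrom="nope"))


class TestPipeline:
    def test_exactly_the_truncated_ends_are_merged(self, small_scenario):
        ext, audits = run_pipeline(
            small_scenario.truncated_genome,
            small_scenario.lookup,
            small_scenario.alignments,
            MOTIF,
            min_run_bp=500,
        )
        by_end = {(a.chrom, a.side): a for a in audits}
        assert set(by_end) == {("chr1", "R"), ("chr2", "L")}
        for end, audit in by_end.items():
            assert audit.status == "merged"
            assert audit.added_bp == small_scenario.truth.ends[end].truncated_bp

    def test_telomere_gain_at_merged_ends(self, small_scenario):
        ext, audits = run_pipeline(
            small_scenario.truncated_genome,
            small_scenario.lookup,
            small_scenario.alignments,
            MOTIF,
            min_run_bp=500,
        )
        before = {r.id: r.sequence for r in small_scenario.truncated_genome}
        after = {r.id: r.sequence for r in ext}
        for a in audits:
            if a.status != "merged":
                continue
            b_win = before[a.chrom][:10000] if a.side == "L" else before[a.chrom][-10000:]
            a_win = after[a.chrom][:10000] if a.side == "L" else after[a.chrom][-10000:]
            assert count_motif(a_win, MOTIF) > count_motif(b_win, MOTIF)

    def test_min_support_above_depth_reports_insufficient(self, small_scenario):
        ext, audits = run_pipeline(
            small_scenario.truncated_genome,
            small_scenario.lookup,
            small_scenario.alignments,
            MOTIF,
            filter_params=FilterParams(min_support=500),
            min_run_bp=500,
        )
        assert all(a.status == STATUS_INSUFFICIENT for a in audits)
        assert len(audits) == 2
        assert [r.sequence for r in ext] == [
            r.sequence for r in small_scenario.truncated_genome
        ]

    def test_genome_preservation_and_length_accounting(self, noisy_scenario):
        ext, audits = run_pipeline(
            noisy_scenario.truncated_genome,
            noisy_scenario.lookup,
            noisy_scenario.alignments,
            MOTIF,
            min_run_bp=500,
        )
        added = {(a.chrom, a.side): a.added_bp for a in audits}
        for orig, new in zip(noisy_scenario.truncated_genome, ext):
            add_l = added.get((orig.id, "L"), 0)
            add_r = added.get((orig.id, "R"), 0)
            assert len(new.sequence) - len(orig.sequence) == add_l + add_r
            assert new.sequence[add_l : add_l + len(orig.sequence)] == orig.sequence

    def test_determinism(self, small_scenario):
        args = (
            small_scenario.truncated_genome,
            small_scenario.lookup,
            small_scenario.alignments,
            MOTIF,
        )
        a_ext, a_aud = run_pipeline(*args, min_run_bp=500, seed=3)
        b_ext, b_aud = run_pipeline(*args, min_run_bp=500, seed=3)
        assert [r.sequence for r in a_ext] == [r.sequence for r in b_ext]
        assert a_aud == b_aud
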