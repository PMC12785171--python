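"""Anchored consensus assembly of end-group overhangs.

Because every overhang starts at the chromosome terminus, the group shares a
common origin: Phase 1 places all reads at column 0 against the longest
overhang and takes per-column majority votes over {A,C,G,T,-}. Phase 2
greedily elongates the consensus with reads whose prefix overlaps its
suffix at high identity — the anchored analogue of overlap-layout-consensus,
sufficient at this scale because no all-vs-all overlap discovery is needed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from telocap._align import build_profile, column_vote as _column_vote, consensus_from_profile
from telocap.errors import ParameterError
from telocap.terminal_reads import TerminalRead

__all__ = ["DraftExtension", "AsmParams", "anchored_consensus", "column_vote"]


def column_vote(column_bases) -> str:
    """Majority vote over one consensus column (see _align.column_vote)."""
    return _column_vote(Counter(column_bases))


@dataclass(frozen=True)
class AsmParams:
    """Assembly knobs for overhang consensus and greedy elongation."""

    min_overlap_bp: int = 100
    min_overlap_identity: float = 0.9
    min_tail_support: int = 2
    band_bp: int = 50

    def __post_init__(self) -> None:
        if self.min_overlap_bp < 20:
            raise ParameterError("min_overlap_bp must be >= 20")
        if not (0 < self.min_overlap_identity <= 1):
            raise ParameterError("min_overlap_identity must be in (0, 1]")


@dataclass
class DraftExtension:
    """Consensus extension for one chromosome end.

    ``sequence`` holds only novel bases beyond the original terminus,
    oriented outward; ``support`` is the per-base read depth from actual
    placements. ``anchor_seq`` is the read-consensus of the genome-adjacent
    region, used by the merge step to verify the junction.
    """

    chrom: str
    side: str
    sequence: str
    support: tuple[int, ...]
    n_reads: int
    anchor_seq: str | None = None
    no_extension: bool = False

    def __post_init__(self) -> None:
        if len(self.support) != len(self.sequence):
            raise ParameterError("support length must equal sequence length")


def _trim_to_support(seq: str, depth: list[int], min_tail_support: int) -> tuple[str, list[int]]:
    end = 0
    for i, d in enumerate(depth):
        if d >= min_tail_support:
            end = i + 1
    return seq[:end], depth[:end]


def _anchored_fit(consensus: str, read: str, threshold: float) -> bool:
    """Does the read belong at the terminus (column 0) of the consensus?"""
    if len(read) >= len(consensus):
        res = edlib.align(consensus, read, mode="SHW", task="distance")
        denom = len(consensus)
    else:
        res = edlib.align(read, consensus, mode="SHW", task="distance")
        denom = len(read)
    if res["editDistance"] < 0 or denom == 0:
        return False
    return 1.0 - res["editDistance"] / denom >= threshold


def _extension_from(consensus: str, read: str, p: int, params: AsmParams):
    """Extension obtained by aligning consensus[p:] to a prefix of the read."""
    overlap_t = consensus[p:]
    if len(overlap_t) < params.min_overlap_bp:
        return None
    res = edlib.align(overlap_t, read, mode="SHW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    end_in_read = res["locations"][0][1] + 1
    ident = 1.0 - res["editDistance"] / len(overlap_t)
    if ident < params.min_overlap_identity:
        return None
    extension = read[end_in_read:]
    if len(extension) < params.min_overlap_bp:
        return None
    return len(overlap_t), ident, extension


def _overlap_extension(
    consensus: str, read: str, params: AsmParams
) -> tuple[int, float, str] | None:
    """Find a suffix(consensus)/prefix(read) overlap and the bases past it.

    A read that fits its anchored placement (it abuts the terminus like the
    consensus does) may only extend from column 0 — otherwise, in a pure
    repeat array, a phase-shifted seed match would fabricate extra copies.
    Only reads that cannot be placed at the terminus get the free
    suffix/prefix overlap search.
    """
    if len(consensus) < params.min_overlap_bp or len(read) < params.min_overlap_bp:
        return None
    if _anchored_fit(consensus, read, params.min_overlap_identity):
        if len(read) <= len(consensus):
            return None
        return _extension_from(consensus, read, 0, params)
    seed_len = min(200, len(read))
    seed = read[:seed_len]
    hit = edlib.align(seed, consensus, mode="HW", task="locations")
    if hit["editDistance"] < 0 or not hit["locations"]:
        return None
    # leftmost best placement maximizes the overlap checked
    p = min(loc[0] for loc in hit["locations"] if loc[0] is not None)
    return _extension_from(consensus, read, p, params)


def _anchor_consensus(group: list[TerminalRead]) -> str | None:
    """Column-vote consensus of the genome-adjacent anchor sequences.

    R-side anchors all end at the junction, so they are reversed to share an
    origin, voted, and reversed back; L-side anchors already start at the
    junction. The result is genome-forward, like the per-read anchors.
    """
    anchors = [tr.anchor_seq for tr in group if tr.anchor_seq]
    if not anchors:
        return None
    side = group[0].side
    if side == "R":
        anchors = [a[::-1] for a in anchors]
    anchors.sort(key=lambda a: (-len(a), a))
    profile = build_profile(anchors[0], anchors, min_identity=0.7)
    seq, _ = consensus_from_profile(profile, min_depth_for_vote=1)
    return seq[::-1] if side == "R" else seq


def anchored_consensus(group: list[TerminalRead], params: AsmParams = AsmParams()) -> DraftExtension:
    """Assemble one end-group of overhangs into a draft extension.

    Phase 1: column-consensus of all overhangs anchored at the terminus,
    trimmed to the last column with depth >= ``min_tail_support``. Phase 2:
    greedy elongation by reads overlapping the consensus suffix at
    >= ``min_overlap_identity``, longest extension first, until no read
    qualifies. Support is then recounted by re-placing every read on the
    final sequence. Fully deterministic.
    """
    if not group:
        raise ParameterError("anchored_consensus: empty group")
    chrom, side = group[0].chrom, group[0].side
    if any(tr.chrom != chrom or tr.side != side for tr in group):
        raise ParameterError("anchored_consensus: group spans multiple ends")
    ranked = sorted(group, key=lambda tr: (-len(tr.overhang_seq), tr.read_id))
    overhangs = [tr.overhang_seq for tr in ranked]
    anchor = _anchor_consensus(group)
    if all(len(o) < params.min_overlap_bp for o in overhangs):
        return DraftExtension(
            chrom=chrom, side=side, sequence="", support=(), n_reads=len(group),
            anchor_seq=anchor, no_extension=True,
        )
    # Phase 1: anchored column consensus on the longest overhang as backbone;
    # reads that do not fit an anchored placement are held back for Phase 2
    backbone = overhangs[0]
    profile = build_profile(
        backbone, overhangs, min_identity=params.min_overlap_identity, band_bp=params.band_bp
    )
    consensus, depth = consensus_from_profile(profile, min_depth_for_vote=1)
    consensus, depth = _trim_to_support(consensus, depth, params.min_tail_support)
    # Phase 2: greedy suffix/prefix elongation, ties by read_id
    remaining = [(tr.overhang_seq, tr.read_id) for tr in ranked]
    while True:
        candidates: list[tuple[int, str, int]] = []
        for idx, (read, read_id) in enumerate(remaining):
            found = _overlap_extension(consensus, read, params)
            if found is not None:
                candidates.append((len(found[2]), read_id, idx, found[2]))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, _, idx, extension = candidates[0]
        consensus = consensus + extension
        remaining.pop(idx)
    # recount support from actual placements on the final sequence; infix
    # mode lets elongating reads support their true (interior) region
    if consensus:
        recount = build_profile(
            consensus,
            overhangs,
            mode="infix",
            min_identity=params.min_overlap_identity,
            band_bp=params.band_bp,
        )
        consensus, depth = _trim_to_support(consensus, recount.cov, params.min_tail_support)
    if not consensus:
        return DraftExtension(
            chrom=chrom, side=side, sequence="", support=(), n_reads=len(group),
            anchor_seq=anchor, no_extension=True,
        )
    return DraftExtension(
        chrom=chrom,
        side=side,
        sequence=consensus,
        support=tuple(depth),
        n_reads=len(group),
        anchor_seq=anchor,
    )
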