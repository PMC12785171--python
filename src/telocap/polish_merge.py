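"""Draft polishing, anchor-verified merging, and the integrated pipeline.

Polishing re-places the end-group reads on the current draft each round and
applies all majority-vote edits at once, so rounds are order-independent;
it stops at convergence or ``max_rounds``. Merging is refusal-based: the
read-consensus anchor must match the existing terminus at
``min_anchor_identity`` or the genome is left untouched for that end —
assembly finishing must be conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import edlib

from telocap._align import build_profile, consensus_from_profile
from telocap.end_assembly import AsmParams, DraftExtension, anchored_consensus
from telocap.errors import DataError, ParameterError
from telocap.seqio import SeqRecord, revcomp
from telocap.telomotif import TelomereMotif, classify_ends
from telocap.terminal_reads import FilterParams, TerminalRead, downsample_support, extract_terminal_reads

logger = logging.getLogger(__name__)

STATUS_MERGED = "merged"
STATUS_INSUFFICIENT = "insufficient-support"
STATUS_ANCHOR_MISMATCH = "anchor-mismatch"
STATUS_NO_EXTENSION = "no-extension"
STATUS_INTACT = "intact"


@dataclass(frozen=True)
class PolishParams:
    """Majority-vote polishing settings; convergence = a round with no edits."""

    max_rounds: int = 3
    min_depth_for_vote: int = 3

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ParameterError("max_rounds must be >= 1")


@dataclass(frozen=True)
class MergeParams:
    """Anchor verification settings for merging a draft into the genome."""

    anchor_bp: int = 500
    min_anchor_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.anchor_bp < 50:
            raise ParameterError("anchor_bp must be >= 50")


@dataclass(frozen=True)
class MergeAudit:
    """Outcome of one end's merge attempt."""

    chrom: str
    side: str
    status: str
    added_bp: int
    anchor_identity: float
    n_reads: int


def polish(
    draft: DraftExtension,
    reads: list[TerminalRead],
    params: PolishParams = PolishParams(),
) -> DraftExtension:
    """Polish a draft by iterated re-placement and column voting.

    Each round aligns every overhang to the current draft, recomputes votes
    where depth >= ``min_depth_for_vote`` (template bases are kept below
    that depth), and applies all changes simultaneously. Error-free reads
    over a correct draft are a fixed point.
    """
    if len(draft.sequence) == 0:
        return draft
    overhangs = sorted((tr.overhang_seq for tr in reads), key=lambda s: (-len(s), s))
    current = draft.sequence
    # reads that do not remotely fit an anchored placement (e.g. from a
    # widened read set) are kept out of the votes
    screen = 0.5
    for _ in range(params.max_rounds):
        profile = build_profile(current, overhangs, min_identity=screen)
        new, _ = consensus_from_profile(
            profile,
            min_depth_for_vote=params.min_depth_for_vote,
            keep_template_below_depth=True,
        )
        if new == current:
            break
        current = new
    recount = build_profile(current, overhangs, mode="infix", min_identity=screen)
    return replace(draft, sequence=current, support=tuple(recount.cov))


def _anchor_identity(genome_anchor: str, read_anchor: str) -> float:
    """Identity of the genome terminus against the reads' consensus anchor.

    The genome anchor is located as an infix of the (longer) read anchor so
    a ragged terminus does not shift the comparison frame.
    """
    if not genome_anchor or not read_anchor:
        return 0.0
    res = edlib.align(genome_anchor, read_anchor, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(genome_anchor)


def merge_extension(
    genome: list[SeqRecord],
    draft: DraftExtension,
    params: MergeParams = MergeParams(),
) -> tuple[list[SeqRecord], MergeAudit]:
    """Append (R) or prepend (L, reverse-complemented) a draft to its
    chromosome after verifying the junction anchor.

    The original chromosome sequence is preserved byte-for-byte; a failed
    anchor check refuses the merge and returns the genome unchanged.
    """
    by_id = {rec.id: rec for rec in genome}
    if draft.chrom not in by_id:
        raise DataError(f"draft for unknown chromosome {draft.chrom!r}")
    if draft.no_extension or not draft.sequence:
        audit = MergeAudit(draft.chrom, draft.side, STATUS_NO_EXTENSION, 0, 0.0, draft.n_reads)
        return genome, audit
    chrom_seq = by_id[draft.chrom].sequence
    if draft.side == "R":
        genome_anchor = chrom_seq[-params.anchor_bp :]
        read_anchor = (draft.anchor_seq or "")[-2 * params.anchor_bp :]
    else:
        genome_anchor = chrom_seq[: params.anchor_bp]
        read_anchor = (draft.anchor_seq or "")[: 2 * params.anchor_bp]
    if draft.anchor_seq is None:
        ident = 1.0  # no anchor material carried; caller opted out of the check
    else:
        ident = _anchor_identity(genome_anchor, read_anchor)
    if ident < params.min_anchor_identity:
        audit = MergeAudit(
            draft.chrom, draft.side, STATUS_ANCHOR_MISMATCH, 0, round(ident, 4), draft.n_reads
        )
        return genome, audit
    if draft.side == "R":
        new_seq = chrom_seq + draft.sequence
    else:
        new_seq = revcomp(draft.sequence) + chrom_seq
    out = [rec if rec.id != draft.chrom else SeqRecord(rec.id, new_seq) for rec in genome]
    audit = MergeAudit(
        draft.chrom, draft.side, STATUS_MERGED, len(draft.sequence), round(ident, 4), draft.n_reads
    )
    return out, audit


def run_pipeline(
    genome: list[SeqRecord],
    reads: dict[str, str] | None,
    alignments: list,
    motif: TelomereMotif,
    filter_params: FilterParams = FilterParams(),
    asm_params: AsmParams = AsmParams(),
    polish_params: PolishParams = PolishParams(),
    merge_params: MergeParams = MergeParams(),
    scan_bp: int = 10_000,
    min_run_bp: int = 200,
    max_interrupt_bp: int = 7,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[MergeAudit]]:
    """Classify, filter, assemble, polish and merge every incomplete end.

    One failing end never aborts the others; every attempted end yields a
    MergeAudit. Deterministic for fixed inputs.
    """
    chrom_lengths = {rec.id: len(rec.sequence) for rec in genome}
    for rec in alignments:
        if rec.ref_id not in chrom_lengths:
            raise DataError(f"alignment of {rec.read_id} to unknown contig {rec.ref_id!r}")
    statuses = classify_ends(
        genome, motif, scan_bp=scan_bp, min_run_bp=min_run_bp, max_interrupt_bp=max_interrupt_bp
    )
    groups = extract_terminal_reads(alignments, reads, chrom_lengths, filter_params)
    current = genome
    audits: list[MergeAudit] = []
    for st in statuses:
        if not st.needs_completion:
            continue
        group = groups.get((st.chrom, st.side), [])
        if len(group) < filter_params.min_support:
            audits.append(
                MergeAudit(st.chrom, st.side, STATUS_INSUFFICIENT, 0, 0.0, len(group))
            )
            logger.info("%s %s: %d supporting reads < min_support", st.chrom, st.side, len(group))
            continue
        group = downsample_support(group, filter_params.max_support, seed=seed)
        try:
            draft = anchored_consensus(group, asm_params)
            draft = polish(draft, group, polish_params)
            current, audit = merge_extension(current, draft, merge_params)
        except Exception:
            logger.exception("end %s %s failed; continuing", st.chrom, st.side)
            audits.append(MergeAudit(st.chrom, st.side, STATUS_NO_EXTENSION, 0, 0.0, len(group)))
            continue
        audits.append(audit)
    return current, audits
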