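"""Selection of terminus-reaching reads and extraction of their overhangs.

A read qualifies for an end when its alignment touches the chromosome
terminus (within ``end_slack``), the clipped portion on the telomere-facing
side is long enough, and mapping quality and alignment ratio (aligned read
bases / read length) clear their gates. Overhangs are stored 5'->3'
pointing away from the chromosome body, so both L- and R-side groups share
one orientation and downstream consensus never re-complements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from telocap.errors import DataError, ParameterError
from telocap.seqio import AlnRecord, revcomp

logger = logging.getLogger(__name__)

# cap on the anchor sequence carried per read; only MergeParams.anchor_bp of
# the consensus anchor is ever compared, 2 kb leaves slack for ragged ends
ANCHOR_CAP_BP = 2000


@dataclass(frozen=True)
class FilterParams:
    """Gates applied when selecting terminal reads."""

    end_slack: int = 100
    min_overhang: int = 200
    min_mapq: int = 20
    min_align_ratio: float = 0.4
    min_support: int = 3
    max_support: int | None = 60

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ParameterError("min_support must be >= 1")
        if not (0 < self.min_align_ratio <= 1):
            raise ParameterError("min_align_ratio must be in (0, 1]")
        if self.max_support is not None and self.max_support < 1:
            raise ParameterError("max_support must be >= 1 or None")


@dataclass(frozen=True)
class TerminalRead:
    """A read anchored at a chromosome terminus with its outward overhang.

    ``overhang_seq`` reads 5'->3' away from the chromosome body;
    ``anchor_seq`` is the aligned read portion adjacent to the junction, in
    genome-forward orientation (suffix-adjacent for R, prefix-adjacent for L).
    """

    read_id: str
    chrom: str
    side: str
    anchor_ref_start: int
    anchor_ref_end: int
    overhang_seq: str
    anchor_identity: float
    align_ratio: float
    mapq: int
    anchor_seq: str = ""

    def __post_init__(self) -> None:
        if len(self.overhang_seq) < 1:
            raise DataError(f"terminal read {self.read_id}: empty overhang")
        if not (0 <= self.align_ratio <= 1):
            raise DataError(f"terminal read {self.read_id}: bad align_ratio")


@dataclass
class FilterLog:
    """Per-alignment audit of every gate decision."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rec: AlnRecord, side: str, **outcome) -> None:
        self.rows.append(
            {
                "read_id": rec.read_id,
                "chrom": rec.ref_id,
                "side": side,
                "mapq": rec.mapq,
                "align_ratio": round(rec.aligned_read_bases / rec.read_length, 4),
                **outcome,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["read_id", "chrom", "side", "mapq", "align_ratio", "overhang_bp", "kept", "reason"]
        return pd.DataFrame(self.rows, columns=cols)


def _oriented_read(rec: AlnRecord, reads: dict[str, str] | None) -> str | None:
    """Full read sequence in stored (reference-forward) orientation."""
    if not rec.has_hard_clip and rec.seq is not None and len(rec.seq) == rec.read_length:
        return rec.seq
    if reads is None or rec.read_id not in reads:
        return None
    original = reads[rec.read_id]
    if len(original) != rec.read_length:
        raise DataError(
            f"read {rec.read_id}: FASTQ length {len(original)} != "
            f"alignment read length {rec.read_length}"
        )
    return original if rec.strand == "+" else revcomp(original)


def extract_terminal_reads(
    alignments: list[AlnRecord],
    reads: dict[str, str] | None,
    chrom_lengths: dict[str, int],
    params: FilterParams = FilterParams(),
    filter_log: FilterLog | None = None,
    summary: dict | None = None,
) -> dict[tuple[str, str], list[TerminalRead]]:
    """Group terminus-reaching reads by (chrom, side) and extract overhangs.

    Emits a TerminalRead when the alignment touches a terminus within
    ``end_slack``, the telomere-facing clip is >= ``min_overhang``, and the
    mapq / align-ratio gates pass. A read seen several times at one end
    keeps only its record with most aligned bases. Hard-clipped records
    whose sequence cannot be recovered are skipped and counted.
    """
    for rec in alignments:
        if rec.ref_id not in chrom_lengths:
            raise DataError(f"alignment of {rec.read_id} to unknown contig {rec.ref_id!r}")
    # best terminal record per (chrom, side, read)
    best: dict[tuple[str, str, str], AlnRecord] = {}
    skipped_no_seq = 0
    for rec in alignments:
        clen = chrom_lengths[rec.ref_id]
        for side in ("L", "R"):
            if side == "R":
                touches = rec.ref_end >= clen - params.end_slack
                clip = rec.read_length - rec.read_end
            else:
                touches = rec.ref_start <= params.end_slack
                clip = rec.read_start
            if not touches:
                continue
            reason = ""
            if clip < params.min_overhang:
                reason = "short-overhang"
            elif rec.mapq < params.min_mapq:
                reason = "low-mapq"
            elif rec.aligned_read_bases / rec.read_length < params.min_align_ratio:
                reason = "low-align-ratio"
            if filter_log is not None:
                filter_log.add(rec, side, overhang_bp=clip, kept=not reason, reason=reason or "pass")
            if reason:
                continue
            key = (rec.ref_id, side, rec.read_id)
            prev = best.get(key)
            if prev is None or rec.aligned_read_bases > prev.aligned_read_bases:
                best[key] = rec
    groups: dict[tuple[str, str], list[TerminalRead]] = {}
    for (chrom, side, read_id), rec in sorted(best.items()):
        full = _oriented_read(rec, reads)
        if full is None:
            skipped_no_seq += 1
            logger.warning("read %s: sequence unavailable (hard clip?); skipped", read_id)
            continue
        if side == "R":
            overhang = full[rec.read_end :]
            anchor = full[max(0, rec.read_end - ANCHOR_CAP_BP) : rec.read_end]
        else:
            overhang = revcomp(full[: rec.read_start])
            anchor = full[rec.read_start : rec.read_start + ANCHOR_CAP_BP]
        tr = TerminalRead(
            read_id=read_id,
            chrom=chrom,
            side=side,
            anchor_ref_start=rec.ref_start,
            anchor_ref_end=rec.ref_end,
            overhang_seq=overhang,
            anchor_identity=1.0,
            align_ratio=rec.aligned_read_bases / rec.read_length,
            mapq=rec.mapq,
            anchor_seq=anchor,
        )
        groups.setdefault((chrom, side), []).append(tr)
    if summary is not None:
        summary["skipped_no_sequence"] = summary.get("skipped_no_sequence", 0) + skipped_no_seq
    return groups


def downsample_support(
    group: list[TerminalRead], max_support: int | None, seed: int = 0
) -> list[TerminalRead]:
    """Bound a group to its ``max_support`` longest overhangs.

    Selection is deterministic — longest overhang first, ties broken by
    lexicographically smaller read_id — so ``seed`` is accepted for
    interface stability but never consulted.
    """
    if max_support is not None and max_support < 1:
        raise ParameterError("max_support must be >= 1")
    if max_support is None or len(group) <= max_support:
        return list(group)
    ranked = sorted(group, key=lambda tr: (-len(tr.overhang_seq), tr.read_id))
    return ranked[:max_support]
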