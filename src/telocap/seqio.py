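"""Sequence and alignment I/O with one internal coordinate convention.

Everything downstream of this module works with 0-based, half-open
coordinates; conversion to/from 1-based formats happens here and only here.
Read coordinates (``read_start``/``read_end``) always refer to the read in
its *stored* orientation, i.e. the orientation in which SAM records the
sequence (reference-forward), and include hard-clipped bases — so
``read_start`` equals the total left clip and ``read_length - read_end`` the
total right clip of the alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from telocap.errors import DataError, FormatError, ParameterError

logger = logging.getLogger(__name__)

# IUPAC single-letter codes; everything ambiguous collapses to N so motif
# counting treats it as a mismatch.
_IUPAC = set("ACGTNRYSWKMBDHV")
_NORMALIZE = {c: (c if c in "ACGT" else "N") for c in _IUPAC}
_NORMALIZE["U"] = "T"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase, map U->T and any non-ACGT IUPAC code to N.

    Raises FormatError on characters outside the IUPAC alphabet.
    """
    seq = raw.upper()
    out = []
    for ch in seq:
        mapped = _NORMALIZE.get(ch)
        if mapped is None:
            raise FormatError(f"illegal sequence character {ch!r}{context}")
        out.append(mapped)
    return "".join(out)


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlnRecord:
    """One read-to-reference alignment in internal coordinates.

    ``aligned_read_bases`` is the number of read bases consumed by M/=/X
    operations. ``seq`` is the stored-orientation sequence when the source
    format carried one (SAM SEQ; absent for PAF); with hard clips it is
    incomplete and the original read must be fetched by ``read_id``.
    """

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    aligned_read_bases: int
    read_length: int
    is_supplementary: bool = False
    has_hard_clip: bool = False
    seq: str | None = None
    cigar: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise FormatError(
                f"alignment of {self.read_id}: bad reference interval "
                f"[{self.ref_start}, {self.ref_end})"
            )
        if not (0 <= self.read_start < self.read_end <= self.read_length):
            raise FormatError(
                f"alignment of {self.read_id}: bad read interval "
                f"[{self.read_start}, {self.read_end}) on length {self.read_length}"
            )
        if self.aligned_read_bases > self.read_length:
            raise FormatError(
                f"alignment of {self.read_id}: aligned bases exceed read length"
            )
        if self.strand not in "+-":
            raise FormatError(f"alignment of {self.read_id}: strand {self.strand!r}")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a SAM CIGAR string into (op, length) pairs."""
    pairs = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not pairs or "".join(f"{n}{op}" for op, n in pairs) != cigar:
        raise FormatError(f"malformed CIGAR string {cigar!r}")
    return pairs


def _find_header_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [rec_id]:
                return i
    return 0


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into normalized SeqRecords, in file order.

    Sequences are uppercased, U is mapped to T and ambiguity codes other
    than ACGT to N. Malformed headers or empty sequences raise FormatError
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: not FASTA (expected '>')")
    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record {len(records) + 1}: empty header")
        if len(rec.seq) == 0:
            line = _find_header_line(path, rec.id)
            raise FormatError(f"{path}: line {line}: record {rec.id!r} has no sequence")
        seq = normalize_sequence(str(rec.seq), context=f" in record {rec.id!r} of {path}")
        records.append(SeqRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_fastq(path: str | Path) -> dict[str, str]:
    """Read FASTQ (or FASTA) reads into a {read_id: sequence} lookup.

    Qualities are parsed but discarded; the pipeline is quality-agnostic.
    Format is sniffed from the first byte ('@' FASTQ, '>' FASTA).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    lookup: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), fmt):
        lookup[rec.id] = normalize_sequence(str(rec.seq), context=f" in read {rec.id!r}")
    if not lookup:
        raise FormatError(f"{path}: no reads found")
    return lookup


def write_fasta(records: Sequence[SeqRecord], path: str | Path, line_width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips exactly through read_fasta."""
    if not records:
        raise ParameterError("write_fasta: no records to write")
    if line_width < 1:
        raise ParameterError("write_fasta: line_width must be >= 1")
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(bio)


def _sniff_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bam":
        return "bam"
    if suffix == ".paf":
        return "paf"
    return "sam"


def _from_pysam(a: pysam.AlignedSegment) -> AlnRecord | None:
    ct = a.cigartuples
    if ct is None:
        return None
    left = 0
    for op, n in ct:
        if op in (4, 5):  # S, H
            left += n
        else:
            break
    right = 0
    for op, n in reversed(ct):
        if op in (4, 5):
            right += n
        else:
            break
    aligned = sum(n for op, n in ct if op in (0, 7, 8))  # M, =, X
    read_length = a.infer_read_length()  # includes hard-clipped bases
    if read_length is None:
        return None
    seq = a.query_sequence
    return AlnRecord(
        read_id=a.query_name,
        ref_id=a.reference_name,
        ref_start=a.reference_start,
        ref_end=a.reference_end,
        read_start=left,
        read_end=read_length - right,
        strand="-" if a.is_reverse else "+",
        mapq=a.mapping_quality,
        aligned_read_bases=aligned,
        read_length=read_length,
        is_supplementary=a.is_supplementary,
        has_hard_clip=any(op == 5 for op, _ in ct),
        seq=normalize_sequence(seq) if seq else None,
        cigar=a.cigarstring,
    )


def _from_paf_line(line: str, lineno: int) -> AlnRecord | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise FormatError(f"PAF line {lineno}: fewer than 12 columns")
    qname, qlen, qstart, qend, strand = fields[0], int(fields[1]), int(fields[2]), int(fields[3]), fields[4]
    tname, tstart, tend = fields[5], int(fields[7]), int(fields[8])
    mapq = int(fields[11])
    cigar = None
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cigar = tag[5:]
        elif tag.startswith("tp:A:") and tag[5:] == "S":
            return "secondary"  # minimap2 marks secondary records tp:A:S
    if cigar is None:
        return None
    aligned = sum(n for op, n in parse_cigar(cigar) if op in "M=X")
    hard = any(op == "H" for op, _ in parse_cigar(cigar))
    # PAF read coordinates are on the original (forward) read; convert to
    # stored (reference-forward) orientation for minus-strand records.
    if strand == "-":
        read_start, read_end = qlen - qend, qlen - qstart
    else:
        read_start, read_end = qstart, qend
    return AlnRecord(
        read_id=qname,
        ref_id=tname,
        ref_start=tstart,
        ref_end=tend,
        read_start=read_start,
        read_end=read_end,
        strand=strand,
        mapq=mapq,
        aligned_read_bases=aligned,
        read_length=qlen,
        is_supplementary=False,
        has_hard_clip=hard,
        seq=None,
        cigar=cigar,
    )


def read_alignments(
    path: str | Path,
    dialect: str | None = None,
    summary: dict | None = None,
) -> list[AlnRecord]:
    """Read alignments from SAM/BAM/PAF into internal AlnRecords.

    Unmapped and secondary records are dropped; supplementary records are
    kept and flagged. Records lacking a CIGAR are skipped with a warning and
    counted in ``summary['skipped_no_cigar']`` when a summary dict is given.
    """
    path = Path(path)
    dialect = dialect or _sniff_dialect(path)
    if dialect not in ("sam", "bam", "paf"):
        raise ParameterError(f"unknown alignment dialect {dialect!r}")
    skipped = 0
    records: list[AlnRecord] = []
    if dialect in ("sam", "bam"):
        mode = "rb" if dialect == "bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for a in af:
                if a.is_unmapped:
                    # htslib demotes mapped records lacking a CIGAR to
                    # unmapped; count those as CIGAR-less skips
                    if a.reference_id >= 0:
                        skipped += 1
                        logger.warning("skipping %s: no CIGAR", a.query_name)
                    continue
                if a.is_secondary:
                    continue
                rec = _from_pysam(a)
                if rec is None:
                    skipped += 1
                    logger.warning("skipping %s: no CIGAR", a.query_name)
                    continue
                records.append(rec)
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = _from_paf_line(line, lineno)
                if rec == "secondary":
                    continue
                if rec is None:
                    skipped += 1
                    logger.warning("skipping PAF line %d: no cg tag", lineno)
                    continue
                records.append(rec)
    if summary is not None:
        summary["skipped_no_cigar"] = summary.get("skipped_no_cigar", 0) + skipped
    return records


def write_sam(
    alignments: Iterable[AlnRecord],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write AlnRecords as SAM text (used by the simulator; round-trips
    through read_alignments)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        for rec in alignments:
            if rec.cigar is None:
                raise DataError(f"cannot write SAM for {rec.read_id}: no CIGAR stored")
            a = pysam.AlignedSegment(af.header)
            a.query_name = rec.read_id
            a.reference_name = rec.ref_id
            a.reference_start = rec.ref_start
            a.mapping_quality = rec.mapq
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.is_supplementary:
                flag |= 2048
            a.flag = flag
            a.cigarstring = rec.cigar
            a.query_sequence = rec.seq
            af.write(a)
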