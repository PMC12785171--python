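"""Telomere-motif mathematics: counting, windowed density, terminal runs.

Orientation convention (G-rich strand points 5'->3' toward the telomere):
the forward-strand monomer (e.g. TTTAGGG in most plants) is expected at
right (R) chromosome ends and its reverse complement (CCCTAAA) at left (L)
ends. A motif supplied in either orientation is normalized to the G-rich
monomer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from telocap.errors import ParameterError
from telocap.seqio import SeqRecord, normalize_sequence, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TelomereMotif:
    """A canonical telomere repeat monomer plus its reverse complement.

    ``monomer`` is stored as given (after normalization to uppercase ACGT);
    ``rc_monomer`` is derived. The monomer must be primitive: not a
    repetition of a shorter string.
    """

    monomer: str

    def __post_init__(self) -> None:
        mono = normalize_sequence(self.monomer, context=" in motif")
        if not (4 <= len(mono) <= 12):
            raise ParameterError(f"motif length must be 4-12 bp, got {len(mono)}")
        if any(c not in "ACGT" for c in mono):
            raise ParameterError(f"motif must be over ACGT, got {self.monomer!r}")
        # primitivity: monomer may not be k copies of a shorter string
        n = len(mono)
        for p in range(1, n):
            if n % p == 0 and mono == mono[:p] * (n // p):
                raise ParameterError(f"motif {mono!r} is a repetition of {mono[:p]!r}")
        object.__setattr__(self, "monomer", mono)

    @property
    def rc_monomer(self) -> str:
        return revcomp(self.monomer)

    def g_rich(self) -> "TelomereMotif":
        """Normalize to the G-rich orientation (more G+T than its complement);
        ties keep the given orientation."""
        fwd, rev = self.monomer, self.rc_monomer
        score = lambda s: s.count("G") * 2 + s.count("T")
        return self if score(fwd) >= score(rev) else TelomereMotif(rev)

    def oriented(self, side: str) -> str:
        """Monomer expected on the forward strand at the given end."""
        if side == "R":
            return self.monomer
        if side == "L":
            return self.rc_monomer
        raise ParameterError(f"side must be 'L' or 'R', got {side!r}")


@dataclass(frozen=True)
class EndStatus:
    """Classification of one chromosome end."""

    chrom: str
    side: str
    telo_run_bp: int
    motif_count: int
    needs_completion: bool


@dataclass(frozen=True)
class DensityTrack:
    """Motif occurrences binned into fixed windows from the sequence start."""

    chrom: str
    window_bp: int
    counts: tuple[int, ...]


def _greedy_starts(seq: str, pattern: str) -> list[int]:
    """Start positions of non-overlapping occurrences, greedily left-to-right."""
    starts = []
    m = len(pattern)
    i = seq.find(pattern)
    while i != -1:
        starts.append(i)
        i = seq.find(pattern, i + m)
    return starts


def _patterns_for(motif: TelomereMotif, orientation: str) -> list[str]:
    if orientation == "forward":
        return [motif.monomer]
    if orientation == "reverse":
        return [motif.rc_monomer]
    if orientation == "both":
        return [motif.monomer, motif.rc_monomer]
    raise ParameterError(f"orientation must be forward/reverse/both, got {orientation!r}")


def count_motif(seq: str, motif: TelomereMotif, orientation: str = "both") -> int:
    """Count non-overlapping exact motif occurrences (greedy, left-to-right).

    For ``both``, forward and reverse-complement counts are computed
    independently and summed. N never matches.
    """
    return sum(len(_greedy_starts(seq, p)) for p in _patterns_for(motif, orientation))


def windowed_counts(
    seq: str,
    motif: TelomereMotif,
    window_bp: int = 100,
    orientation: str = "both",
    chrom: str = "",
) -> DensityTrack:
    """Bin greedy motif occurrences into windows of ``window_bp``.

    Window w covers [w*window_bp, (w+1)*window_bp); an occurrence belongs to
    the window containing its start, so window sums always equal
    ``count_motif`` over the whole sequence.
    """
    if window_bp < len(motif.monomer):
        raise ParameterError(
            f"window_bp ({window_bp}) must be >= motif length ({len(motif.monomer)})"
        )
    n_windows = max(1, -(-len(seq) // window_bp)) if seq else 0
    counts = [0] * n_windows
    for pattern in _patterns_for(motif, orientation):
        for start in _greedy_starts(seq, pattern):
            counts[start // window_bp] += 1
    return DensityTrack(chrom=chrom, window_bp=window_bp, counts=tuple(counts))


def terminal_run(seq: str, motif: TelomereMotif, side: str, max_interrupt_bp: int = 7) -> int:
    """Length of the maximal telomere-array run touching the given end.

    Scans inward using the end-appropriate orientation (forward monomer at R,
    its reverse complement at L). Consecutive motif copies may be separated
    by at most ``max_interrupt_bp`` non-motif bases, and the outermost copy
    must end within ``max_interrupt_bp`` of the terminus — otherwise 0. The
    returned run spans from the innermost to the outermost chained copy,
    including any tolerated interruptions between them.
    """
    pattern = motif.oriented(side)
    m = len(pattern)
    if side == "L":
        # mirror: measure on the reversed sequence with the reversed pattern
        return terminal_run(seq[::-1], _ReversedMotifView(pattern[::-1], m), "R", max_interrupt_bp)
    # overlapping occurrence starts (runs can phase-shift after an interrupt)
    starts = []
    i = seq.find(pattern)
    while i != -1:
        starts.append(i)
        i = seq.find(pattern, i + 1)
    if not starts:
        return 0
    last_end = starts[-1] + m
    if len(seq) - last_end > max_interrupt_bp:
        return 0
    # chain leftward while the gap between consecutive copies is tolerated
    run_start = starts[-1]
    run_end = last_end
    for s in reversed(starts[:-1]):
        gap = run_start - (s + m)
        if gap < 0:
            # overlapping candidate; only accept in-phase extensions
            if (run_start - s) % m == 0:
                run_start = s
            continue
        if gap <= max_interrupt_bp:
            run_start = s
        else:
            break
    return run_end - run_start


class _ReversedMotifView:
    """Internal shim so terminal_run's R-side scan can run on reversed input
    without constructing (and re-validating) a TelomereMotif."""

    def __init__(self, pattern: str, m: int):
        self._pattern = pattern
        self.monomer = pattern

    def oriented(self, side: str) -> str:
        return self._pattern


def classify_ends(
    genome: list[SeqRecord],
    motif: TelomereMotif,
    scan_bp: int = 10_000,
    min_run_bp: int = 200,
    max_interrupt_bp: int = 7,
    orientation: str = "both",
) -> list[EndStatus]:
    """Classify every chromosome end as telomere-bearing or needing completion.

    ``needs_completion`` is True when the terminal run is shorter than
    ``min_run_bp``; ``motif_count`` is the greedy count over the terminal
    ``scan_bp`` window (truncated, with a log note, on short chromosomes).
    """
    if scan_bp < min_run_bp:
        raise ParameterError("scan_bp must be >= min_run_bp")
    out: list[EndStatus] = []
    for rec in genome:
        seq = rec.sequence
        window = scan_bp
        if len(seq) < scan_bp:
            window = len(seq)
            logger.info("%s shorter than scan_bp; scanning %d bp", rec.id, window)
        for side in ("L", "R"):
            region = seq[:window] if side == "L" else seq[-window:]
            run = terminal_run(seq, motif, side, max_interrupt_bp)
            count = count_motif(region, motif, orientation)
            out.append(
                EndStatus(
                    chrom=rec.id,
                    side=side,
                    telo_run_bp=run,
                    motif_count=count,
                    needs_completion=run < min_run_bp,
                )
            )
    return out
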