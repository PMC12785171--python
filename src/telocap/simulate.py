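"""Synthetic scenario generator: genomes with known telomere arrays, a
truncated copy mimicking an incomplete assembly, error-bearing long reads,
and truth-driven alignments.

The generator emulates the situation the pipeline exists for: a chromosome
whose terminal telomere array was lost during assembly while the sequencing
reads still span it. Alignments are synthesized from the reads' true
origins (clipped exactly at the truncated terminus) rather than by running
an aligner, which keeps tests hermetic and the truth table exact; users can
substitute real aligner output at any time since the pipeline only consumes
SAM/BAM/PAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from telocap.errors import IntegrityError, ParameterError
from telocap.seqio import AlnRecord, SeqRecord, revcomp
from telocap.telomotif import TelomereMotif

Ops = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic scenario.

    ``chrom_len_bp`` is the total chromosome length including both telomere
    arrays. ``truncate_bp`` maps (chrom, side) to the number of terminal
    bases removed from the assembly copy. Error rates are per base; read
    lengths are normal-truncated at ``min_read_len``. ``telo_degeneracy``
    is the fraction of telomere monomers carrying one substituted base,
    mimicking the degenerate copies real arrays contain.
    """

    n_chroms: int = 2
    chrom_len_bp: int = 100_000
    telo_len_bp: int | tuple[int, int] = 2000
    truncate_bp: dict = field(default_factory=dict)
    read_len_mean: int = 8000
    read_len_sd: int = 1500
    min_read_len: int = 500
    depth: float = 20.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    telo_degeneracy: float = 0.01
    motif: str = "TTTAGGG"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0 <= r <= 0.2):
                raise ParameterError(f"{name} must be in [0, 0.2]")
        if self.depth <= 0:
            raise ParameterError("depth must be > 0")
        telo_max = self.telo_len_bp if isinstance(self.telo_len_bp, int) else self.telo_len_bp[1]
        if 2 * telo_max >= self.chrom_len_bp:
            raise ParameterError("telomeres longer than the chromosome")
        for (chrom, side), t in self.truncate_bp.items():
            if side not in ("L", "R"):
                raise ParameterError(f"truncation side {side!r}")
            # allow eating into the subtelomere, but never half the chromosome
            if t > telo_max + self.chrom_len_bp // 10:
                raise ParameterError(f"truncation {t} too deep for {chrom} {side}")


@dataclass(frozen=True)
class EndTruth:
    chrom: str
    side: str
    true_telo_len_bp: int
    truncated_bp: int
    removed_forward: str  # genome-forward removed piece ("" when untruncated)

    @property
    def removed_outward(self) -> str:
        """Removed sequence oriented outward (comparable to a DraftExtension)."""
        return self.removed_forward if self.side == "R" else revcomp(self.removed_forward)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    chrom: str
    start: int  # truth-genome coordinates, 0-based half-open
    end: int
    strand: str
    ops: Ops  # physical read vs oriented truth substring (M/I/D)


@dataclass
class TruthTable:
    """Ground truth for a scenario: per-end truncations and per-read origins."""

    ends: dict[tuple[str, str], EndTruth]
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def retained_interval(self, chrom: str) -> tuple[int, int]:
        """Truth-genome interval surviving in the truncated assembly."""
        t_l = self.ends[(chrom, "L")].truncated_bp
        t_r = self.ends[(chrom, "R")].truncated_bp
        return t_l, self.chrom_lengths[chrom] - t_r

    def spanning(self, chrom: str, side: str) -> dict[str, tuple[int, int]]:
        """Reads spanning the given truncated terminus.

        Returns {read_id: (overhang_truth_bp, anchored_truth_bp)} measured
        in truth-genome bases (equal to read bases when error-free).
        """
        lo, hi = self.retained_interval(chrom)
        out: dict[str, tuple[int, int]] = {}
        for rt in self.reads.values():
            if rt.chrom != chrom:
                continue
            if side == "R" and rt.end > hi and rt.start < hi:
                out[rt.read_id] = (rt.end - hi, hi - max(rt.start, lo))
            elif side == "L" and rt.start < lo and rt.end > lo:
                out[rt.read_id] = (lo - rt.start, min(rt.end, hi) - lo)
        return out


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _telomere_array(
    rng: np.random.Generator, monomer: str, length: int, side: str, degeneracy: float
) -> str:
    """A telomere array of exactly ``length`` bp whose terminal copy is pure;
    a partial copy (if any) sits on the body-facing side."""
    m = len(monomer)
    n_full, rem = divmod(length, m)
    copies = []
    for i in range(n_full):
        c = monomer
        if degeneracy > 0 and rng.random() < degeneracy:
            pos = int(rng.integers(0, m))
            alt = str(rng.choice([b for b in "ACGT" if b != monomer[pos]]))
            c = monomer[:pos] + alt + monomer[pos + 1 :]
        copies.append(c)
    # keep the outermost copy exact so the terminal base is inside a motif
    if copies:
        if side == "R":
            copies[-1] = monomer
        else:
            copies[0] = monomer
    arr = "".join(copies)
    if rem:
        partial = monomer[m - rem :] if side == "R" else monomer[:rem]
        arr = (partial + arr) if side == "R" else (arr + partial)
    return arr


def make_genome(config: SimConfig) -> tuple[list[SeqRecord], list[SeqRecord], TruthTable]:
    """Build the truth genome, its truncated assembly copy, and the truth table.

    Each chromosome is an rc-monomer (C-rich) array, a random body, and a
    monomer (G-rich) array; deterministic for a given config/seed.
    """
    rng = np.random.default_rng(config.seed)
    motif = TelomereMotif(config.motif).g_rich()
    truth: list[SeqRecord] = []
    truncated: list[SeqRecord] = []
    ends: dict[tuple[str, str], EndTruth] = {}
    chrom_lengths: dict[str, int] = {}
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        if isinstance(config.telo_len_bp, int):
            telo_l = telo_r = config.telo_len_bp
        else:
            lo, hi = config.telo_len_bp
            telo_l = int(rng.integers(lo, hi + 1))
            telo_r = int(rng.integers(lo, hi + 1))
        body_len = config.chrom_len_bp - telo_l - telo_r
        left = _telomere_array(rng, motif.rc_monomer, telo_l, "L", config.telo_degeneracy)
        right = _telomere_array(rng, motif.monomer, telo_r, "R", config.telo_degeneracy)
        seq = left + _random_seq(rng, body_len) + right
        truth.append(SeqRecord(chrom, seq))
        chrom_lengths[chrom] = len(seq)
        t_l = int(config.truncate_bp.get((chrom, "L"), 0))
        t_r = int(config.truncate_bp.get((chrom, "R"), 0))
        truncated.append(SeqRecord(chrom, seq[t_l : len(seq) - t_r]))
        ends[(chrom, "L")] = EndTruth(chrom, "L", telo_l, t_l, seq[:t_l])
        ends[(chrom, "R")] = EndTruth(chrom, "R", telo_r, t_r, seq[len(seq) - t_r :] if t_r else "")
    return truth, truncated, TruthTable(ends=ends, chrom_lengths=chrom_lengths)


def _apply_errors(
    rng: np.random.Generator, template: str, sub: float, ins: float, dele: float
) -> tuple[str, Ops, int, int]:
    """Apply per-base errors to a read template.

    Returns (read_seq, ops, lead_trim, tail_trim): ops map the read onto
    template[lead_trim : len(template) - tail_trim] and always start and end
    with M (edge indels are trimmed so terminal anchoring stays clean).
    """
    n = len(template)
    if sub == 0 and ins == 0 and dele == 0:
        return template, (("M", n),), 0, 0
    dels = rng.random(n) < dele
    subs = rng.random(n) < sub
    inss = rng.random(n) < ins
    out: list[str] = []
    ops: list[list] = []  # [op, len] runs

    def push(op: str, k: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1][1] += k
        else:
            ops.append([op, k])

    for i, base in enumerate(template):
        if dels[i]:
            push("D")
        else:
            if subs[i]:
                base = str(rng.choice([b for b in "ACGT" if b != base]))
            out.append(base)
            push("M")
        if inss[i]:
            out.append(str(_BASES[rng.integers(0, 4)]))
            push("I")
    lead = tail = 0
    while ops and ops[0][0] != "M":
        op, k = ops.pop(0)
        if op == "I":
            del out[:k]
        else:
            lead += k
    while ops and ops[-1][0] != "M":
        op, k = ops.pop()
        if op == "I":
            del out[len(out) - k :]
        else:
            tail += k
    return "".join(out), tuple((op, k) for op, k in ops), lead, tail


def simulate_reads(
    truth_genome: list[SeqRecord], config: SimConfig, truth: TruthTable
) -> list[SeqRecord]:
    """Draw reads uniformly over the truth genome (both strands) with the
    configured error rates; origins and error ops are recorded in ``truth``.

    Read start positions extend past both termini (reads are clipped to the
    chromosome) so terminal coverage matches the target depth.
    """
    rng = np.random.default_rng((config.seed, 1))
    reads: list[SeqRecord] = []
    for rec in truth_genome:
        L = len(rec.sequence)
        if config.read_len_mean >= L:
            raise ParameterError("read_len_mean must be < chromosome length")
        n = int(np.ceil(config.depth * (L + config.read_len_mean) / config.read_len_mean))
        k = 0
        for _ in range(n):
            length = int(
                max(config.min_read_len, rng.normal(config.read_len_mean, config.read_len_sd))
            )
            s0 = int(rng.integers(-(length - 1), L))
            strand = "+" if rng.random() < 0.5 else "-"
            cs, ce = max(0, s0), min(L, s0 + length)
            if ce - cs < config.min_read_len:
                continue
            template = rec.sequence[cs:ce]
            if strand == "-":
                template = revcomp(template)
            seq, ops, lead, tail = _apply_errors(
                rng, template, config.sub_rate, config.ins_rate, config.del_rate
            )
            if not seq:
                continue
            read_id = f"{rec.id}_r{k:05d}"
            k += 1
            # truth interval actually covered after edge-indel trimming;
            # oriented position 0 sits at truth ce-1 for minus-strand reads
            if strand == "+":
                a, b = cs + lead, ce - tail
            else:
                a, b = cs + tail, ce - lead
            truth.reads[read_id] = ReadTruth(read_id, rec.id, a, b, strand, ops)
            reads.append(SeqRecord(read_id, seq))
    return reads


def write_fastq(reads: list[SeqRecord], path) -> None:
    """FASTQ with constant placeholder qualities (the pipeline ignores them)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def make_alignments(
    reads: list[SeqRecord], truncated_genome: list[SeqRecord], truth: TruthTable
) -> list[AlnRecord]:
    """Synthesize the alignment each read would have against the truncated
    genome given its true origin.

    Reads fully inside the retained region get full-length records; reads
    spanning a truncated terminus are clipped there with the overhang as
    soft clip. CIGAR uses M for matches/mismatches and I/D for indels.
    Reads entirely beyond a terminus produce no record (they would be
    unmapped).
    """
    seqs = {r.id: r.sequence for r in reads}
    out: list[AlnRecord] = []
    for read_id in sorted(truth.reads):
        rt = truth.reads[read_id]
        if read_id not in seqs:
            continue
        lo, hi = truth.retained_interval(rt.chrom)
        if rt.end <= lo or rt.start >= hi:
            continue
        fwd_ops = rt.ops if rt.strand == "+" else tuple(reversed(rt.ops))
        # walk reference-forward ops, splitting at the retained boundaries
        left_clip = 0
        right_clip = 0
        mid: list[list] = []
        tpos = rt.start
        for op, k in fwd_ops:
            while k > 0:
                if op == "I":
                    if tpos <= lo and not mid:
                        left_clip += k
                    elif tpos >= hi:
                        right_clip += k
                    else:
                        _push(mid, "I", k)
                    k = 0
                    continue
                # ops consuming reference: M or D
                if tpos < lo:
                    step = min(k, lo - tpos)
                    if op == "M":
                        left_clip += step
                elif tpos < hi:
                    step = min(k, hi - tpos)
                    _push(mid, op, step)
                else:
                    step = k
                    if op == "M":
                        right_clip += step
                tpos += step
                k -= step
        # mid must start and end with M; trimmed edge D shifts the ref block
        lead_d = 0
        while mid and mid[0][0] != "M":
            op2, k2 = mid.pop(0)
            if op2 == "I":
                left_clip += k2
            else:
                lead_d += k2
        while mid and mid[-1][0] != "M":
            op2, k2 = mid.pop()
            if op2 == "I":
                right_clip += k2
        if not mid:
            continue
        ref_len = sum(k for op, k in mid if op in "MD")
        mid_read = sum(k for op, k in mid if op in "MI")
        ref_start = max(rt.start, lo) - lo + lead_d
        read_seq = seqs[read_id]
        read_len = len(read_seq)
        if rt.strand == "-":
            read_seq = revcomp(read_seq)
        if left_clip + mid_read + right_clip != read_len:
            raise IntegrityError(
                f"{read_id}: clip/op accounting does not match read length"
            )
        cigar = ""
        if left_clip:
            cigar += f"{left_clip}S"
        cigar += "".join(f"{k}{op}" for op, k in mid)
        if right_clip:
            cigar += f"{right_clip}S"
        out.append(
            AlnRecord(
                read_id=read_id,
                ref_id=rt.chrom,
                ref_start=ref_start,
                ref_end=ref_start + ref_len,
                read_start=left_clip,
                read_end=read_len - right_clip,
                strand=rt.strand,
                mapq=60,
                aligned_read_bases=sum(k for op, k in mid if op == "M"),
                read_length=read_len,
                seq=read_seq,
                cigar=cigar,
            )
        )
    return out


def _push(runs: list[list], op: str, k: int) -> None:
    if runs and runs[-1][0] == op:
        runs[-1][1] += k
    else:
        runs.append([op, k])


def mirror_scenario(
    truth_genome: list[SeqRecord],
    truncated_genome: list[SeqRecord],
    truth: TruthTable,
) -> tuple[list[SeqRecord], list[SeqRecord], TruthTable]:
    """Reverse-complement the scenario, swapping L and R everywhere.

    The physical reads are untouched (they are molecules, not coordinates);
    only their recorded origins flip. Running the pipeline on the mirrored
    scenario must produce the reverse-complemented extensions.
    """
    rc_truth = [SeqRecord(r.id, revcomp(r.sequence)) for r in truth_genome]
    rc_trunc = [SeqRecord(r.id, revcomp(r.sequence)) for r in truncated_genome]
    flip = {"L": "R", "R": "L"}
    ends = {}
    for (chrom, side), et in truth.ends.items():
        ends[(chrom, flip[side])] = EndTruth(
            chrom=chrom,
            side=flip[side],
            true_telo_len_bp=et.true_telo_len_bp,
            truncated_bp=et.truncated_bp,
            removed_forward=revcomp(et.removed_forward),
        )
    reads = {}
    for read_id, rt in truth.reads.items():
        L = truth.chrom_lengths[rt.chrom]
        reads[read_id] = ReadTruth(
            read_id=read_id,
            chrom=rt.chrom,
            start=L - rt.end,
            end=L - rt.start,
            strand=flip_strand(rt.strand),
            ops=rt.ops,
        )
    return rc_truth, rc_trunc, TruthTable(
        ends=ends, reads=reads, chrom_lengths=dict(truth.chrom_lengths)
    )


def flip_strand(strand: str) -> str:
    return "-" if strand == "+" else "+"


def demo_config(noisy: bool = False, seed: int = 7) -> SimConfig:
    """The package's reference validation scenario.

    Two 100-kb chromosomes with 2-kb telomere arrays at every end; the
    right telomeres are truncated by 1,500 bp (chr1, leaving a 500-bp
    remnant) and 2,000 bp (chr2, leaving a bare end), mimicking an assembly
    that lost its terminal arrays. Reads are HiFi/ONT-scale (mean 8 kb) at
    20x depth, error-free or at 2% substitution + 0.5% indel rates.
    """
    return SimConfig(
        n_chroms=2,
        chrom_len_bp=100_000,
        telo_len_bp=2000,
        truncate_bp={("chr1", "R"): 1500, ("chr2", "R"): 2000},
        read_len_mean=8000,
        read_len_sd=1500,
        depth=20.0,
        sub_rate=0.02 if noisy else 0.0,
        ins_rate=0.0025 if noisy else 0.0,
        del_rate=0.0025 if noisy else 0.0,
        seed=seed,
    )
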