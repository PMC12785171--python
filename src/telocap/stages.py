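"""File-level pipeline stages behind the CLI.

Each stage reads and writes plain files in an output directory, so the
integrated ``run`` command is literally the four stages executed in order —
chaining the subcommands by hand reproduces ``run`` byte for byte.

Stage files (TSV unless noted):
  end_status.tsv       chrom, side, telo_run_bp, motif_count, needs_completion
  terminal_reads.tsv   one row per kept terminal read, incl. overhang/anchor
  overhangs.fasta      the same overhangs for eyeballing
  filter_log.tsv       every gate decision
  drafts.tsv           per-end consensus drafts (+ status for skipped ends)
  drafts.fasta / support.tsv
  genome_extended.fasta, merge_audit.tsv
  completion_report.tsv, supplemented.bed, density.tsv
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from telocap import __version__
from telocap.end_assembly import AsmParams, DraftExtension, anchored_consensus
from telocap.errors import DataError
from telocap.polish_merge import (
    MergeAudit,
    MergeParams,
    PolishParams,
    STATUS_INSUFFICIENT,
    STATUS_NO_EXTENSION,
    merge_extension,
    polish,
)
from telocap.report import build_report, density_figure, density_table, report_frame, supplemented_bed
from telocap.seqio import SeqRecord, read_alignments, read_fasta, read_fastq, write_fasta
from telocap.telomotif import TelomereMotif, classify_ends
from telocap.terminal_reads import (
    FilterLog,
    FilterParams,
    TerminalRead,
    downsample_support,
    extract_terminal_reads,
)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default."""

    motif: str = "TTTAGGG"
    scan_bp: int = 10_000
    min_run_bp: int = 200
    max_interrupt_bp: int = 7
    window_bp: int = 100
    flank_bp: int = 30_000
    orientation: str = "both"
    filter: FilterParams = field(default_factory=FilterParams)
    asm: AsmParams = field(default_factory=AsmParams)
    polish: PolishParams = field(default_factory=PolishParams)
    merge: MergeParams = field(default_factory=MergeParams)
    threads: int = 1
    seed: int = 0


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _append_summary(outdir: Path, stage: str, items: dict) -> None:
    path = outdir / "summary.txt"
    new = not path.exists()
    with open(path, "a") as fh:
        if new:
            fh.write(f"# telocap {__version__} run summary\n")
        for k, v in items.items():
            fh.write(f"{stage}\t{k}\t{v}\n")


def filter_stage(
    genome_path: str | Path,
    aln_path: str | Path,
    reads_path: str | Path | None,
    outdir: str | Path,
    cfg: RunConfig,
) -> None:
    """Stage 1: classify ends and extract terminal reads with overhangs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_path)
    reads = read_fastq(reads_path) if reads_path else None
    summary: dict = {}
    alignments = read_alignments(aln_path, summary=summary)
    motif = TelomereMotif(cfg.motif).g_rich()
    statuses = classify_ends(
        genome, motif, cfg.scan_bp, cfg.min_run_bp, cfg.max_interrupt_bp, cfg.orientation
    )
    _write_tsv(
        pd.DataFrame([vars(s) for s in statuses]).sort_values(["chrom", "side"]),
        outdir / "end_status.tsv",
    )
    chrom_lengths = {r.id: len(r.sequence) for r in genome}
    log = FilterLog()
    groups = extract_terminal_reads(alignments, reads, chrom_lengths, cfg.filter, log, summary)
    rows = []
    fasta_records = []
    for (chrom, side) in sorted(groups):
        for tr in sorted(groups[(chrom, side)], key=lambda t: t.read_id):
            rows.append(
                {
                    "chrom": chrom,
                    "side": side,
                    "read_id": tr.read_id,
                    "anchor_ref_start": tr.anchor_ref_start,
                    "anchor_ref_end": tr.anchor_ref_end,
                    "mapq": tr.mapq,
                    "align_ratio": round(tr.align_ratio, 4),
                    "overhang_seq": tr.overhang_seq,
                    "anchor_seq": tr.anchor_seq,
                }
            )
            fasta_records.append(
                SeqRecord(f"{chrom}|{side}|{tr.read_id}|{tr.anchor_ref_end}", tr.overhang_seq)
            )
    cols = [
        "chrom", "side", "read_id", "anchor_ref_start", "anchor_ref_end",
        "mapq", "align_ratio", "overhang_seq", "anchor_seq",
    ]
    _write_tsv(pd.DataFrame(rows, columns=cols), outdir / "terminal_reads.tsv")
    if fasta_records:
        write_fasta(fasta_records, outdir / "overhangs.fasta")
    _write_tsv(log.to_frame(), outdir / "filter_log.tsv")
    summary.update(
        n_alignments=len(alignments),
        n_terminal_reads=len(rows),
        n_ends_needing_completion=sum(s.needs_completion for s in statuses),
    )
    _append_summary(outdir, "filter", summary)


def _load_groups(outdir: Path) -> dict[tuple[str, str], list[TerminalRead]]:
    df = pd.read_csv(outdir / "terminal_reads.tsv", sep="\t", dtype={"anchor_seq": str})
    groups: dict[tuple[str, str], list[TerminalRead]] = {}
    for row in df.itertuples():
        tr = TerminalRead(
            read_id=row.read_id,
            chrom=row.chrom,
            side=row.side,
            anchor_ref_start=int(row.anchor_ref_start),
            anchor_ref_end=int(row.anchor_ref_end),
            overhang_seq=row.overhang_seq,
            anchor_identity=1.0,
            align_ratio=float(row.align_ratio),
            mapq=int(row.mapq),
            anchor_seq="" if pd.isna(row.anchor_seq) else row.anchor_seq,
        )
        groups.setdefault((row.chrom, row.side), []).append(tr)
    return groups


def assemble_stage(outdir: str | Path, cfg: RunConfig) -> None:
    """Stage 2: anchored consensus per incomplete end."""
    outdir = Path(outdir)
    status = pd.read_csv(outdir / "end_status.tsv", sep="\t")
    groups = _load_groups(outdir)
    targets = [
        (row.chrom, row.side)
        for row in status.sort_values(["chrom", "side"]).itertuples()
        if row.needs_completion
    ]

    def one(end: tuple[str, str]) -> dict:
        chrom, side = end
        group = groups.get(end, [])
        if len(group) < cfg.filter.min_support:
            return {
                "chrom": chrom, "side": side, "status": STATUS_INSUFFICIENT,
                "n_reads": len(group), "sequence": "", "anchor_seq": "", "support": "",
            }
        group = downsample_support(group, cfg.filter.max_support, seed=cfg.seed)
        draft = anchored_consensus(group, cfg.asm)
        return {
            "chrom": chrom,
            "side": side,
            "status": STATUS_NO_EXTENSION if draft.no_extension else "ok",
            "n_reads": draft.n_reads,
            "sequence": draft.sequence,
            "anchor_seq": draft.anchor_seq or "",
            "support": ",".join(map(str, draft.support)),
        }

    if cfg.threads > 1 and len(targets) > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            rows = list(pool.map(one, targets))
    else:
        rows = [one(t) for t in targets]
    rows.sort(key=lambda r: (r["chrom"], r["side"]))
    cols = ["chrom", "side", "status", "n_reads", "sequence", "anchor_seq", "support"]
    _write_tsv(pd.DataFrame(rows, columns=cols), outdir / "drafts.tsv")
    drafted = [r for r in rows if r["status"] == "ok"]
    if drafted:
        write_fasta(
            [SeqRecord(f"{r['chrom']}|{r['side']}|n={r['n_reads']}", r["sequence"]) for r in drafted],
            outdir / "drafts.fasta",
        )
        support_rows = [
            {"chrom": r["chrom"], "side": r["side"], "pos": i, "depth": int(d)}
            for r in drafted
            for i, d in enumerate(r["support"].split(","))
        ]
        _write_tsv(pd.DataFrame(support_rows), outdir / "support.tsv")
    _append_summary(
        outdir, "assemble",
        {"n_targets": len(targets), "n_drafted": len(drafted)},
    )


def complete_stage(genome_path: str | Path, outdir: str | Path, cfg: RunConfig) -> None:
    """Stage 3: polish each draft with its read group and merge into the genome."""
    outdir = Path(outdir)
    genome = read_fasta(genome_path)
    drafts = pd.read_csv(outdir / "drafts.tsv", sep="\t", dtype={"sequence": str, "anchor_seq": str})
    groups = _load_groups(outdir)
    current = genome
    audits: list[MergeAudit] = []
    for row in drafts.sort_values(["chrom", "side"]).itertuples():
        if row.status == STATUS_INSUFFICIENT:
            audits.append(
                MergeAudit(row.chrom, row.side, STATUS_INSUFFICIENT, 0, 0.0, int(row.n_reads))
            )
            continue
        if row.status == STATUS_NO_EXTENSION or pd.isna(row.sequence) or not row.sequence:
            audits.append(
                MergeAudit(row.chrom, row.side, STATUS_NO_EXTENSION, 0, 0.0, int(row.n_reads))
            )
            continue
        support = (
            ()
            if pd.isna(row.support) or not str(row.support)
            else tuple(int(x) for x in str(row.support).split(","))
        )
        draft = DraftExtension(
            chrom=row.chrom,
            side=row.side,
            sequence=row.sequence,
            support=support,
            n_reads=int(row.n_reads),
            anchor_seq=None if pd.isna(row.anchor_seq) or not row.anchor_seq else row.anchor_seq,
        )
        group = downsample_support(
            groups.get((row.chrom, row.side), []), cfg.filter.max_support, seed=cfg.seed
        )
        draft = polish(draft, group, cfg.polish)
        current, audit = merge_extension(current, draft, cfg.merge)
        audits.append(audit)
    write_fasta(current, outdir / "genome_extended.fasta")
    _write_tsv(pd.DataFrame([vars(a) for a in audits]), outdir / "merge_audit.tsv")
    _append_summary(
        outdir, "complete",
        {"n_merged": sum(a.status == "merged" for a in audits),
         "total_added_bp": sum(a.added_bp for a in audits)},
    )


def report_stage(
    genome_path: str | Path,
    outdir: str | Path,
    cfg: RunConfig,
    figure: bool = False,
) -> None:
    """Stage 4: per-end before/after accounting, BED, density track."""
    outdir = Path(outdir)
    before = read_fasta(genome_path)
    after = read_fasta(outdir / "genome_extended.fasta")
    audit_df = pd.read_csv(outdir / "merge_audit.tsv", sep="\t")
    audits = [
        MergeAudit(r.chrom, r.side, r.status, int(r.added_bp), float(r.anchor_identity), int(r.n_reads))
        for r in audit_df.itertuples()
    ]
    motif = TelomereMotif(cfg.motif).g_rich()
    reports = build_report(
        before, after, audits, motif, cfg.scan_bp, cfg.max_interrupt_bp, cfg.orientation
    )
    _write_tsv(report_frame(reports), outdir / "completion_report.tsv")
    supplemented_bed(after, audits, outdir / "supplemented.bed")
    if figure:
        density_figure(
            before, after, motif, cfg.window_bp, cfg.flank_bp,
            outdir / "density.png", outdir / "density.tsv", cfg.orientation,
        )
    else:
        table = density_table(before, after, motif, cfg.window_bp, cfg.flank_bp, cfg.orientation)
        _write_tsv(table, outdir / "density.tsv")
    _append_summary(
        outdir, "report",
        {"n_merged_ends": sum(r.status == "merged" for r in reports)},
    )


def run_stage(
    genome_path: str | Path,
    aln_path: str | Path,
    reads_path: str | Path | None,
    outdir: str | Path,
    cfg: RunConfig,
    figure: bool = False,
) -> None:
    """The integrated pipeline: exactly the four stages, in order."""
    filter_stage(genome_path, aln_path, reads_path, outdir, cfg)
    assemble_stage(outdir, cfg)
    complete_stage(genome_path, outdir, cfg)
    report_stage(genome_path, outdir, cfg, figure=figure)
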