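"""Quantification and visualization of completion results.

Every figure has a TSV twin: the numbers are computed once with telomotif
and written to the TSV; the figure only draws them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from telocap.errors import IntegrityError, ParameterError
from telocap.polish_merge import MergeAudit, STATUS_INTACT
from telocap.seqio import SeqRecord
from telocap.telomotif import TelomereMotif, count_motif, terminal_run, windowed_counts


@dataclass(frozen=True)
class CompletionReport:
    """Before/after accounting for one chromosome end."""

    chrom: str
    side: str
    status: str
    added_bp: int
    motif_count_before: int
    motif_count_after: int
    telo_run_before: int
    telo_run_after: int
    n_support_reads: int

    def __post_init__(self) -> None:
        if self.status == "merged" and self.added_bp <= 0:
            raise IntegrityError(f"{self.chrom} {self.side}: merged with added_bp=0")
        if self.status != "merged" and self.added_bp != 0:
            raise IntegrityError(f"{self.chrom} {self.side}: added_bp without merge")


def build_report(
    before: list[SeqRecord],
    after: list[SeqRecord],
    audits: list[MergeAudit],
    motif: TelomereMotif,
    scan_bp: int = 10_000,
    max_interrupt_bp: int = 7,
    orientation: str = "both",
) -> list[CompletionReport]:
    """One row per chromosome end, counts measured from each genome's own
    termini over identical scan windows."""
    before_by = {r.id: r for r in before}
    after_by = {r.id: r for r in after}
    if set(before_by) != set(after_by):
        raise ParameterError("before/after genomes have different chromosome sets")
    for cid in before_by:
        if len(after_by[cid].sequence) < len(before_by[cid].sequence):
            raise IntegrityError(f"{cid}: extended genome shorter than input")
    audit_by = {(a.chrom, a.side): a for a in audits}
    rows: list[CompletionReport] = []
    for cid in sorted(before_by):
        for side in ("L", "R"):
            audit = audit_by.get((cid, side))
            status = audit.status if audit else STATUS_INTACT
            added = audit.added_bp if audit else 0
            n_reads = audit.n_reads if audit else 0
            b_seq, a_seq = before_by[cid].sequence, after_by[cid].sequence
            b_win = b_seq[:scan_bp] if side == "L" else b_seq[-scan_bp:]
            a_win = a_seq[:scan_bp] if side == "L" else a_seq[-scan_bp:]
            rows.append(
                CompletionReport(
                    chrom=cid,
                    side=side,
                    status=status,
                    added_bp=added,
                    motif_count_before=count_motif(b_win, motif, orientation),
                    motif_count_after=count_motif(a_win, motif, orientation),
                    telo_run_before=terminal_run(b_seq, motif, side, max_interrupt_bp),
                    telo_run_after=terminal_run(a_seq, motif, side, max_interrupt_bp),
                    n_support_reads=n_reads,
                )
            )
    return rows


def report_frame(reports: list[CompletionReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def supplemented_bed(
    after: list[SeqRecord], audits: list[MergeAudit], path: str | Path
) -> None:
    """BED (0-based half-open, on the extended genome) of supplemented
    intervals, one line per merged end."""
    lines = []
    lengths = {r.id: len(r.sequence) for r in after}
    for a in sorted(audits, key=lambda a: (a.chrom, a.side)):
        if a.status != "merged":
            continue
        if a.side == "R":
            start, end = lengths[a.chrom] - a.added_bp, lengths[a.chrom]
        else:
            start, end = 0, a.added_bp
        lines.append(f"{a.chrom}\t{start}\t{end}\tsupplemented_{a.side}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def density_table(
    before: list[SeqRecord],
    after: list[SeqRecord],
    motif: TelomereMotif,
    window_bp: int = 100,
    flank_bp: int = 30_000,
    orientation: str = "both",
) -> pd.DataFrame:
    """Windowed motif counts over each terminal flank, before vs after.

    Windows are indexed from the terminus inward-to-outward start for L and
    from flank start for R, in genome coordinates of each genome.
    """
    if flank_bp < window_bp:
        raise ParameterError("flank_bp must be >= window_bp")
    rows = []
    for label, genome in (("before", before), ("after", after)):
        for rec in genome:
            for side in ("L", "R"):
                if side == "L":
                    region = rec.sequence[:flank_bp]
                    offset = 0
                else:
                    offset = max(0, len(rec.sequence) - flank_bp)
                    region = rec.sequence[offset:]
                track = windowed_counts(region, motif, window_bp, orientation, chrom=rec.id)
                for w, c in enumerate(track.counts):
                    rows.append(
                        {
                            "genome": label,
                            "chrom": rec.id,
                            "side": side,
                            "window_start": offset + w * window_bp,
                            "window_end": offset + min((w + 1) * window_bp, len(region)),
                            "count": c,
                        }
                    )
    return pd.DataFrame(rows)


def density_figure(
    before: list[SeqRecord],
    after: list[SeqRecord],
    motif: TelomereMotif,
    window_bp: int = 100,
    flank_bp: int = 30_000,
    path: str | Path = "density.png",
    tsv_path: str | Path | None = None,
    orientation: str = "both",
) -> pd.DataFrame:
    """Plot per-end windowed motif density, before vs after, junction marked.

    The underlying numbers are written to ``tsv_path`` (default: alongside
    the image) so the figure is auditable; the returned frame is that TSV.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = density_table(before, after, motif, window_bp, flank_bp, orientation)
    tsv_path = tsv_path or str(Path(path).with_suffix(".tsv"))
    table.to_csv(tsv_path, sep="\t", index=False)

    before_len = {r.id: len(r.sequence) for r in before}
    chroms = sorted({r.id for r in before})
    fig, axes = plt.subplots(
        len(chroms), 2, figsize=(10, 2.2 * len(chroms)), squeeze=False, sharey=True
    )
    for i, cid in enumerate(chroms):
        for j, side in enumerate(("L", "R")):
            ax = axes[i][j]
            for label, style in (("before", "C0-"), ("after", "C1--")):
                sub = table[
                    (table.genome == label) & (table.chrom == cid) & (table.side == side)
                ]
                ax.plot(sub.window_start, sub["count"], style, label=label, lw=1)
            # junction between original terminus and supplemented sequence
            if side == "R":
                ax.axvline(before_len[cid], color="red", ls=":", lw=1)
            else:
                ax.axvline(0, color="red", ls=":", lw=1)
            ax.set_title(f"{cid} {side} end", fontsize=9)
            ax.legend(fontsize=7)
    fig.supxlabel("position (bp)")
    fig.supylabel(f"motif count / {window_bp} bp")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return table
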