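# Methods

## Problem setting

A chromosome-level assembly may terminate before the telomere: the terminal
repeat array (monomer `TTTAGGG` / reverse complement `CCCTAAA` in most
plants) is partially or wholly absent, while long reads spanning the true
terminus are present in the data and align to the assembly with soft-clipped
tails hanging past the end. `telocap` reconstructs the missing array from
those tails and splices it onto the assembly.

Orientation convention used throughout: the G-rich strand points 5'→3'
toward the telomere, so the forward strand carries the monomer at right (R)
ends and its reverse complement at left (L) ends. Overhangs are always
stored 5'→3' *outward* (away from the chromosome body); L-side material is
reverse-complemented once, at merge time. The mirror property — running the
pipeline on a reverse-complemented genome with swapped side labels yields
reverse-complemented output — is enforced by test.

All internal coordinates are 0-based half-open; conversion to and from
1-based formats happens only in the I/O layer.

## End classification

The terminal run of an end is the maximal span of monomer copies touching
it, scanning inward in the end-appropriate orientation, tolerating up to
`max_interrupt_bp` (default 7, one monomer length) of non-motif sequence
between copies and before the outermost copy. An end needs completion when
its run is shorter than `min_run_bp`. No published threshold exists for
"telomere present", so `min_run_bp` is an explicit knob: the default 200 bp
treats any substantial array as present; analyses expecting arrays of a
known length should raise it (the validation scenario uses 1,000 bp, i.e.
half its 2-kb arrays).

Motif counting is exact, non-overlapping and greedy left-to-right, which
matches copy number for non-self-overlapping telomere monomers and makes
the statistic reproducible; window tracks (default 100 bp) assign each
occurrence to the window containing its start, so window sums always equal
the whole-sequence count. Tolerance to degenerate copies lives solely in
the terminal-run interrupt allowance, not in the counting.

## Terminal-read selection

A read is kept for an end when (a) its alignment touches the terminus
within `end_slack` (100 bp, allowing ragged assembly ends), (b) the clip on
the telomere-facing side is at least `min_overhang` (200 bp), (c) mapping
quality ≥ `min_mapq` (20), and (d) its alignment ratio — aligned read bases
over read length, from the single terminal record, supplementary records
not merged — is at least `min_align_ratio` (0.4). The ratio gate removes
reads whose placement at the terminus is supported by only a small fraction
of their length, the main source of chimeric joins in repeat regions. A
read appearing several times at one end keeps only its most-aligned record.
Groups larger than `max_support` (60) are capped to the longest overhangs
(ties by read id) to bound consensus cost; groups smaller than
`min_support` (3) are reported as `insufficient-support`, never silently
dropped.

Each kept read also contributes an anchor: up to 2 kb of its aligned
sequence adjacent to the junction, used later to verify the merge.

## Anchored consensus assembly

Because every overhang begins at the terminus, the group shares a common
origin and full overlap-layout-consensus machinery is unnecessary.

*Phase 1.* The longest overhang is the backbone. Every overhang is aligned
to it end-anchored (edlib, prefix mode); reads whose placement identity
falls below `min_overlap_identity` (0.9) are held back rather than voted —
a read that does not belong at column 0 would only poison the columns.
Per-column majority votes over `{A,C,G,T,–}` (ties broken by the fixed
order `– < A < C < G < T`; `N` never wins unless alone; a winning `–`
deletes the column; insertion columns win by the same vote among junction-
spanning reads) produce the consensus, trimmed to the last column with
depth ≥ `min_tail_support` (2) so a single read can never extend the tip
alone.

*Phase 2.* Reads may elongate the consensus greedily, longest qualifying
extension first (ties by read id), until none qualifies. A read that fits
its anchored placement may only extend from column 0 — i.e. it must itself
reach past the consensus end. Only reads that cannot be anchored at all get
a free suffix/prefix overlap search (seeded by their first 200 bp, leftmost
best placement, overlap and extension both ≥ `min_overlap_bp` = 100,
overlap identity ≥ 0.9). This restriction matters: inside a pure repeat
array a phase-shifted seed match is as good as the true one, and an
unrestricted search was observed to fabricate extra monomer copies
(~50% over-extension in one simulated replicate) before the rule was
adopted.

Support is then recounted by re-placing every read on the final sequence
(infix placement, so elongating reads support their true interior region)
and the tail re-trimmed. Assembly is fully deterministic: no randomness,
all ties broken by length then read id.

`band_bp` (50) bounds every placement's edit-distance search at
`band_bp + 10%` of the query length — edlib's O(k·n) bounded search is the
banded primitive here; placements beyond the bound count as failed.

## Polishing and merging

Polishing re-places the end-group overhangs on the current draft each round
and applies all majority-vote edits at once (rounds are therefore
order-independent), recomputing only columns with depth ≥
`min_depth_for_vote` (3) and keeping the draft base below that depth. It
stops when a round changes nothing or after `max_rounds` (3). Error-free
reads over a correct draft are a fixed point. By default the polishing
reads are the same end-group that built the draft; a wider read set can be
supplied.

Merging is refusal-based. The read-consensus anchor (column-vote consensus
of the per-read anchors, built with the same kernel) is compared to the
existing terminus over `anchor_bp` (500) bases, locating the genome anchor
as an infix of the longer read anchor so a ragged terminus cannot shift the
frame. Identity below `min_anchor_identity` (0.95) refuses the merge and
leaves the chromosome untouched (`anchor-mismatch`); assembly finishing
must be conservative. On success the extension is appended (R) or
reverse-complemented and prepended (L); the original sequence survives
byte-for-byte at offset 0 (R) or at offset `added_bp` (L).

## The simulator

The generator emulates the target situation directly: each chromosome is a
C-rich array + random-composition body + G-rich array (arrays of exactly
the configured length, outermost copy always pure, 1% of monomers
carrying one substituted base to mimic natural degeneracy); a truncated
assembly copy removes configured amounts from chosen ends; reads are drawn
uniformly across both strands (start positions extend past the termini so
terminal coverage matches the nominal depth), lengths normal-truncated at
500 bp, with per-base substitution/insertion/deletion errors recorded as
op-lists. Alignments are synthesized from the recorded truth (clipped
exactly at the truncated terminus, errors reflected in the CIGAR) rather
than by running an aligner, keeping tests hermetic and the truth table
exact; real aligner output can be substituted since the pipeline consumes
ordinary SAM/BAM/PAF.

What the simulator does **not** model: platform-specific error profiles
(no homopolymer bias), heterozygosity/diploidy, subtelomeric satellite
structure, chimeric reads, or alignment ambiguity from an actual aligner.
Passing tests therefore demonstrate correctness of the algorithmic
contracts (exact recovery, orientation, preservation, refusal, determinism)
under idealized-to-moderately-noisy conditions, not performance on any
particular real dataset.

The reference validation scenario (`simulate.demo_config`): two 100-kb
chromosomes, 2-kb arrays at every end, right ends truncated by 1,500 and
2,000 bp, 20× reads of mean 8 kb — error-free, and at 2% substitution +
0.5% indel rates. Problem sizes were chosen so the whole suite and the
acceptance script each run in well under a few minutes on one CPU while
still exercising read-length-scale overhangs.

## Numerical and design choices

- Degenerate inputs: empty sequences count zero; an empty end-group is a
  precondition error; a group whose overhangs are all shorter than
  `min_overlap_bp` yields a zero-length draft flagged `no-extension`; a
  zero-length draft passes through polishing unchanged.
- `downsample_support` accepts a seed for interface stability but its
  stated selection rule is deterministic, so the seed is never consulted.
- Per-end work items are independent; the CLI can run them on a thread
  pool, and outputs are ordered by (chrom, side) regardless of scheduling,
  so thread count never changes results.
- The CLI `run` command executes the four stage functions on the same
  output directory, so chaining `filter → assemble → complete → report` by
  hand reproduces `run` byte-for-byte by construction.
- Supplying the motif as `TTTAGGG` or `CCCTAAA` is equivalent: it is
  normalized to the G-rich orientation.

## Known limitations

- Exact recovery requires reads that span the entire missing array;
  telomeres longer than the read length can only be partially restored
  (the draft stops at the supported tip).
- The anchor check verifies the junction, not the far tip of the
  extension; tip accuracy rests on consensus depth (reported per-base in
  `support.tsv`).
- Internal assembly gaps are out of scope; only terminal extension is
  performed.
- PAF input must carry `cg` CIGAR tags; records without them are counted
  and skipped.
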