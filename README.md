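# telocap

Telomere completion for telomere-to-telomere (T2T) genome assemblies.

Telomeres — tandem arrays of a short monomer, typically `TTTAGGG` on the
G-rich strand in plants — cap every chromosome, but because they sit at the
very ends of highly repetitive sequence they are routinely lost during
whole-genome assembly. The reads that cover them usually survive, though:
long reads (HiFi/ONT) whose alignments reach a chromosome terminus and whose
soft-clipped tails project beyond it carry exactly the missing sequence.

`telocap` turns those tails into finished telomeres. Given an assembly, the
long reads, and their alignments (SAM/BAM/PAF), it:

1. **filter** — classifies every chromosome end by its terminal telomere
   run; selects reads whose alignments touch an incomplete terminus, gating
   on mapping quality, alignment ratio (aligned read bases / read length)
   and overhang length, and extracts each read's outward-pointing overhang;
2. **assemble** — builds a consensus extension per end by *anchored
   consensus*: all overhangs share a common origin (the terminus), so they
   are stacked at column 0, majority-voted per column over `{A,C,G,T,–}`,
   and greedily elongated by reads overlapping the consensus suffix at high
   identity — no all-vs-all overlap discovery is needed;
3. **complete** — polishes each draft by iterated re-placement and column
   voting, verifies the read-consensus anchor against the existing terminus
   (identity ≥ 0.95 or the merge is refused), and appends (right ends) or
   prepends the reverse complement (left ends), preserving the original
   assembly byte-for-byte;
4. **report** — per-end added length, telomere run and motif counts before
   vs after, a BED of supplemented intervals, and windowed (100-bp) motif
   density tracks with the junction marked; every figure has a TSV twin.

A bundled simulator generates complete synthetic scenarios — genome with
known telomere arrays, a truncated assembly copy, error-bearing reads, and a
truth table — so the whole pipeline is testable without any external data.

## Worked example

Simulate an assembly that lost 1.5 kb and 2 kb of telomere from the right
ends of two 100-kb chromosomes, then complete it:

```bash
telocap simulate --out sim --truncate chr1:R:1500 --truncate chr2:R:2000 \
    --depth 20 --seed 7
telocap run --genome sim/genome.fasta --aln sim/alignments.sam \
    --reads sim/reads.fastq --out run --min-run-bp 1000 --seed 7
cat run/completion_report.tsv
```

```
chrom	side	status	added_bp	motif_count_before	motif_count_after	telo_run_before	telo_run_after	n_support_reads
chr1	L	intact	0	284	284	1995	1995	0
chr1	R	merged	1500	71	286	490	1995	23
chr2	L	intact	0	280	280	1995	1995	0
chr2	R	merged	2000	1	285	0	1995	17
```

Reading the merged rows: chr1's right end had only a 490-bp telomere
remnant (71 motif copies in the terminal 10 kb); 23 terminal reads supported
a 1,500-bp extension, restoring the full 1,995-bp run. chr2's right end had
no telomere at all (`telo_run_before` 0); 17 reads rebuilt all 2,000 bp
(285 motif copies). `intact` ends are untouched and their counts are
unchanged — the original chromosome sequence is always preserved exactly.

The same four stages can be run separately (`telocap filter`, `assemble`,
`complete`, `report`); chaining them reproduces `run` byte-for-byte.

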