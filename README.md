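# bcrseq

Longitudinal B-cell receptor (BCR) repertoire sequencing analysis — from
raw paired-end targeted amplicon reads to subset-level repertoire
statistics, with a fully ground-truthed V(D)J read simulator that makes
every stage of the pipeline verifiable.

## Who this is for

Groups analyzing targeted immune-repertoire sequencing of sorted B-cell
subsets (immature, naive, memory, plasmacyte) followed over time — e.g.
through natural infection — and anyone who needs a transparent,
reimplementable version of the classic amplicon BCR pipeline: demultiplex
by sample barcode, quality-trim, merge read pairs, assign germline
segments, extract CDR3s, filter clonotypes, and compute diversity,
overlap, gene-usage and isotype statistics.

## The method

**Rearrangement model.** A heavy-chain transcript is V′·N1·D′·N2·J′·C′
(light chains V′·N1·J′·C′): germline segments with exonucleolytic trimming
and non-templated N insertions. The CDR3 is the span strictly between the
conserved 2nd-CYS codon of V and the J-TRP/J-PHE codon of J (anchors
excluded), translated in the V frame; a clonotype is keyed by
(sample, CDR3-aa, V gene, J gene, isotype).

**Pipeline.** Reads are demultiplexed on the 6-nt barcode at the 5′ end of
the constant-region read; trimmed with a 2-base sliding window at Q20;
merged through their best ungapped overlap with *zero tolerance* — any
mismatch in the overlap discards the pair, which acts as a consensus
filter. Merged reads are mapped by affine-gap Smith–Waterman (match +2,
mismatch −3, gap −5/−2) to germline V, D, J and C references; the germline
anchor coordinates are migrated through the alignment onto the read to cut
the CDR3. Non-functional CDR3s (out of frame or containing a stop) and
clonotypes seen fewer than 4 times per library are removed, and samples
below 5 reads per sorted cell are flagged for exclusion.

**Analytics.** Unique-CDR3 set algebra across subsets (Venn regions,
percent common to all), time-point occurrence histograms, CDR3 length and
amino-acid usage, V/J usage stratified by health status (infected =
self-reported illness with hs-CRP > 1.0 mg/L), CDR3↔VJ multiplicity maps,
isotype distributions with the early class-switched fraction, and the D50
clonality index: with clonotypes ranked by read count, D50 = 100·k/N where
k is the least number of clonotypes holding ≥ 50% of reads. Statistical
comparisons use Kolmogorov–Smirnov, χ², Wilcoxon signed-rank and
Kruskal–Wallis tests with Benjamini–Hochberg correction at 0.05.

**Simulator.** `bcrseq.simulate` draws subset-structured clonal
repertoires (Dirichlet-multinomial clone sizes — clonal in memory and
plasmacytes, flat in immature/naive), geometric junction trimming/insertion,
subset-conditional isotypes including a small switched fraction in early
subsets (no IgE), clone persistence across time points, somatic
hypermutation in antigen-experienced subsets, and 2 × 250 bp paired reads
with per-base qualities, substitution errors and barcode prefixes. Every
read is linked to its generating rearrangement in a truth table.

## Worked example

```bash
python examples/01_simulate_repertoire.py   # write a ground-truthed run
python examples/02_process_and_annotate.py  # full pipeline + truth check
python examples/03_diversity_and_overlap.py # D50, Venn overlap, occurrence
```

The second script prints, for a 4-time-point, 4-subset run with ~20,000
read pairs at a 0.1% per-base error rate:

```
unassigned pairs: 127
annotation outcomes: {'annotated': 14199}
clonotypes after functional + >=4-count filters: 931
V gene call accuracy: 1.0000
J gene call accuracy: 1.0000
```

Every annotated read's V and J call matches the rearrangement that
generated it; the gap between emitted and annotated pairs is the strict
merge discarding pairs whose overlap contains a sequencing error. The
third script then shows memory/plasmacyte D50 well below immature/naive
(clonal vs flat repertoires) and near-zero CDR3 sharing between subsets.

A thin CLI wraps the same stages:

```bash
bcrseq simulate --out run/ --seed 1
bcrseq process-reads --r1 run/reads_R1.fastq.gz --r2 run/reads_R2.fastq.gz \
    --manifest run/manifest.json --germline run/germline.fasta \
    --anchors run/anchors.tsv --out run/clonotypes.tsv
bcrseq analyze --table run/clonotypes.tsv --analysis d50
```

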