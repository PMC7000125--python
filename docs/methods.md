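# Methods

## Scope and model

`bcrseq` analyzes targeted BCR amplicon sequencing of sorted B-cell
subsets followed longitudinally in one subject. The unit of analysis is
the clonotype — (sample, CDR3 amino-acid sequence, V gene, J gene,
isotype) — where the CDR3 is the nucleotide span strictly between the
conserved V 2nd-CYS codon and the J-TRP/J-PHE codon, both excluded, so an
11-residue heavy CDR3 reads `ARSIVGATFDY` rather than `CARSIVGATFDYW`.
Productivity is defined as: CDR3 length divisible by 3 and no stop codon
in the anchor-to-anchor translation.

All coordinates are 0-based half-open. Germline anchor positions refer to
the ungapped sequence (IMGT gap characters are stripped on load), and the
germline file checksum is recorded in simulation manifests so outputs are
traceable to a reference version without asserting one.

## Read processing

**Order.** Demultiplexing precedes trimming (the barcode bases must still
be present); trimming precedes merging.

**Demultiplexing** assigns a pair to the unique sample whose 6-nt barcode
is within `max_mismatch` (default 0) of the first six bases of the
constant-side read; the map is rejected up front unless pairwise barcode
Hamming distance exceeds `2·max_mismatch`.

**Quality trimming** scans 2-base windows 5′→3′ in steps of 1 and, at the
first window containing a quality below 20, truncates the read at the
first such base. This is idempotent, and with window ≥ 1 it is equivalent
to cutting at the first sub-threshold base; the window formulation is kept
because it is the field's conventional statement of the rule.

**Merging** reverse-complements R2 and scores every ungapped relative
placement at +1/−1 with free end gaps. The best placement with at least
`min_overlap` (default 10) overlapping bases is examined: if its score is
below `min_overlap` the pair is discarded as having no credible overlap;
if it contains any mismatch the pair is discarded outright. This strict
rule means a merged read is, within its overlap, a two-read consensus —
the main defense against sequencing error downstream. Overlap qualities
take the per-base maximum of the two mates. The output length law
`len(merged) = len(R1) + len(R2) − overlap` is asserted on every merge.

Because an error position also receives a low simulated quality (below),
the Q20 trim usually removes errors before the merge sees them; the two
mechanisms overlap deliberately, as they do in the real chemistry.

## Alignment and annotation

Segment assignment uses an affine-gap Smith–Waterman implemented as a
numba kernel: match +2, mismatch −3, a gap of length L costs −5 − 2L.
Defaults `min_score_v = 50`, `min_score_j = 20` separate correct from
incorrect toy-germline segments with a wide margin (an exact 25-nt match
already scores 50). Score ties are broken toward the smallest read start,
then reference start, then end coordinates, making results deterministic.
Candidate segments are ranked with a score-only rolling-row kernel; the
full traceback is computed once for the winning V and J. A brute-force DP
oracle (independent implementation in the tests) checks exact score
equality on random instances.

The chain is decided by the best V hit across all chains; a best J from a
different chain marks the read chimeric. D segments are searched only in
the window between the V and J alignments and are reported opportunistically
(score ≥ 12); no analytics depend on them. The constant segment is aligned
3′ of J; an isotype subclass (e.g. IgG1 vs IgG3) is reported only when the
best C alignment beats the runner-up by ≥ 8 score points, otherwise the
call falls back to class level (IgG) — short captured C fragments cannot
support subclass claims.

**Boundary migration.** The germline anchor positions are projected onto
the read through the alignment's aligned-pair list. When the boundary base
itself falls in a gap column (which happens when junction bases happen to
resemble the trimmed germline tail), the coordinate is lifted through the
nearest aligned pair on the anchor's side assuming local colinearity.
Anchor codons not covered by their alignment reject the read
(`anchor_uncovered`); a projected V anchor landing 3′ of the projected J
anchor rejects it as a boundary conflict. Annotation is a pure function of
the merged sequence, so identical reads are aligned once and relabelled.

## Filtering

Clonotype counts are read counts (this chemistry has no UMIs). Two filters
follow standard practice for these libraries: non-functional CDR3s are
removed, and clonotypes with fewer than 4 reads are treated as noise. The
count rule is applied per sample (each library is an independent
sequencing unit); applying it across pooled samples is available via the
aggregation key. Depth QC flags samples below 5 reads per sorted cell;
depth-sensitive analyses (gene usage by health status) exclude flagged
samples.

## Analytics conventions

* Unique-CDR3 analyses operate on amino-acid sequences, counted once per
  grouping unit regardless of abundance; nucleotide-level clonotyping is
  available through the aggregation `by_nt` flag.
* Subset overlap reports all 15 exclusive Venn regions; the
  "percent common to all" uses the union of the four subset sets as the
  denominator, and raw region counts are emitted so any other convention
  can be recomputed.
* D50 ranks clonotypes by descending read count with ties broken by CDR3
  lexicographic order (for determinism) and reports 100·k/N. It is exactly
  50% for any even-sized uniform abundance vector and decreases with
  clonality.
* Isotype distributions are clonotype-weighted by default (read-weighted
  available); the switched fraction is the non-IgM/IgD mass, with
  class-level calls counting toward their class. Class-switched CDR3
  overlap between subsets is restricted to IgA/IgG/IgE rows, since
  IgM/IgD co-expression on naive cells would trivially inflate sharing.
* Health labels: a time point is infected iff self-reported illness
  coincides with hs-CRP strictly above 1.0 mg/L; missing hs-CRP yields an
  unknown label excluded from health-stratified tests.

## Statistics

scipy provides the test machinery behind a thin result-typed surface:
two-sample Kolmogorov–Smirnov, Pearson χ² without continuity correction,
Wilcoxon signed-rank (exact for n ≤ 25 without ties, normal approximation
otherwise; zero differences dropped), Kruskal–Wallis with tie correction,
and Benjamini–Hochberg step-up adjustment. P-values are two-sided;
corrected p < 0.05 (strict) is significant. Health-stratified gene-usage
screens treat time points as replicates: each gene's per-time-point usage
fractions are compared across health strata and BH-adjusted across genes.

The null-calibration property tests use designs chosen for approximation
quality: KS at n = 1000 per side (asymptotic; the exact two-sample KS is
conservative at n ≤ 100 because of its discrete statistic), signed-rank at
n = 60 (normal approximation), Kruskal–Wallis with 4 groups of 25, and χ²
on 2×5 tables with row sums of 200 (expected counts of 40).

## Simulator: what it emulates, and what it does not

Defaults describe a desk-scale version of a single-subject longitudinal
design: 4 time points; subset pools of 300/400/250/60 cells
(immature/naive/memory/plasmacyte — plasmacytes deliberately scarce, which
is why VJ-multiplicity analyses exclude them); clone pools of
500/700/250/50; sequencing at 5 reads per cell; 2 × 250 bp reads.

* **Clone sizes** are Dirichlet-multinomial with per-subset concentration:
  50 (flat) for immature/naive, 1.0 for memory, 0.3 for plasmacytes
  (clonal). In the concentration → ∞ limit clone sizes are uniform and
  D50 → 50%.
* **Junctions**: trim and N-insert lengths are geometric with mean 3 nt —
  the simplest heavy-tailed discrete model; no published junctional model
  is asserted. Light chains have no D and a single N region. 80% of clones
  are resampled toward productivity, mimicking selection on expressed
  transcripts while leaving a non-functional minority for the filter to
  remove.
* **Isotypes**: memory/plasmacyte draw from a full vector (default ~25%
  unswitched, the rest split over switched classes, no IgE); immature and
  naive cells are IgM/IgD except for a 2% class-switched fraction
  (`switch_rate_early`, a free parameter, not a biological claim), never
  IgE.
* **Dynamics**: clones enter at a uniform random time point and persist to
  the next with probability 0.2, so most clones appear once.
* **SHM** is uniform substitution at rate 0.002 in antigen-experienced
  subsets, sparing the two anchor codons so truth CDR3 boundaries stay
  valid; it is applied per clone occurrence (per subset × time point), not
  per cell copy, so the truth table's read → CDR3 mapping stays exact.
* **Reads**: per clone occurrence, Poisson(reads_per_cell × abundance)
  pairs; substitution errors at 0.001 per base with quality dropped from
  Phred 37 to 12 at error positions; an optional 3′ quality ramp exercises
  the trimmer. R2 = barcode + reverse complement of the amplicon.

Not modelled: PCR chimeras and amplification bias, indel sequencing
errors, per-cycle quality structure, SHM hotspots and clonal lineages,
allele-level germline variation. Passing ground-truth tests therefore
demonstrates the pipeline's correctness under substitution-type noise and
skewed clonal structure, not robustness to chimeric or indel artefacts.

A note on the 0.5%-error regime: because simulated errors carry Phred 12,
the Q20 trim truncates a read at its first error, and the strict merge
discards pairs with errors in the overlap. High error rates therefore cost
depth rather than accuracy — the pipeline's guarantee under noise is
precision (clonotypes called with ≥ 4 reads are almost always true
sequences, since an error variant would need four identical copies), and
that is what the tests assert.

## Problem sizes

Test and acceptance runs are sized for a single CPU: the read-level
ground-truth study uses 3 subsets × 4 time points with 2,000 clones
(~10,000 read pairs); analytics-level studies run on clone tables directly
(`events_to_table`) at 7,500–10,000 clones, which is cheap because no
alignment is involved; the null-calibration property uses 10,000
replicates per test.

## Known limitations

* The toy germline generator produces random, maximally separable
  segments; real IMGT alleles are far more similar, so real-data V-call
  ambiguity (and the margin-based fallbacks) will matter more than the
  toy fixtures suggest. Real IMGT downloads are supported but never
  required.
* The merge contract (discard on any overlap mismatch) is faithful to the
  strict-consensus design but sacrifices depth at high error rates; no
  quality-aware reconciliation is attempted.
* D segment calls are opportunistic short-sequence local alignments and
  should not be treated as confident assignments.
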