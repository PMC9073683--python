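# Methods

## Promoter extraction

Promoters are the `upstream_len` (default 1000) bp immediately 5' of a
gene's annotated start, taken from gene-level annotation (no transcript or
UTR model: the gene-feature start stands in for the TSS). For plus-strand
genes this is reference positions `[start − 1000, start − 1]`, truncated
at the contig edge; for minus-strand genes, positions
`[end + 1, end + 1000]`, reverse-complemented so every promoter reads
5'→3' relative to its gene. That orientation convention is load-bearing:
without it, the distinction between the `AAAG(N)ACGT` and `ACGT(N)AAAG`
orientations would be meaningless for half the genes. A raw-strand mode
(`orient_to_gene=False`) preserves the uncomplemented plus-strand window
for sensitivity analysis. Promoter overlap with neighboring gene bodies is
not masked. Truncated and zero-length promoters are kept and flagged, not
dropped, so the gene universe used by the likelihood statistic is the full
annotation.

Internally coordinates are converted to 0-based half-open at the point of
slicing; files are read and written in their native 1-based inclusive
(GFF3) or 0-based half-open (BED-like hit tables) conventions.

## Pair scanning

`find_motif` reports every occurrence, including mutually overlapping ones
(relevant for poly-A runs and the AAAG motif); the ambiguity code N never
matches. `scan_pairs` enumerates every ordered occurrence pair
(left at l, right at r) with spacer `r − (l + |left|)` inside the query
range: exhaustive counting is the only convention that is reproducible
from a verbal description, so no exclusion rules are applied by default. A
pair is counted even if another motif occurrence lies inside its spacer;
`exclusive=True` suppresses such nested hits for sensitivity analysis.
Scanning is single-strand — promoters are already gene-oriented, and
genome-wide scans default to the given strand — with an optional
both-strands mode.

The scanner is validated against an independent brute-force oracle (a
nested loop over the two occurrence lists) on random sequences, and
against two published worked examples: the AAAG-first example with its
24-nt spacer and the ACGT-first example with its 14-nt spacer, both
packaged verbatim in `spacerscan.examples`.

## Normalization, enrichment and statistics

"Coverage" is the total scanned bp of a region set (genome length, or
summed promoter lengths). Normalized frequency is count ÷ coverage;
enrichment at spacer N is the promoter frequency divided by the genome
frequency. Where the genome count is zero the ratio is reported as
undefined (`.` in TSV output), never as zero.

Orientation comparisons treat the 31 per-spacer counts (N = 0–30) as
paired samples: a two-tailed paired Student's t-test at 30 df, plus a
Pearson correlation restricted by default to spacers 6–11, the window in
which the two orientations share peaks and dips. Control comparisons run
the same paired t-test between the true pair's profile and each of the 12
shuffled-tetramer control profiles. Tests are two-tailed throughout and no
multiple-testing correction is applied (none is part of the protocol).
The t and Pearson routines delegate to scipy.stats but refuse degenerate
input (zero-variance differences) rather than returning infinities; the
test suite cross-checks them against direct-formula oracles to 1e-9.

## Consensus calling

For each spacer length, the per-position fractions of A/C/G/T over all
collected spacer sequences are computed, and a base is called conserved
when its fraction *strictly* exceeds its class threshold: 0.40 for A/T,
0.25 for G/C. The asymmetric thresholds reflect the ~36% G/C background
of the genome under study — a G or C at 30% of sequences is more
surprising than an A at 30%. The threshold sentence in the source
protocol is ambiguous between "25% absolute" and "25% of the GC content";
this implementation uses absolute fractions (the reading stated first
there) and exposes both thresholds as parameters so the other reading can
be tried. When several bases pass, the highest fraction wins; exact ties
(within 1e-9) are reported joined, e.g. `G/C`. Positions where nothing
passes are `N`. The caller is deterministic and order-invariant.

## Likelihood of occurrence

For condition set A, motif-bearing set B and universe U:
`L = (|A∩B|/|B|) / (|A|/|U|)`. B at spacer N is the set of genes with at
least one pair hit at N in their promoter ("at least one pair" is the
default reading of genes "containing multiple elements", since a single
left+right co-occurrence already involves two elements; `min_hits` allows
stricter readings). The overall statistic uses B = union of the per-spacer
gene sets — averaging per-spacer L values is ill-defined when some spacers
have empty B, though that mean is also available
(`mean_per_spacer_likelihood`). Conditions are flagged at L strictly
greater than 1.25. Note the universe dependence: padding the universe with
genes outside A and B inflates L proportionally, so A and B must be
defined over the same annotation.

Condition gene lists are supplied as plain two-column TSV files
(`condition_direction`, `gene_id`); no expression-atlas client is built,
because the exact experiment selections behind any given published list
are not recoverable.

## Clustering

Genes are represented by their per-spacer hit-count rows (counts by
default; a binary presence/absence option exists, as does z-scoring —
neither is applied by default since counts share a scale). Spacer columns
that are zero across all genes are dropped first. K-means (scikit-learn,
`n_init=10`, seeded) is fit for each K in a candidate range and the K
maximizing the mean silhouette is kept, smallest K on ties; the full
silhouette curve is written out so a human can override the automatic
pick — silhouette maxima on sparse spacer matrices can sit on wide
fluctuations, and reproducing a manual judgment call is not attempted.
When even the best mean silhouette is below 0.25 the result carries a
`low_silhouette` flag (single-blob / flat-curve situations). With K equal
to the number of rows every cluster is a singleton and the mean silhouette
is taken as 0 by convention.

## Synthetic data

The generator's defaults emulate the study conditions: i.i.d. nucleotides
at 36% G/C (an order-1 Markov option exists for robustness checks only),
gene models laid out with a full promoter-length margin on both sides so
every synthetic promoter is full-length, and planted
`left + spacer + right` sites written over the background *in place*, so
coordinates and coverage never shift. Accidental background pairs are
expected — a random 36%-GC 1-kb promoter carries ~0.4 AAAG(N)ACGT pairs
over N = 0–30 in expectation — so truth tables guarantee only that planted
sites are a subset of scanner output.

*Enrichment studies* (default: 1-Mb genome, 100 genes, 1-kb promoters,
all plus-strand) plant pairs at a single spacer length (N = 10) at an
overall density of 1e-3 pairs/bp, split between promoters and background
so the promoter density is exactly `factor` times the overall genome
density. Measuring at a single spacer length is deliberate: over the full
0–30 window the accidental background rate (~6e-4/bp) is comparable to
any reasonable planted density and would bias the recovered factor,
whereas at one N it is ~2% of the planted density. The recovered factor
is accurate to a few percent at these sizes.

*Condition studies* (default: 2000 genes, 1-kb promoters, 10% of genes
given one planted pair at a random spacer, |A| = 10% of the universe)
first generate and scan their own promoters to determine the realized
motif-bearing set B — planted plus accidental — and then sample A so that
`|A∩B| = round(lift · |A| · |B| / |U|)`, i.e. P(A|B) = lift · P(A). The
realized (post-rounding) lift is recorded. Feasibility requires
`lift · |B| ≤ |U|`; with ~50% of 1-kb promoters carrying an accidental
pair, the 10% planted fraction keeps |B| near 0.48·|U| and lifts up to
~2 feasible. Pipeline recovery of the lift is then exact up to rounding,
which is the point: the test isolates the consistency of the scanning →
indexing → likelihood chain rather than re-testing binomial noise.

*Clustering studies* build gene × spacer count matrices directly: each
planted group concentrates its counts (signal 5, integer noise ≤ 1) on
its own block of three spacer columns, giving between/within separation
well above 5, under which K-means recovers the partition exactly.

What the generators do **not** emulate: real promoter base composition
(CpG/TATA structure, repeats), transcript-level TSS placement, linkage
between neighboring genes, or expression measurement noise behind real
condition gene lists. Passing the synthetic recovery tests therefore
shows the pipeline's arithmetic and inference are correct under the
stated model, not that real-genome estimates are unbiased.

## Problem sizes used in tests

The default test suite and acceptance checks run on desk-scale inputs:
random sequences ≤ 5 kb for oracle equivalence (100 sequences), a 1-Mb
genome with 100 promoters for enrichment recovery, 2000-gene universes
for likelihood recovery (1000 Monte-Carlo resamples under the null), and
30–40-gene matrices for clustering. These sizes were chosen so the whole
suite completes in well under a minute while keeping Monte-Carlo error an
order of magnitude below the asserted tolerances.

## Reproducing full-genome numbers

With the TAIR10 chromosome FASTA and gene GFF3 and a set of condition
gene lists, the published quantities correspond to:

* `enrich` on all chromosomes vs extracted promoters — expected promoter/
  genome ratios roughly 1.7–2.0 (AAAG-first) and 1.5–2.0 (ACGT-first);
* `orientation_comparison` on the two promoter profiles — paired t over
  N = 0–30 near 3.7 at 30 df (critical value 2.04 at α = 0.05) and
  Pearson r over spacers 6–11 near 0.5;
* `likelihood` with jasmonic-acid down-regulated gene lists — L near 1.3
  in both orientations.

These depend on the annotation release and on atlas experiment selections
that are not recoverable, so agreement should be expected only
approximately; the package asserts none of these values in its tests.

## Known limitations

Exact-match scanning only (no PWMs or mismatch tolerance); gene-level TSS
approximation; no masking of promoter/gene-body overlap; the likelihood
statistic is a ratio of proportions without an attached significance test
(a hypergeometric test would be the natural extension); K-means assumes
roughly spherical count clusters and is sensitive to the counts-vs-binary
choice on sparse matrices.
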