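# Methods

## Coordinate model and architecture metrics

Transcripts are stored in UCSC genePred convention: 0-based, half-open
intervals, with the transcript span delimited by the first exon start and
the last exon end. GTF input (1-based, inclusive) is converted on read.
For a transcript with exons *e*₁…*e*ₙ the metrics are

- *l*<sup>tr</sup> = txEnd − txStart (genomic span, nt),
- *l*<sup>ex</sup> = Σ|*e*ᵢ|, *l*<sup>int</sup> = *l*<sup>tr</sup> − *l*<sup>ex</sup>,
- *n*<sup>ex</sup> exons, *n*<sup>int</sup> = *n*<sup>ex</sup> − 1 introns,
- average exon length *l*<sup>ex</sup>/*n*<sup>ex</sup>, average intron
  length *l*<sup>int</sup>/*n*<sup>int</sup>, and the ratio
  *l*<sup>int</sup>/*l*<sup>ex</sup>.

The average intron length of a single-exon transcript is *missing*, not
zero: it is a 0/0 quantity, and padding it with zeros would distort
per-intron distributions. Exons are not sub-partitioned into CDS and UTR;
lengths are strand-symmetric, so strand is stored but ignored.

Genes are identified by annotation symbol with no alias resolution. The
per-gene representative is the transcript with maximal *l*<sup>tr</sup>,
ties broken by input-file order (first wins) — a deterministic rule that
makes every downstream quantity reproducible from the annotation file
alone. *N*<sup>tr</sup> counts all transcripts carrying the symbol.
*L*<sup>tr</sup> > 200,000 nt flags exceptionally long genes.

## Case-vs-other comparisons

All tests are one-sided Mann–Whitney with the alternative "case values are
stochastically greater than other values". For tie-free samples with
combined size ≤ 16 the p-value is exact: the null distribution of U is
computed by the integer Gaussian-binomial recurrence
f(u; n, m) = f(u−m; n−1, m) + f(u; n, m−1), and the tail is a ratio of
integers, so it agrees bit-exactly with brute-force enumeration of all
C(n+m, n) labelings. Larger or tied samples use the normal approximation
with tie correction and continuity correction (scipy). The cutoff is
configurable per call; 16 keeps the exact branch cheap while covering every
sample size where exactness is observable in the tests.

The "other" gene group is the full annotation universe minus the
case-pathway genes — including genes in no pathway — so case and other
always partition the universe, and a gene in both a case and another
pathway counts as case only. Pathway-level comparisons run over per-pathway
arithmetic means of *L*<sup>tr</sup> or *N*<sup>tr</sup>; pathways with no
annotated member are flagged missing and excluded. Genes listed in a
pathway but absent from the annotation are tallied, not imputed.

Stratified decoupling tests address the known positive dependence between
gene length and splice-variant count: the length shift is re-tested within
fixed *N*<sup>tr</sup> categories (default 1–10) and the splice-count shift
within narrow half-open *L*<sup>tr</sup> windows (default 25-kb bins from
0). A stratum where either group has fewer than `min_group_size` genes
(default 5) is reported as skipped rather than tested — small strata would
otherwise produce noise dressed as p-values. Binned case-fraction curves
use half-open bins ([k·w, (k+1)·w), default w = 3,000 nt on the length
axis; one bin per integer on the *N*<sup>tr</sup> axis); underpopulated
bins are flagged, never silently dropped, and bin counts always conserve
the case-gene total.

The resampling check draws `n_iter` equal-sized samples of other-labelled
pathways (without replacement within a draw) and compares their mean
pathway average against the observed case mean; the empirical p uses an
add-one pseudocount, (1 + #{resample ≥ observed}) / (n_iter + 1), so it is
never zero and is uniform on its attainable grid under the null. Resampling
with the mean (not the median) matches the quantity the main comparison
tests. No multiple-testing correction is applied anywhere: the comparison
battery reports raw p-values by design.

## Top-gene selection and EASE enrichment

Two selection rules produce gene lists: metric > median + k·SD (default
k = 2, sample SD with n−1 denominator; under normality this keeps roughly
the top 2.3%) and *N*<sup>tr</sup> strictly greater than a threshold
(default 3). A zero-variance metric yields an empty selection with a
warning rather than an arbitrary cut.

Enrichment uses the EASE score: the one-tailed over-representation Fisher
exact p computed after removing one gene from the list-hit cell. With k
list hits, list size n, K background hits and universe N, the score is
P(X ≥ k−1) for X ~ Hypergeom(N−1, K−1, n−1), and exactly 1 for k ≤ 1. The
penalty makes the test conservative (never stronger than plain Fisher) and
immune to single-gene coincidences. The background universe defaults to all
annotated genes; pathways and lists are intersected with it first, and
pathways with no background overlap are excluded. Significance is raw
p < α (default 0.05), no FDR step.

## Mutation burden

Catalog records are deduplicated on (chromosome, position) — 1-based
positions, first occurrence keeps its source stream; multi-base variants
reduce to their start position. A position p is engulfed by a transcript
iff p−1 lies in its half-open span; among several engulfing transcripts the
first in annotation-file order takes the event, mirroring the tie rule used
for representative transcripts. Per-gene counts come from the
representative transcript only; events on alternates are dropped, not
re-attributed, so per-gene totals never exceed assigned totals. Genes with
zero mapped events are excluded by default (configurable), since a catalog
says nothing about positions it never sampled.

The burden fit is ordinary least squares of per-gene count on
*L*<sup>tr</sup>, reported with the Pearson correlation of the same pairs
and the slope per 1,000 nt. A constant-count input yields slope 0 and a
correlation reported as 0 (the 0/0 case). Mapping uses a
numpy-searchsorted fast path when per-chromosome spans are non-overlapping
and an interval tree otherwise; both honor the first-in-file rule, and a
test pins their agreement.

## Synthetic data generator

The generator produces the three inputs the pipeline consumes, with the
marginal structure the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 19,219 | size of a deduplicated human protein-coding gene universe |
| `ntr_mean` | 1.95 | ≈ 37.6k transcripts / 19.2k genes |
| `exon_count_mean` | 8 | typical human multi-exon gene |
| exon length | log-normal, median 150 nt (log-SD 0.75) | human exon length scale |
| intron length | log-normal, median 2,000 nt (log-SD 1.3) | heavy-tailed human intron lengths |
| `ntr_exon_coupling` | 0.25 | plants the positive L–N dependence (more transcripts → more exons → longer gene) |
| `n_pathways` / `n_case_pathways` | 186 / 15 | KEGG-scale collection with a small case subset |
| `n_case_genes` | 380 | case-pathway gene pool |
| `case_length_shift` | 1.4 | multiplicative intron shift ≈ the observed case/other mean length ratio |
| `case_ntr_shift` | 0.5 | additive splice-count shift ≈ the observed case/other mean difference |
| `mutation_rate_per_nt` | 0.0032 | length-proportional Poisson catalog rate |
| `noncoding_fraction` | 0.862 | share of records routed to the noncoding stream |
| `duplicate_record_rate` | 0.05 | injected duplicates to exercise dedup |

Per gene, *N*<sup>tr</sup> is zero-truncated geometric (case genes use a
shifted mean); the longest transcript is assembled from sampled exon and
intron lengths; alternates are exon sub-selections sharing the span, with
the full transcript written first so the representative is well defined.
Case genes' intron lengths are multiplied by `case_length_shift`
(optionally only within chosen *N*<sup>tr</sup> strata via
`case_length_shift_ntr`, which lets tests plant an effect in one stratum
and verify the stratified comparisons localize it). Genes are laid end to
end with a 10-kb gap across 22 synthetic chromosomes, so spans never
overlap. Every case gene is dealt into at least one case pathway and other
pathways draw from non-case genes only, making the planted case/other
partition exactly recoverable. Mutation counts are Poisson(rate ·
*l*<sup>tr</sup>) per longest transcript with uniform positions in the
span.

`generate_gene_summaries` is a fast path that consumes the identical random
stream as `generate_annotation` but skips materializing exon structures; a
test asserts the two agree gene by gene, and replicated power/calibration
studies use the fast path. All three generators draw from independent
seeded substreams of the config seed and are byte-reproducible.

What the generator does *not* emulate: real chromosome lengths and
inter-gene overlap, sequence content, mutational signatures or hotspots,
isoform-level exon usage (alternates exist only to make *N*<sup>tr</sup>
countable), pathway overlap between case and other sets, and gene-symbol
aliasing. Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under a clean length-
proportional, independence-respecting model — not robustness to annotation
noise or to mutation-rate covariates (replication timing, expression,
chromatin) that real catalogs carry.

## Numerical and design choices

- Exact Mann–Whitney arithmetic is integer-only; approximation and tie
  handling delegate to scipy's corrected asymptotic method.
- The EASE tail uses scipy's hypergeometric survival function on the
  decremented table; tests pin it to an exact rational-arithmetic oracle.
- Quantiles in the per-*N*<sup>tr</sup> burden summaries use linear
  interpolation (numpy default).
- OLS on noise-free collinear input reproduces slope/intercept to machine
  precision; degenerate inputs (zero length variance, fewer than 3 genes)
  are errors, not NaNs.
- Replicated studies size: power and localization use 100 seeds of the
  full-size fixture via the fast path; calibration uses 2,000 replicates at
  moderate group sizes (60 vs 240 genes; 15 vs 171 pathways); slope
  recovery uses 20 replicates of 2,000 genes. These sizes give binomial /
  sampling error comfortably inside the asserted bounds.

## Known limitations

- The case-pathway name heuristic (substring match on "cancer" etc.) is a
  convenience default; real analyses should pass an explicit case list.
- Enrichment against DAVID's own output is not expected to match exactly:
  DAVID uses its internal gene-ID universe as background, this package uses
  the annotation universe.
- Transcripts sharing an ID across chromosomes are kept as distinct records
  of the same gene symbol; no assembly/patch reconciliation is attempted.
- Deduplication by (chromosome, position) merges genuinely recurrent
  events at the same site, so very long genes lose a small fraction of
  their counts (<0.2% at default rates); this mirrors how such catalogs
  are commonly trimmed and is negligible for the fits reported here.
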