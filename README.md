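# genarch

Tools for asking whether the genes of designated ("case") pathways — e.g.
KEGG cancer pathways — are systematically longer and more alternatively
spliced than the rest of the genome, and whether somatic mutation counts
scale with gene length.

The package is aimed at computational biologists working with standard
genome annotation (UCSC genePred/refFlat or GTF), MSigDB-style GMT gene-set
collections, and somatic mutation catalogs (COSMIC-style TSV). It covers:

- **Gene architecture metrics.** Per transcript: span length *l*<sup>tr</sup>,
  summed exon/intron lengths *l*<sup>ex</sup>, *l*<sup>int</sup>
  (*l*<sup>ex</sup> + *l*<sup>int</sup> = *l*<sup>tr</sup>), exon/intron
  counts and averages. Per gene: the longest transcript (first wins ties)
  defines *L*<sup>tr</sup>; the number of annotated transcripts is the
  splice-variant count *N*<sup>tr</sup>.
- **Case-vs-other comparisons.** One-sided Mann–Whitney tests of the
  alternative "case values are stochastically greater", at the gene level
  and over per-pathway averages; exact enumeration p-values for small
  tie-free samples, tie/continuity-corrected normal approximation otherwise.
  Stratified decoupling tests (length within fixed *N*<sup>tr</sup>,
  splice count within narrow *L*<sup>tr</sup> windows), binned case-gene
  fraction curves, and a resampling check over equal-sized pathway draws.
- **EASE-score enrichment.** Top-gene lists by the median + 2·SD rule or by
  *N*<sup>tr</sup> > 3, tested for pathway over-representation with DAVID's
  conservative variant of the one-tailed Fisher exact test
  (the list-hit cell is decremented by one, so single-gene hits never score).
- **Mutation burden.** Catalog merge with (chromosome, position)
  deduplication, position-to-transcript mapping (first engulfing transcript
  in file order), per-gene counts from the longest transcript, and the OLS
  fit of mutation count on *L*<sup>tr</sup> with its Pearson correlation.
- **Synthetic data.** A seeded generator for annotation, pathway collections
  with planted case shifts, and Poisson mutation catalogs, so the whole
  pipeline runs and is validated without external downloads.

## Worked example

Generate a small synthetic fixture and run the analysis:

```sh
genarch simulate --preset toy --seed 7 --out-dir fixture/
```

```python
import genarch as ga
from genarch.pathways import read_case_list

with open("fixture/annotation.genepred") as fh:
    transcripts = ga.parse_annotation(fh)
genes = ga.summarize_genes(transcripts)

with open("fixture/pathways.gmt") as fh:
    coll = ga.parse_gmt(fh)
with open("fixture/case_pathways.txt") as fh:
    coll = ga.label_pathways(coll, read_case_list(fh))

case, other = ga.partition_genes(coll, genes)
r = ga.compare_gene_metric(case, other, "l_tr")
print(f"l_tr: case mean {r.mean_case:.0f} nt vs other {r.mean_other:.0f} nt, "
      f"one-sided p = {r.p_one_sided:.3g}")

records, rep = ga.load_and_dedup([
    ("fixture/mutations_coding.tsv", "coding"),
    ("fixture/mutations_noncoding.tsv", "noncoding"),
])
tx_counts, _ = ga.assign_to_transcripts(records, transcripts)
fit = ga.fit_burden(ga.counts_per_gene(tx_counts, genes))
print(f"burden fit: {fit.slope_per_kb:.2f} mutations per kb, "
      f"intercept {fit.intercept:.2f}, r = {fit.pearson_r:.3f} ({fit.n_genes} genes)")
```

This prints:

```
l_tr: case mean 50391 nt vs other 20368 nt, one-sided p = 0.0623
burden fit: 3.25 mutations per kb, intercept -0.75, r = 0.998 (268 genes)
```

The toy fixture plants a 1.4× intron-length shift in 40 case genes; with
only 300 genes the gene-level test is borderline (p ≈ 0.06), while the
pathway-averaged comparison on the same fixture is clearly significant
(p ≈ 0.005). The mutation catalog was generated at 0.0032 events per
nucleotide, and the fit recovers 3.25 mutations per kilobase with the
near-perfect length correlation a pure Poisson-rate model implies.

The full pipeline (metrics → pathway summaries → comparisons → stratified
tests → binned fractions → top genes → enrichment → burden) can also be
driven from a YAML config:

```sh
genarch run --config run.yaml --out-dir out/
```

which writes stage TSV/JSON outputs plus a `manifest.json` recording
versions, the seed and input checksums.

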