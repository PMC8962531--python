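# wgsval

Analytical-validation analyses for clinical whole-genome sequencing, as a
reusable Python library.

Clinical WGS programs that return hereditary-disease-risk and
pharmacogenomic results must demonstrate, before going live, that the assay
is accurate, reproducible across laboratories, and bounded in what it
promises to report. `wgsval` implements the statistics and rule systems
behind such a validation:

- **Accuracy** — genotype-aware comparison of an evaluation call set against
  a truth set. A true positive requires an exact match on
  (chrom, pos, ref, alt, genotype) after normalization (indel left-alignment
  and MNP decomposition); a right-allele/wrong-zygosity call counts as a
  false positive *and* a false negative. Agreement is summarised as
  **PPA = TP/(TP+FN)** and **NPA = TN/(TN+FP)** — the sensitivity and
  specificity analogues used when the comparator is a validated assay rather
  than ground truth — with normal-approximation per-sample intervals
  (mean ± 1.96·SD/√n) or binomial Wald/Wilson intervals on the pooled
  proportion, stratified by genomic context, variant type, zygosity and
  event length.
- **Precision** — within- and between-lab reproducibility via the Jaccard
  coefficient |A∩B|/|A∪B| over exact variant+genotype keys, plus a
  permutation test of the claim that between-lab variability is no greater
  than within-lab variability.
- **Reportable range** — rule-based interval engineering: exon padding
  (−15/+6 intronic, strand-aware), single-base additions for known P/LP and
  PGx sites, subtraction of high-GC windows (>75% across 100 bp),
  homopolymers and di-/tri-nucleotide micro-repeats, and annotation of
  regions failing a 20×-in-80%-of-samples coverage rule.
- **QC thresholds & limit of detection** — degradation of site-level read
  counts (downsampling, duplicate injection, cross-individual contamination)
  measured through a binomial genotype caller; allele-balance contamination
  estimation; and the allele-fraction band over which heterozygous calls
  stay accurate.
- **Pharmacogenomics** — rule-based star-allele diplotype calling from a
  definition table and multi-method concordance tabulation.
- **Synthetic cohorts** — every input (truth/eval call sets across labs and
  replicates with controlled FN/FP/genotype-error rates, reference fragments
  with engineered GC/homopolymer/repeat content, coverage matrices with
  planted low-coverage pockets, PGx cohorts) is generated from a single
  seed, so every estimate can be checked against the rate that produced it.

The published summary tables of a three-laboratory clinical WGS validation
ship as checksummed fixtures (`wgsval.tables`) so the headline statistics
can be recomputed offline.

## Worked example

```bash
python examples/printed_tables.py
```

```
stratum                      pooled PPA  printed  match
All compiled                     99.74%   99.74%    yes
SNVs only                        99.92%   99.92%    yes
Insertions only                  96.15%   96.20%     NO
Deletions only                   94.24%   94.24%    yes
...
PGx overall concordance across rows: 595/595 = 100%
```

Each row pools the fixture's TP/FN counts into TP/(TP+FN); all rows
reproduce the printed PPA at two decimals except insertions, whose printed
value reflects per-sample (macro) averaging rather than pooling — the
package reports both conventions and decides neither. The PGx table's
per-row correct/total counts pool to 595/595.

The other scripts in `examples/` each demonstrate one capability on a small
seeded input: `accuracy_stratified.py` (context-stratified PPA/NPA on a
synthetic cohort), `interlab_precision.py` (Jaccard + permutation test),
`reportable_range_build.py` (interval rules on a toy locus),
`qc_thresholds.py` (degradation curves, contamination estimate, LoD band),
`pgx_star_alleles.py` (diplotype calling and concordance).

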