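# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Genotype-aware matching

Variants are normalized before comparison: indels are left-aligned against
the reference and trimmed to a single anchor base (the classic parsimony
algorithm: strip shared trailing bases, extending left with reference
sequence when an allele empties, then strip shared leading bases keeping one
anchor), and multi-base substitutions decompose into per-base SNVs that
inherit the genotype. Matching is exact on (chrom, pos, ref, alt, zygosity)
within a caller-supplied comparison region. Genotypes are unphased
zygosities; hom-ref is the absence of a call.

Two decisions are configurable because the field uses both conventions:

- **Genotype mismatch.** The default counts a right-allele/wrong-zygosity
  call as one FP plus one FN (the truth genotype was missed *and* a
  different genotype was asserted). `gt_mismatch="fp_only"` reproduces the
  stricter FP-only reading.
- **True negatives.** TN has no canonical per-variant definition, so it is
  positional: region bases minus the distinct positions covered by any truth
  or evaluation footprint (an indel's footprint is its REF span). The region
  used for TN is always an explicit argument, never inferred.

Stratification is deliberately non-exclusive — each call lands in every
overlapping genomic context and every satisfied type/zygosity predicate,
with per-stratum TN recomputed over context ∩ region — matching how
stratified accuracy tables are reported. Recurrent-artifact detection flags
site keys discordant in ≥ 20% of samples by default (threshold inclusive and
configurable; no canonical value exists).

## Agreement statistics

PPA = TP/(TP+FN), NPA = TN/(TN+FP); zero denominators yield `nan` rather
than an exception so stratified tables stay rectangular. Pooled (micro)
estimates are the default; per-sample (macro) means are available because
published tables sometimes mix the two (the packaged insertions row is
macro). Intervals: normal approximation on per-sample values
(mean ± z·SD/√n, z = 1.96, requiring n ≥ 2) or binomial Wald/Wilson on the
pooled proportion (delegated to `statsmodels`; the tests check the closed
forms independently). Intervals are clamped to [0, 1] by default since the
normal interval can exceed it. Printed-style rounding is half-up at 2
decimals and lives only in presentation code, never in stored values.

## Interlab precision

Jaccard similarity is computed over exact variant+genotype keys, optionally
region-restricted; two empty call sets score 1 (replicates that both call
nothing agree). The equivalence claim — between-lab variability no greater
than within-lab — is made testable with a permutation test: statistic
mean(within-lab pairwise J) − mean(between-lab pairwise J), null built by
permuting lab labels among the (lab, replicate) units of each sample
independently, one-sided p with the add-one convention. The calibration
suite uses 3 labs × 2 replicates × 3 samples: with only 2 labs × 2
replicates the permutation orbit has just 3 distinct pairing structures per
sample and ties at the observed statistic make the test noticeably
conservative.

## Reportable range

Rules compose as pad → add sites → subtract exclusions → annotate coverage:

- Exon pads default to 15 bases transcription-upstream and 6 downstream,
  strand-aware, clamped at coordinate 0, merged after padding.
- High-GC exclusion: sliding window (step 1) of 100 bp, excluding every
  position covered by a window with GC strictly > 0.75. Both parameters are
  configurable; the rule is stated approximately in the field, so nothing is
  hard-coded.
- Homopolymer runs ≥ 10 bp and tandem 2-/3-mer repeats with ≥ 6 complete
  units are excluded; no canonical thresholds exist, so these defaults are
  reported in output metadata and configurable.
- Pseudogene-homology regions are *inputs* (`named_exclusions`), not
  detected: homology search is out of scope.
- The coverage rule (≥ 20% of samples below 20×, boundary inclusive)
  annotates rather than excludes — low coverage is a quality observation,
  not a reason to silently shrink the range.
- Exclusions take precedence over added P/LP/PGx sites, and every site lost
  this way is listed in a conflict report instead of being silently decided.

## QC simulation and limit of detection

A production-scale study degrades aligned reads; this package degrades the
sufficient statistic those reads provide to a diploid genotyper: per-site
(depth, alt-read) counts. The caller is a uniform-prior binomial argmax with
allele-fraction models (ε, ½, 1−ε), ε = 0.01 by default, ties broken toward
hom-ref (fewest reportable calls). Degradations:

- **Downsampling** at fraction f: depth′ ~ Binomial(depth, f), alt′
  hypergeometric — exactly uniform read removal without replacement. Two
  thinnings compose multiplicatively in distribution (KS-tested).
- **Duplicate injection** at rate r holding yield constant leaves unique
  depth Binomial(depth, 1−r); it is implemented as thinning at f = 1−r with
  the same seed path, so equal-f curves are identical by construction.
- **Contamination** at fraction α redraws alt counts from the mixture
  (1−α)·AF_host + α·AF_contaminant, depth preserved.

The contamination estimator uses allele balance at homozygous sites: a
contaminant heterozygous at such a site contributes non-consensus reads at
rate α/2, so α̂ = max(0, 2·(median non-consensus AF − ε)). Site selection
uses the truth genotype carried by the observations: selecting on the
*called* genotype truncates the allele-fraction distribution at the het
decision boundary (at α = 0.2, depth 40, roughly a quarter of contaminated
hom-ref sites are called het), which biases the median down by ~0.05 and
breaks the estimator's accuracy contract. With truth selection the
estimator's RMSE is ≈ 0.01–0.015 at α ∈ {0.05, 0.1, 0.2}, depth 40, 5,000
sites (small negative bias from count discreteness; the simulations draw
Poisson depths around the nominal mean, as real per-site depths vary).

Limit of detection simulates het-truth sites at each allele fraction
(alt ~ Binomial(depth, AF)) and reports het-call accuracy per level plus the
widest contiguous grid band with accuracy ≥ 0.99 (configurable; "confident
and accurate" has no canonical quantification). At 30× with ε = 0.01 the
caller's het window is 5–25 alt reads of 30, giving a band of roughly
0.35–0.65.

Threshold selection scans from the least-degraded level (axis-aware:
highest retained fraction, lowest contamination/duplicate rate) and stops at
the first failure — the conservative reading of a non-monotone curve.
Sensitivity curves are non-increasing only up to Monte-Carlo noise and a
boundary-quantization effect (thinning can carry a borderline site across
the caller's depth-scaled het boundary), which is why the property tests
allow a 10⁻³ tolerance at the plateau. The sensitivity floor used to pick a
threshold is a required user input; no default is meaningful.

## PGx star alleles

A star-allele definition table maps allele names to sets of defining variant
keys; the reference allele (*1) is the empty set. The caller is rule-based
and transparent: alleles whose full defining set is present are candidates;
all-homozygous → allele on both haplotypes; a single all-het candidate →
allele/reference; a pair of candidates whose combined zygosity pattern
(shared sites hom, symmetric-difference sites het) explains every call →
that pair, flagged ambiguous because unphased genotypes cannot exclude the
cis configuration. Nested definitions resolve to the largest fully matched
set; size ties, partial matches, leftover variants and calls at undefined
sites all set the ambiguous flag with explicit conflict messages. Ploidy is
an explicit argument (haploid genes return a single allele); sex inference
is out of scope. Round-trip recovery of generated diplotypes is exhaustive
over the toy table's allele pairs; it is guaranteed only for tables whose
defining sets are pairwise non-nested.

## Synthetic cohorts

`SyntheticCohortConfig` defaults describe a desk-scale analogue of a
multi-center validation: 3 labs × 2 replicates, ~200 kb of region (the size
order of a reportable range), variant rate 10⁻³/bp with an SNV-dominated mix
(85/7/8), 62% heterozygous, truncated-geometric indel lengths on 1..50, and
small baseline error rates. Truth variants are placed uniformly without
footprint overlap; each evaluation set independently drops truth calls
(per-stratum FN rates, max-of-applicable-strata), flips zygosity at the site
(genotype error, preserving site and alt allele), and adds false calls at a
per-base rate with the same type mix. All randomness flows through
`numpy.random.SeedSequence` spawning, so identical configs are bit-identical
and labs/replicates are independent streams.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: read-level error processes (mapping artifacts,
strand bias, systematic context-dependent miscalls), haplotype structure and
phasing, population allele-frequency spectra, structural variants, and the
correlated inter-lab error modes of real wet-lab pipelines. Recovery of an
injected rate demonstrates that the estimators are correct, not that a real
assay achieves any particular accuracy.

## Problem sizes in the checked runs

The packaged test suite and the reproduction script use: 500 random cohorts
of ≤ 50 variants for oracle equivalence; ≥ 10,000 pooled truth variants for
rate recovery; 500 null replicates × 199 permutations for test calibration;
5 kb fragments for the exclusion-scanner oracle; 5,000 homozygous sites × 8
trials per contamination level; and 2,000–3,000 sites per
degradation/LoD level. These sizes put Monte-Carlo noise well inside the
asserted tolerances while keeping a full run in tens of seconds.
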