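# Methods

This note documents the models, conventions and numerical choices behind
`regvar`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Interval layer

All coordinates are BED-convention 0-based half-open `[start, end)`.  A
regulatory track is always stored merged: overlapping **and abutting**
intervals are fused, so `total_length` is the size of the per-bp union —
the denominator of every density and percentage.  Merging is idempotent and
is re-checked against a per-bp set-arithmetic oracle in the tests.
Chromosome names are normalised to a `chr` prefix by default (configurable
off); tracks re-emit as BED3.

The seven genomic region classes are derived from gene models:

* `coding_exon` — union of CDS spans;
* `utr5` / `utr3` — exonic bp 5′/3′ of the CDS span, strand-aware;
* `intron` — transcript span minus exon union;
* `upstream` / `downstream` — strand-aware 2,000 bp flanks (`flank`
  parameter), clipped at chromosome bounds;
* `intergenic` — complement of gene spans plus flanks.

The classes are deliberately **not** mutually exclusive (a bp can be exonic
for one gene and intronic for an overlapping one); only `intergenic` is
defined by complement, and the union of all seven covers every bp.  This is
why overlap-matrix rows can sum to more than 100%.  Unstranded gene records
default to `+` with a logged warning.

## Variants

A variant is keyed by `(chrom, pos, ref, alt)`; identical positions with
different alleles are distinct variants.  Interval membership is tested on
the position alone (1-based converted to 0-based), treating every variant
as a point: indel spans would change counts in a way that depends on
normalisation conventions, so they are intentionally ignored.  Allele
frequency is the alternate-allele frequency as supplied (global or
super-population — user's choice, not folded to minor-allele frequency:
the matching procedure only needs distributional equality).  Multi-allelic
VCF records split into one variant per ALT; duplicate keys collapse with a
logged count.  The background control group is the supplied panel minus the
union of all disease keys (`subtract`), which also resolves any planted
collisions in the synthetic scenarios.

## Density

`DVPM = 1e6 * unique_count / track_length`.  The float value is canonical in
machine-readable output; the integer column rounds half away from zero and
is cosmetic.  (Published density tables mix truncation and rounding across
rows — 1,812/3.8335 Mb = 472.7 appears as 472 while 26,188/387.1 Mb = 67.7
appears as 68; standardising on rounding reproduces all rows except the
first, which differs by 1.)  Per-class cells count variants in
(track ∩ class) and may double-count a variant across overlapping classes;
the `total_unique` column deduplicates.

## 2×2 enrichment

`OR = (DMW/DMO)/(DCW/DCO)`; `SE(ln OR) = sqrt(1/DMW + 1/DMO + 1/DCW +
1/DCO)`; Pearson chi-squared on the table with 1 df and **no** Yates
correction, upper-tail p.  Zero-cell policy: the OR/ln-OR become `inf`/`0`/
`NaN` and are flagged, never silently corrected; an opt-in Haldane–Anscombe
`+0.5` flag exists for plotting.  A zero row/column margin makes the test
degenerate: statistic 0, p 1, logged warning.  The batch path used by the
resampling null evaluates the algebraically identical closed form
`N(ad−bc)² / (r₁r₂c₁c₂)`; tests pin the two routes together to 1e-9 and
against `scipy.stats.chi2_contingency(correction=False)`.  Error bars in
reports are ±1 SE on the log scale.

## Matched resampling null

Default AF bin edges `{0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5,
1.0}` (last bin closed at 1.0) plus a missing-AF stratum.  The rare-dense
edges reflect disease-set site-frequency spectra; they are configurable
because matching should be stress-tested under mismatched shapes.  Missing-AF
variants are matched as their own stratum rather than dropped, preserving
the equal-size property of control groups.  Sampling is exact-quota per bin,
without replacement within a set and independent across the N sets; a
capacity shortfall in any bin raises an error naming the bin.

Per replicate *i* the control counts come from one matched draw; the disease
margin is fixed.  Summaries: median OR over finite replicate ORs (the count
of non-finite replicates is reported), the significant fraction at `alpha`
(default 0.05), and a scalar q.  The q definition is a declared
interpretation, recorded in the output metadata: Benjamini–Hochberg over the
N replicate p-values, reporting the maximum adjusted value among replicates
with raw p < alpha (1.0 if none).  It is monotone and conservative; the raw
significant fraction is always reported alongside.

Randomness: replicate *i* draws from `numpy.random.default_rng([seed, i])`,
so any replicate reproduces in isolation and the whole result is a pure
function of (inputs, seed).

Note that the N replicate tests share one disease set and one pool
realisation, so replicate p-values are positively correlated: across
*independent studies* the significant fraction under no enrichment scatters
more than the binomial(N, alpha) width, even though within one study the
procedure is exact.

## Synthetic-data generator

The generator emulates the statistical structure the enrichment analysis
assumes — and nothing more.  Defaults define the reference scenario: an
8 Mb two-chromosome genome, 150 non-overlapping genes with random exon/CDS
structure, nine tracks at the genome fractions reported for real
promoter/enhancer/insulator/methylation/histone/chromatin-interaction/
DNA-binding/DNase/FAIRE tracks (0.12% … 87%), a 100,000-SNP uniform
background pool with Beta(0.2, 2) allele frequencies (rare-skewed, a crude
site-frequency-spectrum shape), and four disease categories at one tenth of
the curated real-set sizes, planted at the folds reported for the strongest
real matched-null enrichments (22×, 10.87×, 26.5×, 1.5×).

Planting: with track coverage `c`, a disease variant lands in-track with
probability `p = λc/(λc + 1 − c)`, uniformly within the chosen side.  The
identity `(p/(1−p))/(c/(1−c)) = λ` makes the population OR exactly λ — the
analytic oracle for all recovery tests.  Track synthesis throws exponential-
length intervals until the merged union reaches the target fraction, then
trims the last interval so the union length is exact.  All components draw
from `default_rng([seed, component_key])` (genome 0, pool 1, track i 10+i,
disease i 100+i) and are bit-reproducible.

What the generator does **not** emulate: linkage disequilibrium, mutation-
rate or gene-density heterogeneity, clustering of regulatory elements near
genes, indels, and any AF–position correlation.  Passing recovery tests
therefore demonstrate the *estimators* are correct and calibrated under the
stated sampling model; they do not show robustness to confounders (LD,
gene-density matching à la SNPsnap) that real data add.  Consequence terms
and functional scores from `annotate_consequences` are category-tilted
surrogates for upstream annotation tools, used only to exercise the
summarisation code.

## Validation scales

Oracle-equivalence tests run per-bp set arithmetic on toy genomes of at
most ~100 kb, where exhaustive enumeration is exact and fast.  Recovery
checks use one 4 Mb chromosome, a track at 1% coverage, 2,000 disease
variants, a 40,000-SNP pool and 200 replicates; at that size the median-OR
sampling band around a planted fold is roughly ±15–25% (dominated by the
binomial planting of the ~2,000·p in-track disease count, plus the shared
pool realisation), which is why recovery is asserted at ±25%.  The
reference analysis scenario (8 Mb, 100k pool, 1000 replicates) runs in
seconds on one core; whole-genome inputs scale linearly in variants and
intervals.

## Known limitations

* Point-membership semantics undercount spanning deletions.
* The q-value summary is one defensible reading of a replicate-wise q; a
  different aggregation (e.g. an empirical-null tail probability) could be
  substituted without touching the sampler.
* No genome-assembly liftover, no alternate-haplotype contigs, no
  covariate-matched (LD/gene-density/TSS-distance) control sampling.
* Exome-capture target stratification and upstream annotation (VEP, GWAVA,
  CADD, GERP, Mutation Assessor) are consumed as inputs, never computed.
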