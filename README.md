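# regvar

Where do disease-associated variants sit relative to the regulatory genome,
and is that placement more than chance?  `regvar` implements the stratified
enrichment analysis used to answer this for categories of disease variants
(Mendelian, complex, cancer-predisposing germline, recurrent cancer somatic)
against regulatory element tracks (promoters, enhancers, insulators,
methylation and histone-modification regions, chromatin-interaction regions,
protein DNA-binding sites, open chromatin): variant densities per track,
odds-ratio enrichment against a genome-variant background, and an
allele-frequency-matched resampling null.  It is aimed at regulatory
genomicists who have variant lists (VCF/TSV), region tracks (BED) and gene
models (GFF3) and want the full chain — including a synthetic-data generator
with *known* planted enrichment, so every statistic can be validated against
ground truth before being pointed at real data.

## The statistics

**Density (DVPM).**  For a merged track of total length $L$ bp containing
$n$ unique disease variants, the density is
$\mathrm{DVPM} = 10^6 \, n / L$ — disease variants per million bp.

**Background enrichment.**  The control group is the full SNP panel minus
every disease-associated variant.  Counting disease/control variants within
and outside a track gives the 2×2 table (DMW, DMO, DCW, DCO) and

$$\mathrm{OR} = \frac{DMW/DMO}{DCW/DCO}, \qquad
\mathrm{SE}_{\ln \mathrm{OR}} = \sqrt{\tfrac1{DMW}+\tfrac1{DMO}+\tfrac1{DCW}+\tfrac1{DCO}},$$

tested with the Pearson chi-squared statistic (1 df, no continuity
correction).

**Matched resampling null.**  Because disease variants have a different
allele-frequency spectrum than the genomic background, the background
comparison is repeated against $N = 1000$ control groups drawn so that each
one's binned AF histogram equals the disease set's *exactly* (missing AF is
its own stratum).  Each replicate yields an OR and a chi-squared p-value;
the summary is the median OR, the fraction of replicates significant at
$\alpha = 0.05$, and a Benjamini–Hochberg q-value over the replicate
p-values.

**Synthetic ground truth.**  The generator places each disease variant
inside a track of genome coverage $c$ with probability
$p = \lambda c / (\lambda c + 1 - c)$, which makes the population odds ratio
against a uniform background exactly $\lambda$ — so recovery of the planted
fold is a sharp correctness check.

## Worked example

```bash
python analysis/01_simulate_scenario.py   # toy genome + planted variants
python analysis/02_density_tables.py
python analysis/03_background_enrichment.py
python analysis/04_matched_null.py
python analysis/05_consequence_profiles.py
```

The scenario plants, e.g., Mendelian variants at 22× in the promoter track.
Script 03 prints the background-enrichment recovery:

```
planted fold vs recovered ln(OR) +/- SE (all variants):
        mendelian in promoter   planted ln  3.09  recovered  2.88 +/- 0.16  (p = 1.73e-132)
   cancer_somatic in promoter   planted ln  2.39  recovered  2.51 +/- 0.16  (p = 2.63e-92)
  cancer_germline in histone    planted ln  3.28  recovered  3.34 +/- 0.58  (p = 8.57e-19)
          complex in enhancer   planted ln  0.41  recovered  0.55 +/- 0.27  (p = 0.0429)
```

— each recovered log-odds-ratio sits within ~2 standard errors of the
planted log-fold.  Script 04 runs the matched null (1000 control groups per
cell) and prints, among others:

```
       category     track  median_or            q  significant_fraction
cancer_germline   histone  28.121000 6.720700e-11                 1.000
 cancer_somatic  promoter  12.565400 5.304050e-09                 1.000
      mendelian  promoter  19.380100 7.596170e-09                 1.000
```

Planted cells show large median ORs with q ≪ 0.001 and every replicate
significant; unplanted cells hover at median OR ≈ 1 with q near 1.  The same
functionality is available as a CLI (`regvar simulate|density|enrich|
matched-null|consequences`) and as library calls (`regvar.pipeline`).

Pointing the pipeline at real data only changes the config: BED tracks,
GFF3 gene models, variant files per category, and a background panel.

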