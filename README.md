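# sitemut

Localized somatic mutation enrichment in classes of genomic elements.

Cancer genomes accumulate mutations at rates that vary both with local
sequence (trinucleotide context) and with megabase-scale genomic environment
(replication timing, chromatin state). On top of that background, specific
classes of functional elements — CTCF binding sites, transcription start
sites, open-chromatin peaks — can be focal points of mutational processes.
`sitemut` tests whether such a class of elements, taken as a whole, is
enriched or depleted in somatic mutations relative to its immediate flanking
sequence, for whole-genome cancer cohorts. It is aimed at researchers in
cancer and regulatory genomics who have a site catalogue (BED), somatic
calls (VCF or TSV) and a reference genome (FASTA).

## The model

Sites are normalized to a fixed width `2h` around their midpoints, with
equal-width upstream and downstream flanks (together `4h`); positions are
pooled genome-wide and deduplicated so each nucleotide is a site or flank
position, never both. Sites are grouped into ten equal-frequency bins by
their cohort mutation count within ±0.5 Mbp (*MbpRate*), and mutation counts
*nMut* are stratified by bin, site/flank status (*isSite*) and mutation
class (96 pyrimidine-centred trinucleotide substitution classes plus one
indel class), with the corresponding opportunity counts *nPosits* (three
substitutions per valid position, plus one indel opportunity). The counts
follow a negative-binomial regression,

    nMut ~ NegBin( offset(log nPosits) + triNucMutClass
                   + log1p(MbpRate) [+ coFac] + isSite [+ isSite:coFac] )

and enrichment is the likelihood-ratio test of *isSite* (positive
coefficient = elevated mutation frequency in sites). A binary tumour-level
cofactor *coFac* (driver mutation, CNA, WGD, PGA-high, subtype) enables the
*isSite:coFac* interaction test for subgroup-restricted mutagenesis. Fold
changes come from 1000-fold sampling of site counts from the fitted model
with the site effect removed (observed / median expected, CI from the
2.5th/97.5th percentiles), and batches of tests are BH-FDR adjusted. See
`docs/methods.md` for the full account.

The package also ships the surrounding cohort workflows — mutation-subset
batteries (substitution types, strands, SBS signatures, indels),
hypermutator and outlier-tumour filters, down-sampling power analysis,
value-binned site-group comparisons, gene-set TSS analysis, a
genetic-feature interaction screen with PGA computation — and a synthetic
cohort simulator with injected ground truth used by the benchmark suite.

## Worked example

Simulate a 50-tumour cohort on a 5 Mbp genome with 10,000 CTCF-like sites
and a true site-level fold change of 1.25, then run the default battery:

```python
import sitemut as sm

spec = sm.SimulationSpec(
    genome_length=5_000_000, n_sites=10_000, half_width=25,
    n_tumours=50, mean_rate=2000.0, site_fold_change=1.25, seed=7,
)
genome = sm.simulate_genome(spec)
sites = sm.simulate_sites(spec, genome)
muts, truth = sm.simulate_cohort(spec, genome, sites)
res = sm.run_cohort_analysis(sites, muts, genome,
                             config=sm.CohortConfig(seed=7))
print(res[["subset", "p", "q", "coef", "fc", "ci_low", "ci_high",
           "n_mut_site"]].to_string(index=False))
```

```
subset         p         q   coef   fc  ci_low  ci_high  n_mut_site
 total 4.47e-268 4.47e-267  0.222 1.24    1.23     1.26       58828
   C>A  1.08e-46  1.35e-46  0.226 1.25    1.23     1.28        9191
   C>G  2.05e-51   4.1e-51  0.242 1.27    1.25      1.3        9190
   C>T  3.48e-50  4.96e-50  0.237 1.27    1.24      1.3        9270
   T>A  1.76e-51   4.1e-51  0.234 1.26    1.24     1.29        9267
   T>C  2.33e-45  2.59e-45   0.22 1.25    1.22     1.27        9165
   T>G  3.39e-50  4.96e-50  0.221 1.25    1.22     1.28        9151
     w 2.51e-151 8.38e-151  0.221 1.25    1.23     1.26       27391
     c 8.07e-185 4.03e-184  0.239 1.27    1.25     1.29       27843
 indel     0.147     0.147 0.0298 1.03   0.999     1.07        3594
```

Every SNV subset recovers the injected enrichment: the `isSite` coefficient
is ~0.22–0.24 (`exp(0.22) ≈ 1.25`), the sampled fold change 1.24–1.27 with
tight CIs, and the BH-adjusted q-values are overwhelming. The indel subset
is flat (fc ≈ 1.03, q = 0.15) because the generator places indels uniformly
— a built-in negative control in this run.

The same pipeline runs from the shell on standard files:

```
sitemut simulate --genome-length 5000000 --n-sites 10000 --n-tumours 50 \
        --site-fold-change 1.25 --seed 7 --out-prefix toy
sitemut run --sites toy.bed --mutations toy.muts.tsv --genome toy.fa \
        --half-width 25 --seed 7 --out results.tsv
```

Other subcommands: `power` (down-sampling grid), `bins` (value-binned,
down-sampled comparisons), `genesets` (GMT gene sets against TSS sites),
`screen` (binary feature interaction screen, optionally with SEG-derived
PGA), all thin wrappers over the `sitemut.workflows` functions.

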