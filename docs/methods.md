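# Methods

## The model

`sitemut` asks whether a *class* of genomic elements — CTCF binding sites,
transcription start sites, open-chromatin peaks — is collectively enriched or
depleted in somatic mutations relative to its immediate flanking sequence,
after controlling for the two dominant covariates of somatic mutation rate:
trinucleotide context and megabase-scale regional burden.

Each element ("site") is redefined as a fixed-width window `[mid−h, mid+h)`
around its midpoint; the upstream `[mid−3h, mid−h)` and downstream
`[mid+h, mid+3h)` windows are its flanking controls, together twice the site
width. Site and flank positions are pooled genome-wide and deduplicated with
site-over-flank precedence (then nearest midpoint, then smaller site id), so
every nucleotide — and every mutation — counts exactly once. Sites whose full
`6h` window leaves the chromosome are dropped rather than truncated, keeping
all site widths identical (the offset logic assumes this).

For every site, the total cohort mutation count in the one-megabase window
(±0.5 Mbp of the midpoint, always from the *total* mutation set, never from
an analysed subset) defines its `MbpRate`; sites are ranked by
`log1p(count)` and split into ten equal-frequency bins. Counts are then
stratified per (bin × site/flank × mutation class), where the class is one of
the 96 pyrimidine-normalized trinucleotide substitution classes (SBS96) or a
single pooled indel class. Each valid position contributes three SNV
opportunities (its context with each alternative base) and one indel
opportunity (`nPosits`); positions with N in the trinucleotide window are
excluded from opportunities and counts alike.

The stratified counts are modelled with negative-binomial regression,

    nMut ~ NegBin( offset(log nPosits) + triNucMutClass
                   + log1p(MbpRate) [+ coFac] + isSite [+ isSite:coFac] ),

with a log link. The significance of localized enrichment is the chi-square
likelihood-ratio test of `isSite` (df 1); a positive coefficient means
elevated mutation frequency in sites. With a binary tumour-level cofactor
(driver mutation, recurrent CNA, WGD, PGA-high, clinical label), the
`isSite:coFac` interaction tests subgroup-restricted localized mutagenesis;
its p-value is reported unadjusted because it is conditional on the main
effect. Rates, bins, opportunities and counts are computed separately per
cofactor group by default (a `shared_bins` switch pools them).

Fold changes are estimated by sampling: each site row's count is drawn 1000
times from the fitted negative binomial with the site effect removed
(expected counts had sites mutated like flanks), and the observed site total
is divided by the median of the sampled totals; the CI maps the 2.5th/97.5th
percentiles so that it covers the estimate
(`low = obs/P97.5`, `high = obs/P2.5`). Expectations default to the
alternative fit with the site term zeroed rather than the null fit: the null
fit's baseline absorbs part of the enrichment itself (sites are one third of
the pooled positions), which would bias the ratio toward 1 by roughly a
third of the effect; with the alt-based expectation `fc ≈ exp(coef_site)`.
A switch restores null-fit expectations.

Within an analysis batch (one cohort × one site class × all mutation
subsets; per gene set or per feature in the screens) p-values are adjusted
with Benjamini–Hochberg.

## Fitting

Coefficients are estimated by IRLS and the NB shape `theta = 1/alpha` by 1-D
maximum likelihood on `log alpha`, alternated to joint convergence
(tolerance 1e-8, at most 100 rounds). Because the class factor enters as a
one-hot block (the intercept is absorbed into it), the weighted normal
equations are block-diagonal: the class block is a diagonal and only the few
dense covariates need a small Schur-complement solve, making a fit on a
~2000-row table sub-millisecond per iteration. Numerical choices:

- If the NB likelihood exceeds the Poisson likelihood by less than 1e-3, the
  model snaps to exact Poisson (`theta = inf`); near the boundary the
  profile is flat and the estimate would otherwise jitter without ever
  meeting the outer tolerance.
- Rows of classes with zero total count are dropped before fitting: their ML
  coefficient diverges to −∞ and their likelihood contribution to 0, so the
  fit is unchanged while the alternation stays stable. Null and alternative
  fits drop the same rows, so likelihood-ratio tests are unaffected.
- Linear predictors are capped at ±30; zero-opportunity rows are rejected.
- On non-convergence the fit restarts from Poisson-initialized coefficients;
  if that also fails, the Poisson fit is returned flagged
  (`fallback_used='poisson'`), never silently reported as NB.
- Wald standard errors for the dense terms come from the Schur complement of
  the Fisher information at the optimum (dispersion treated as fixed, as in
  standard NB-GLM practice).

statsmodels is used for BH adjustment; in the test suite its NB GLM serves
as an independent cross-check of the fitter (coefficients at the fitted
dispersion, and the dispersion as the profile-likelihood argmax).

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `half_width` h | 25 bp (CTCF-like); 100 bp for TSS / open-chromatin-like | site half-width; flanks are 2h per side |
| `n_bins` | 10 | equal-frequency megabase-rate bins |
| rate window | 1 Mbp | ±0.5 Mbp window for `MbpRate`, truncated at chromosome edges without rescaling |
| hypermutator threshold | 90,000 | tumours with at least this many mutations are removed |
| outlier FDR | 0.001 | single-tumour localized-signal exclusion threshold (BH across tumours, positive coefficient required) |
| min cohort size | 25 | smaller cohorts must be pooled into a meta-cohort explicitly |
| `n_draws` | 1000 | fold-change sampling rounds |
| feature filters | <15 carriers or >2/3 prevalence | strict bounds, applied before the interaction screen |
| gene-set size | 100–1000 genes (inclusive) | measured on genes present in the TSS annotation |

Value-binned comparisons (mRNA-abundance quintiles, CTCF cell-line
conservation bins) down-sample each bin to a common site count (default
4500) over 100 iterations and report the iteration with the median p-value
(lower median for even counts), then BH across bins.

## The synthetic-data generator

The simulator emulates the *statistical* structure the regression consumes,
not mutational biology: an i.i.d. random genome; fixed-width sites placed
uniformly with a minimum gap (default `6h`, keeping analysis windows
disjoint) or, with `site_rate_bias`, clustered preferentially in regions of
high/low regional rate (weight `multiplier**bias`, min-gap not enforced, so
windows overlap and exercise the dedup path); per-tumour mutation totals
Poisson (optionally NB) around `mean_rate` per Mbp; SNV positions drawn
proportionally to a regional multiplier times the injected site fold change
(times a carrier fold change in carrier tumours); SNV classes drawn from a
configurable SBS96 weight vector restricted to the position's context;
indels placed uniformly.

The regional rate field is a lognormal per-Mbp profile (log-sd
`heterogeneity_sigma`, default 0.5) smoothed with a Gaussian kernel of 2 Mbp
and linearly interpolated between block centres. Two properties of this
construction matter and were chosen deliberately:

- *Smoothness.* The `MbpRate` covariate assumes the ±0.5 Mbp window count is
  a faithful estimate of the site-local rate, which holds for real rate
  covariates (replication timing, chromatin domains) whose correlation
  length is multi-megabase. An uncorrelated per-Mbp step field violates
  this — the window average is biased near every step — and produces
  spurious overdispersion that makes the site test conservative for reasons
  that do not exist at genome scale.
- *Edge margin.* Sites are placed so the full rate window fits the
  chromosome. On a 5 Mbp toy genome, edge-truncated windows would otherwise
  fill the lowest rate bin with sites whose local rate is not low (a +28%
  residual in bin 1 in diagnostics); on real chromosomes the affected
  fraction is negligible. When the chromosome is shorter than the rate
  window the margin reverts to `3h` (every window spans everything).

The trinucleotide-preserving shuffle relocates every SNV to a uniformly
chosen position with the identical pyrimidine-normalized context within
±0.5 Mbp (window configurable; indels move to any in-window position),
exactly preserving the SBS96 histogram and approximately preserving regional
rates while destroying site-level localization — the null used for
calibration.

What the generator does **not** emulate: real trinucleotide composition
(the genome is i.i.d. uniform by default), signature mixtures per tumour,
replication-timing or expression mechanisms, structural variants, copy
number, or inter-site width variation. Passing benchmarks therefore show the
statistics behave as designed under their assumptions — calibrated nulls,
unbiased recovery, covariate value under confounding — not that any
biological conclusion transfers to a particular real cohort.

## Benchmark study conditions

All four benchmark procedures live in `sitemut.benchmarks` with frozen
conditions; replicate seeds derive from a single base seed.

- **Null calibration** — 200 cohorts at generator defaults (5 Mbp genome,
  10,000 sites of 50 bp, 50 tumours, 2 mutations/kb/tumour, megabase
  heterogeneity, fold change 1); the default ten-subset battery with
  per-cohort BH. Measured: proportion of cohorts with any q < 0.05 (should
  be ≤ 0.05) and KS uniformity of the total-subset p-values.
- **Recovery** — injected site fold change 1.3; 10 Mbp genome, 20,000
  sites, 100 tumours; success = p < 0.05 and fc ∈ [1.2, 1.4]; 50 seeds.
- **Rate-covariate ablation** — 20,000 clustered sites with placement
  weight `multiplier^-2` (regulatory elements prefer low-rate,
  early-replicating chromatin), heterogeneity sigma 1.0, injected fold
  change 1.15, paired with the trinucleotide-preserving shuffle of the same
  cohort. The ablated model carries no megabase information at all (single
  bin): the bins exist only to carry `MbpRate`, and keeping rate-stratified
  rows without the covariate lets the NB dispersion absorb the confounded
  variation, masking the effect the comparison is about. Expected: the full
  model beats the ablated one on true signals, and the ablated model
  reports spurious significance on the shuffled nulls.
- **Interaction recovery** — 30-of-100 carrier tumours with carrier-only
  fold change 1.3; interaction LRT p < 0.05 with a positive coefficient; 50
  seeds.

Problem sizes were set so the full battery runs in minutes on one CPU while
keeping per-stratum counts comparable to genome-scale cohorts (the 5 Mbp ×
2/kb cohort has the same counts per stratum as a 3 Gbp genome at a
realistic per-tumour burden with proportionally more tumours).

## Known limitations

- Variable-width elements (exons, ncRNAs) are unsupported by design; the
  equal-width construction is load-bearing for the offset logic.
- The framework tests a site *class* in aggregate; it has no per-element
  p-values and is not a driver-discovery method.
- Whole chromosomes are held in memory as byte arrays; fine for simulated
  and regional genomes, wasteful for many full references at once.
- The single-tumour outlier filter refits per tumour and is therefore not
  part of the default battery path; it is exposed as an explicit step
  (`filter_outliers` in the config, or `filter_outlier_tumours` directly).
- LRTs re-estimate the dispersion under null and alternative independently
  (joint ML); with boundary-Poisson data both collapse to the same Poisson
  fit, so the test stays exact in that limit.
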