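# snpsat

Depth-aware single-nucleotide polymorphism (SNP) analysis for shotgun
metagenomes: reliable SNP filtering under varying sequencing depth,
strain-level SNP profiling, saturation assessment over downsampling
series, and prediction of a strain's saturated SNP number from
shallow-sample features.

## The problem

Metagenomic SNPs are the raw material of strain-level analysis of the gut
microbiome, but how many SNPs you find depends strongly on how deep you
sequence. Shallow samples miss real variants; very deep samples accumulate
false positives from sequencing errors and cross-mapping between
homologous genomes, and fixed depth cutoffs stop being appropriate as
depth grows. `snpsat` implements a framework built around four ideas:

1. **Dual-caller consensus.** SNP calls from an mpileup-style caller and a
   VarScan-style caller are each filtered with the conventional thresholds
   (depth ≥ 10, alt-supporting reads ≥ 4, RMS mapping quality ≥ 15,
   variant quality ≥ 10 for the former; depth ≥ 10, reads2 ≥ 4, variant
   frequency ≥ 0.2, p ≤ 0.05 for the latter) and intersected on the
   (chrom, pos, ref, alt) key. Only calls both callers agree on survive.

2. **Mixture-model depth filtration.** For each strain, the per-base depth
   histogram is modelled as a two-component mixture
   `w_exp · Exp(λ) + w_norm · N(μ, σ)`: the normal component is depth from
   correctly recruited reads, the exponential component is low-depth noise
   from errors and homologous mismapping. After an EM fit, the filter
   keeps at least 90 % of the normal mass and discards at least 50 % of the
   exponential mass, taking the smaller of the two cutoffs; across a
   downsampling series, cutoffs are made non-decreasing with depth.

3. **Saturation statistic R.** For a strain observed at increasing
   subsample levels, depth and SNP count are min–max normalised to [0, 1]
   and `R_i = |Y_i − Y_{i−1}| / (X_i − X_{i−1})` is computed between
   adjacent points. A strain is saturated when R decreases along the
   series and the final R is below 0.1; the SNP count at the deepest level
   is then its *saturated SNP number*.

4. **SNPsnp prediction.** A linear and a random-forest regression predict
   the saturated SNP number from six shallow-sample features (sequencing
   coverage, sequencing depth, relative abundance, genome length, current
   SNP number, current SNP density), evaluated by relative square error
   (RSE), relative absolute error (RAE) and R² = 1 − RSE on a held-out
   1/5 split, with forest hyperparameters chosen by 5-fold CV grid search.

Along the way the package computes the standard strain-level profiles:
length-normalised relative abundance `r_s = (n_s/l_s) / Σ_t (n_t/l_t)`,
genome depth and coverage, CDS vs non-CDS SNP classification against a
GFF3 annotation, dN/dS (the count ratio of non-synonymous to synonymous
variants), allele-frequency spectra, taxon-level SNP aggregation, and
shared-SNP partitions across samples with per-subset dN/dS and a
chi-square comparison.

A synthetic-data module generates every input the toolkit consumes (depth
profiles, paired caller VCFs, GFF3 annotations, FASTQ reads, downsampling
series, predictor cohorts) with known ground truth, so the whole pipeline
is testable without any download.

## Worked example

```python
from snpsat.synthetic import default_scenario, simulate_depth_profile
from snpsat.depth_mixture import fit_depth_mixture, select_threshold
from snpsat.strain_profiles import compute_dnds

scenario = default_scenario(seed=1)
_, hist = simulate_depth_profile(scenario, "strainA")   # true mixture: w_exp=0.3, λ=0.2, μ=60, σ=6
fit = fit_depth_mixture(hist)
print(f"w_exp={fit.w_exp:.3f}  lambda={fit.lam:.3f}  mu={fit.mu:.2f}  sigma={fit.sigma:.2f}")
thr = select_threshold(fit)
print(f"t_norm={thr.t_norm}  t_exp={thr.t_exp}  t_final={thr.t_final}")

print(compute_dnds(counts=(15.73, 76.06)).ratio_2dp)
```

prints

```
w_exp=0.298  lambda=0.197  mu=59.96  sigma=6.00
t_norm=52  t_exp=4  t_final=4
0.21
```

The EM fit recovers the generating mixture to well under 1 % relative
error; the depth cutoff of 4 discards half the exponential (noise) mass
while keeping far more than 90 % of the normal mass (whose 90 %-retention
cutoff would be 52). The last line is the dN/dS ratio for a sample where
non-synonymous and synonymous variants make up 15.73 % and 76.06 % of SNPs.

The full pipeline — simulate, fit, dual-caller filter, depth filter,
profile, saturation — runs from the shell and writes a sha256 manifest, so
you can verify that two runs with the same seed are bit-identical:

```bash
snpsat run --out out_dir --seed 7
```

Narrative scripts for each capability live in `examples/`.

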