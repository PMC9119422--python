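# Methods

This note documents the models and procedures `snpsat` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Depth-mixture filtration

**Model.** For each strain, per-base depths of covered positions (depth ≥ 1;
uncovered positions carry no reads and cannot host SNP calls) are modelled
as a two-component mixture: an exponential component for noise-derived
bases (sequencing errors, mismapping among homologous genomes, which pile
up at low depth) and a normal component for correctly recruited bases
centred near the strain's genome depth.

**Likelihood.** Depths are positive integers, so both components are
defined on the integer lattice. The exponential component uses the exact
law of `ceil(Exp(λ))`, a geometric-form pmf `(1 − e^−λ)·e^{−λ(k−1)}`,
k ≥ 1. This choice matters twice: it matches how the simulator discretises
exponential draws (round up, so every draw is a covered position), and its
weighted MLE has the closed form `λ = −log(1 − 1/m̄)` where `m̄` is the
responsibility-weighted mean — making the M-step an exact maximiser. The
normal component uses the Gaussian density evaluated at integer depths;
its lattice sum deviates from 1 by less than 1 % for σ ≥ 0.5 (and
negligibly for σ ≥ 1), so the standard weighted mean/SD M-step is exact
for this objective too. Both M-steps being exact, the EM log-likelihood is
monotone non-decreasing, which the tests assert per iteration.

**EM settings.** Relative log-likelihood tolerance 1e-8, max 500
iterations, one moment-based initialisation (λ from the mean of depths at
or below the 25th percentile, μ/σ from the rest) plus 3 random restarts
from a generator seeded at 42; the highest-likelihood fit wins. σ is
floored at 0.5 to prevent variance collapse onto a single depth atom. A
histogram with a single distinct depth returns a flagged degenerate fit
(pure normal at that depth); fewer than 50 covered positions is an error.

**Threshold selection.** Cutoffs are read off the fitted *continuous*
distributions: `t_norm` is the largest integer t with truncated-at-zero
normal survival `P(D ≥ t | D > 0) ≥ 0.9` (so `keep_normal = 1` gives
t_norm = 0), and `t_exp` is the smallest integer t with exponential CDF
`P(D < t) ≥ 0.5` (for λ = log 2 the exponential median is exactly 1, so
t_exp = 1). The final cutoff is `min(t_norm, t_exp)`; sites shallower than
it are discarded. The cutoff is a *lower* bound on depth because the
exponential noise component dominates at low depth. The split — discrete
likelihood for fitting, continuous CDFs for quantile selection — keeps the
fit exact for integer data while making the quantile rules independent of
lattice artefacts. Degenerate fits get t_final = 0 (no filtering).

**Cross-level harmonisation.** Over a downsampling series ordered by
level, a cutoff lower than its predecessor's is replaced by the
predecessor's value (flagged), so cutoffs are non-decreasing with depth.

## Dual-caller consensus

Both filters use inclusive bounds. The mpileup-style filter maps the
vcf-annotate letter codes d/a/Q/q to minimum depth 10, minimum
alt-supporting reads 4, minimum RMS mapping quality 15 and minimum variant
quality 10; the VarScan-style filter requires depth ≥ 10, reads2 ≥ 4,
variant frequency ≥ 0.2 and p ≤ 0.05. A record missing an optional field
(p-value, mapping quality, variant quality) skips that sub-test — caller
output is heterogeneous and absence is not evidence of failure — with
skip counts logged. Records are intersected on (chrom, pos, ref, alt)
after multi-allelic splitting; the merged record keeps both callers'
provenance tags and the larger of the two depths (callers pile up reads
differently; disagreements are logged). Indels are dropped on read, not
errored: the analysis is defined over single-base substitutions.

## Per-cycle read trimming

For a read set, `f_j` counts base calls at read cycle j (so f is
non-increasing for variable-length read sets). Cycles with
`|f_j − mean(f)| > 2·SD(f)` (population SD over cycles 1..max length) are
removed as whole columns from every read — the text this implements says
sites are "cut", not end-trimmed, so interior columns can be removed and
the flagged-cycle report lets users audit. Quality strings are cut in
lockstep. Reads below 45 bases afterwards are dropped, mirroring the
minimum-length filter applied upstream. With zero variance (all lengths
equal) nothing is cut; `k_sd = inf` is an explicit no-trim sentinel. The
2·SD rule is applied per read cycle, not per genomic site; the source text
is ambiguous and the per-cycle reading is the one implemented.

## Strain profiles

Relative abundance is `r_s = (n_s/l_s) / Σ_t (n_t/l_t)` over uniquely
mapped read counts and genome lengths; genome depth is mapped bases over
genome size; coverage is the fraction of positions with depth ≥ 1; SNP
density is SNP count over covered length, with "covered" meaning depth ≥ 1
(configurable; the alternative reading, depth at or above the filter
threshold, is not the default). A SNP is CDS iff its position lies in any
CDS interval, 1-based inclusive on both ends. dN/dS is the raw count ratio
of non-synonymous ({missense variant, start lost, stop gained, stop lost})
to synonymous ({start retained variant, stop retained variant, synonymous
variant}) labels — no per-site opportunity correction — which makes it
scale-invariant, so published percentage tables reproduce published
ratios exactly; a zero synonymous count leaves the ratio undefined rather
than infinite. Reported ratios round half-up to 2 decimals. The chi-square
comparison of non-synonymous/synonymous composition across shared-SNP
categories is Pearson's test on the 2×k table without continuity
correction (counts are large in the intended setting). "SNP-enriched
genes" is a ranking by length-normalised SNP count per CDS; no enrichment
test is invented. The allele-frequency spectrum uses 50 bins over [0, 1]
with a right-closed final bin so fixed variants (frequency 1.0) are
counted.

## Saturation

Levels and SNP counts are min–max normalised per strain — the only
normalisation that maps any series onto [0, 1] endpoints, and it makes R
invariant under affine rescaling of either axis, so raw read counts and
raw depths are interchangeable as the x variable when proportional.
`R_i = |ΔY|/|ΔX|`. Saturation requires (1) R non-increasing along the
series within a 5 % relative tolerance, and (2) final R < 0.1. One
addition to the strict reading of (1): an increase whose new value stays
below 0.1 (the flatness cutoff of condition 2) is not counted as a
violation. On a plateau, adjacent subsamples differ by a SNP or two of
sampling noise, which sends R from exactly 0 to a tiny positive value;
vetoing saturation on such a step would reject visibly plateaued series.
Both tolerances are configurable and reported in the verdict. The
saturated SNP number of a saturated series is its count at the deepest
level — the quantity the predictor regresses on.

## SNPsnp predictor

Features: coverage, depth, abundance, genome length, SNP count, SNP
density (in that order); target: saturated SNP number; only saturated
strains contribute rows, one per (strain, subsample level). The split is
a seeded random 4:1 row split (a grouped-by-strain split is available
because rows of one strain are correlated, but the plain split is the
default). The forest grid is trees {100, 300, 500} × max depth
{unlimited, 10, 20} × min samples per leaf {1, 3, 5}, scored by 5-fold CV
R² on the training split only; test metrics come from the untouched
split. RSE = SS_res/SS_tot, RAE = Σ|residual|/Σ|deviation|, R² = 1 − RSE
(an identity the tests assert). The linear model keeps all singular
values in its least-squares solve (`tol=0`): the features span ~10 orders
of magnitude and the default small-singular-value truncation silently
degrades an exactly linear fit. Predictions are clipped at 0, and a
prediction below the strain's current SNP count is flagged as model
misfit rather than silently returned. Models persist as a directory of
joblib files plus a JSON with format version, feature order,
hyperparameters and training metadata.

## Synthetic data: what it emulates, and what it does not

Generators are bit-reproducible: all randomness flows from a scenario
seed through numpy seed sequences with fixed per-strain, per-purpose
spawn keys.

*Depth profiles* draw each position independently from the strain's
exponential+normal mixture (exponential draws rounded up to ≥ 1, normal
draws rounded and clipped at 1). No positional autocorrelation is
modelled — the histogram-based fit ignores position order, so tests of
the mixture machinery do not depend on it — which means passing tests say
nothing about spatially structured coverage artefacts (GC waves, repeat
pile-ups).

*Call sets* detect a true SNP per caller iff site depth ≥ 10 and an
independent binomial draw of alt reads (success probability
`freq·(1 − error)`) reaches 4 reads and 20 % frequency — deliberately
mirroring the consensus thresholds so limit cases are analytically
predictable (zero error, fixed alleles, depths ≥ 10 ⇒ both callers emit
exactly the truth). Each caller adds its own false positives at sites
drawn independently, so intersection removes most of them; the tests
assert the qualitative property that intersection precision beats either
single caller, not a specific precision number. No read-level sequence is
simulated: counts, not bases, so caller-specific error modes are out of
scope.

*Saturation series* thin each SNP's full-depth site binomially to
`level/level_max` and apply the detection rule. The study conditions used
by the saturation acceptance checks: one strain with 400 true SNPs, full
site depth 200 ± 10, an 8-point schedule at fractions
(0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0) of 2×10⁷ reads; "truncated"
series keep the first 3 points at the full-series depth scale. 400 SNPs
at depth 200 is a small but realistic dominant strain; the sizes keep the
full suite in seconds while leaving the binomial noise visible.

*Predictor cohorts* draw coverage in [0.5, 1], depth in [1, 500],
abundance in [0.01, 0.3], genome length in [2, 7] Mb, SNP count
log-uniform in [10³, 10⁵], density = count/(coverage·length). The linear
relation is an exact affine function of the six features (for exact
recovery tests); the nonlinear relation multiplies the current SNP count
by a smooth monotone factor of log-density, so the target is dominated by
current SNP number with SNP density the clear second signal — matching
the qualitative importance ordering the method's motivation predicts —
plus 2 % multiplicative noise by default.

*Bundled pipeline scenario*: three strains (30/20/25 kb genomes,
abundances 0.5/0.3/0.2, 150/100/60 true SNPs, genome depths 60/45/30).
Genome sizes are far below real bacterial genomes; they keep the
end-to-end run under a second while exercising every stage. Mapped-read
counts in the fixture metadata are proportional to abundance × genome
length, so relative abundances reproduce the specified values exactly.

## Known limitations

- dN/dS is a count ratio; it is comparable across categories within this
  framework but is not a per-site ω estimate.
- The depth filter assumes a unimodal "correct" component; strains with
  strongly bimodal true coverage (e.g. plasmids at different copy number)
  would need more components, which are out of scope.
- The saturation criterion is a heuristic on a finite series; a series
  that plateaus within the observed range but would rise again deeper
  cannot be distinguished from a truly saturated one.
- Effect labels are consumed, never computed: annotation is the job of an
  external effect predictor, and label vocabularies are normalised only
  by case and space/underscore.
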