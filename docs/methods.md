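# Methods

## Error model

A pool of N diploid individuals drawn from a population with SNP allele
frequency p has true pool frequency `p̂ ~ Binomial(2N, p)/2N`, with sampling
variance `V_s = p(1−p)/2N`. Measuring `p̂` on array x yields
`p̃_x = p̂ + e_construction + e_array_x`, where the construction error is
shared by every array of one physically constructed pool and the array error
is independent per array. Both error variances are treated as constant
across SNPs — an approximation that understates the error of low-MAF SNPs —
and unequal allelic amplification is assumed to cancel in the paired-array
contrasts that all estimators below are built on.

## Allele-frequency estimation and filtering

The per-SNP estimate is the unweighted mean over beads of
`G/(G + c·R)`, where `c` is the strip's red-channel scale (1 in raw mode).
Beads with a negative intensity in either channel are removed first; beads
with zero in both channels are counted as failed and removed next (a bead
with one negative and one zero channel is classed negative — the two rules
are order-dependent and this order is fixed here). SNPs with fewer than four
remaining beads are excluded entirely rather than reported as missing, so
downstream pairings operate on SNP-set intersections.

Normalization solves, per strip, the scale `c` at which the mean of per-SNP
frequency estimates equals 0.5. The mean is strictly decreasing in `c`
whenever some bead has both channels positive, so bisection on log c over
[1e-6, 1e6] (tolerance 1e-9 on the mean, cap 200 iterations) finds the
unique root; strips where the mean is bounded away from 0.5 raise instead of
returning a boundary value. The targeted mean is SNP-level (estimate per
SNP, then average); a `level="bead"` switch averages raw bead ratios
instead, which differs when bead counts vary between SNPs.

## Variance estimators

For two arrays sharing n SNPs the difference variance is
`(1/(n−2)) Σ d_i²` — the n−2 divisor is kept exactly as defined for this
estimator (at array scale the difference from 1/n is negligible; at test
scale it is visible, and the unit tests pin it). Type A divides by 2;
Type B likewise after pairing arrays across two replicate constructions;
Type C subtracts, per SNP, the binomial term
`V~_i = p1(1−p1)/2Na + p2(1−p2)/2Nb` computed from the observed pair of
frequencies. The sum convention (not a difference) and the 2N denominators
follow from `V~` being the variance of a difference of two independent pool
frequencies under the same diploid convention as `V_s`; a
`denominator="N"` switch is provided for comparison with haploid-count
conventions.

With k arrays per pool, every estimate averages all C(k,2) within-pool or
kA·kB cross-pool pairings, unweighted (pairings are not weighted by SNP
overlap; overlaps are near-identical on a given array type). Construction
variance is the pooling estimate minus the experiment- or batch-mean array
variance, clamped at zero with the raw value and a flag retained — clamping
induces a small upward bias in averages of construction estimates, which is
why the pre-clamp value is kept. Arrays whose mean within-pool pairwise
variance exceeds 5× the experiment median are flagged (not removed) as
suspected hardware faults.

`PooledExperiment.fit()` wires these together: per batch (optional
stratification by `batch_id`), the array variance is the mean of per-pool
Type A estimates with min/max range; per pool, Type B is used when a
construction replicate exists and Type C against every other pool otherwise,
averaging all pairings that involve the pool.

## Planner and power

`RSS = V_s / (V_s + var(e_pooling)/k)` and `N* = round(RSS·N)` (round to
nearest — the planning tables this package reproduces round 283.76 to 284).
The 1/k replicate-array reduction is applied to the whole pooling variance,
construction term included, matching the convention of the planning tool
this module re-implements; a `reduce="array-only"` switch confines the
reduction to the array component for users who construct a single pool.
An array:construction ratio like 7:3 is read as shares of the *total*
pooling variance (`var_pooling = var_array/0.7`); this is the reading that
reproduces the published planning tables, and differs from taking 30% of
the array variance. Shipped MAF defaults: 0.21 (1M-class arrays) and 0.29
(660-class), HapMap-CEU averages.

Array allocation between two pools minimizes
`var_poolingA/kA + var_poolingB/kB` (the estimation-error contribution to
the case-control frequency-difference variance) by exhaustive scan, ties
broken toward the balanced split; with equal pooling variances the equal
split is optimal regardless of pool sizes.

Power uses the allelic two-proportion normal approximation on effective
chromosome counts (2·ESS per group): a per-allele odds ratio OR shifts the
case frequency to `OR·p/(1+p(OR−1))`, and the two-sided level-α z-test power
follows with the pooled-null standard error under H0 and the unpooled one
under H1. This is a deliberate approximation to dedicated genetic power
calculators (which model penetrance and disease incidence); at the rare
incidences typical of these designs control frequencies approximate
population frequencies and the two agree to within a few hundredths of an
odds ratio, so MDOR checks in the tests use a ±0.05 tolerance and ordering
properties, never bit-exactness. MDOR is found by bisection on log OR to
1e-4.

## Synthetic data generator

`simdata` emulates the generative chain sampling → construction → array →
beads with additive Gaussian errors on the frequency scale, clipped to
[0, 1] (clip events are counted; above 1% of draws a `heavy_clipping` flag
warns that the additive model is breaking down). Defaults are chosen to
represent a normalized Illumina-class experiment: 17 beads per SNP,
`sd_array = 0.0182` (variance ≈ 3.3e-4), `sd_construction = 0.0119`
(construction ≈ 30% of pooling variance), `sd_bead = 0.02` of per-bead
jitter, MAF ~ Uniform(0.05, 0.5), pools of 300, total bead intensity ~
Normal(1000, 100). Allele labels are randomly oriented per SNP so strip
means sit near 0.5 as on real arrays. Because each array-level frequency
averages `beads_per_snp` noisy beads, the estimators see an *effective*
array variance `sd_array² + sd_bead²/beads_per_snp`
(`SimConfig.var_array_effective`); recovery tests compare against this
quantity. Construction replicates share the realized binomial frequencies
but draw independent construction errors.

What the generator does not emulate: dye-specific intensity physics
(saturation, unequal allelic amplification — a hook field is reserved),
LD between SNPs (all SNPs independent), array-to-array bead-count variation
(bead count is fixed per configuration), and heavy-tailed error
distributions. Passing recovery tests therefore demonstrate estimator
correctness under the stated additive-Gaussian model, not robustness to
every artefact of real arrays.

## Problem sizes and numerical choices

Parameter-recovery tests use 1e5 SNPs / 2 arrays for the array-variance
check (estimator SD ≈ 0.5% of the value, well inside the 10% tolerance) and
20 seeded replicates of a 3-pool × 2-array experiment at 1e4 SNPs for the
construction share (SD of the 20-replicate mean ≈ 0.5 percentage points
against a 5-point tolerance). The acceptance script's quantities are exact
planner arithmetic and run in milliseconds. All simulations take explicit
integer seeds; identical configuration and seed reproduce byte-identical
bead tables.

## Known limitations

* Constant-variance assumption across SNPs; no MAF-stratified modelling.
* Type C construction estimates inherit any misfit of the binomial
  correction (e.g. related individuals or population structure inflate it),
  and zero-clamping biases averages of small construction components upward.
* The planner's published control-pool table is reproducible only for its
  in-text claims; one printed column is consistent with a slightly smaller
  effective MAF than its stated 0.29, so exact checks are restricted to the
  case pool and in-text values.
* Power is approximate by design; for matched designs, dominance models or
  two-stage designs, use a dedicated calculator with the ESS from here.
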