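# Methods

This note documents the models, algorithms and design choices behind
`tetragp`, what the synthetic breeding program does and does not emulate,
and the numerical conventions the implementation relies on.

## The synthetic breeding program

The simulator exists so that every analysis stage can be exercised and
validated without access to a real program's confidential genotypes. It
reproduces the *statistical structure* the analysis depends on, not potato
biology in full.

**Genomes and meiosis.** Each individual is tetraploid: four allele copies
per biallelic marker, dosage = count of the alternate allele ∈ {0..4}.
Meiosis is tetrasomic: a gamete receives two of the parent's four copies
drawn without replacement (random chromatid segregation), except that with
probability `alpha_dr` a double-reduction event duplicates one uniformly
drawn copy. The theoretical ceiling for the double-reduction rate under
random chromatid segregation is 1/6, which the code enforces. The default
`alpha_dr = 0.05` reflects genome-wide rates of a few percent typically
estimated in autotetraploids; the exact value is not critical to any
tested quantity and is a single dial for sensitivity analyses. Two exact
consequences are used as test oracles: a duplex (AAOO) parent yields an AA
gamete with probability 1/6 at α = 0, and a simplex (AOOO) parent yields
AA only through double reduction, with probability α/4.

**Loci are unlinked.** Chromosome labels (1–12) are carried in marker
names for file realism only. None of the downstream quantities —
ridge-regression GEBVs, PCoA, heritability, accuracy — use map positions,
so linkage would add cost without touching anything the tests measure.
Consequently the simulator cannot emulate linkage-disequilibrium decay
between training and test sets; accuracies measured here reflect
family/cohort relatedness, not marker–QTL phase.

**Founders and families.** Founder genotypes are drawn with per-marker
alternate-allele frequencies Uniform(0.1, 0.9) (so most markers survive
the MAF filter and the post-QC panel size is stable). The T1 generation
is five bi-parental full-sib families of sizes (51, 51, 149, 152, 62) —
465 seedlings — with deliberately overlapping parentage: three of the five
mothers are themselves full-sibs from one grandparental cross and four
families share a father, mirroring the pedigree entanglement that makes
cross-family prediction hard in practice.

**Selected cohorts.** T2 (138 clones) and T3–7 (62 clones) are separate
crossing cohorts drawn from the same parental pool, passed through one and
`n_cycles + 1` rounds of phenotypic truncation selection respectively.
Selection truncates on the single-location phenotype mean, emulating
visual field selection; the selected fraction per round is
`selection_fraction` (default 0.3) and the final cohort sizes are pinned
to the configured targets. Because one fraction cannot produce both
465→138 and 138→62 exactly, the cohort sizes are explicit configuration
(`generation_sizes`, defaults (138, 62)) and the fraction sizes the
candidate pools. Making T2/T3–7 separate cohorts (rather than subsets of
T1) keeps generation labels a partition of the sample set while still
producing a measurable selection response: the mean true genetic value of
T2 exceeds T1's because both descend from the same founder pool.

**Genetic values and phenotypes.** Genetic values are additive in dosage:
`g = Xc·β` with β drawn once and rescaled so that var(g) over the T1
cohort equals `sigma2_g`; the same β is applied to all later cohorts, so
the trait stays heritable across cycles (necessary for any selection
response). Plot records follow `y_ijk = μ + g_i + l_j + (gl)_ij + ε_ijk`
with independent normal location, G×E and residual draws at the configured
variances. Defaults `σg² = 1, σloc² = 0.5, σg×e² = 0.5, σE² = 1` give a
plot-basis heritability of 1/3 and entry-mean H² around 0.6 for the
multi-location trial design — the moderate range reported for tuber yield
traits. The trial layout mimics a real program: T1 at one site with one
replicate, T2/T3–7 at the main site with two, a 38-clone subset of T3–7
at all three sites with 1–2 replicates (the set heritability is estimated
on), and five check cultivars at every site. Dominance and epistasis are
not simulated: the analysis model is additive, and simulated data with
non-additive variance would only add a constant haze to every accuracy.

**Marker-panel size.** The default `n_markers = 2000` is a deliberate
desk-scale choice: prediction accuracy and all validated properties depend
on sample structure and variance components, not on matching a commercial
array's panel size, and a ten-times-larger panel would multiply every test
and pipeline runtime by the same factor for no informational gain.

**What a passing test shows.** Green tests demonstrate that each stage
computes its estimand correctly under the model the generator implements
(independent loci, additive effects, normal environmental structure). They
do not certify behaviour under linkage, assay artefacts beyond random
no-calls, or non-normal G×E — real-data properties the study design itself
has to handle.

## Dosage QC

Filter order is fixed and idempotent: missingness → mode imputation → MAF.
Markers with missing fraction strictly greater than 0.10 are removed;
remaining no-calls are imputed with the marker's modal dosage (ties break
to the numerically lowest dosage, for determinism); markers with MAF
strictly below 0.05 are then removed. Allele frequency of a tetraploid
marker is mean dosage / 4 over observed calls — the dosage-weighted
definition standard for polyploid array data — and MAF is folded,
min(p, 1−p). Frequencies are computed on exactly the samples passed in,
so subsetting samples before filtering legitimately changes the retained
panel (family-level analyses re-filter within their subset). Duplicate
concordance is the fraction of jointly observed markers with unequal
calls; technical replicates should sit well below 1%, unrelated clones
near 50% or above.

## PCoA

Classical scaling of the Euclidean dosage distance matrix: double-center
−D²/2, eigendecompose, scale eigenvectors by √λ. Percent variance is
reported over positive eigenvalues only (for exact Euclidean input all
eigenvalues are non-negative up to round-off; small negative ones are
excluded from the denominator, the ordination literature's convention).
Axis signs are fixed by making each axis's largest-magnitude coordinate
positive so output is platform-reproducible. On dosage input this is
identical to centered PCA of the dosage matrix — an identity the tests
assert to 1e-8, alongside a cross-check against scikit-bio's independent
implementation.

## Phenotype processing

Location adjustment is additive centering: each record gets
`raw − (check mean at its location − grand mean of the per-location check
means)` for its trait. This preserves trait units and within-location
contrasts exactly, zeroes the between-location variance of check means,
and leaves the checks' grand mean unchanged. A multiplicative alternative
was rejected because zero-valued check means would be degenerate.
Late-blight severity is never location-adjusted (scored on a per-plant
basis only). AUDPC is the plain trapezoid rule over strictly increasing
scoring dates, in score·days; no standardization by trial length.

## Bayesian ridge regression

The model is `y = 1μ + Xβ + e` with a flat prior on μ,
`β ~ N(0, σβ²I)`, `e ~ N(0, σe²I)`, and scaled-inverse-χ² priors on both
variances (df = 5 each). Prior scales are solved from a prior proportion
of variance explained R² = 0.5:

    scale_β = R² · var(y) · (df_β + 2) / (df_β · Σ_j var(x_j))
    scale_e = (1 − R²) · var(y) · (df_e + 2) / df_e

the convention of the widely used whole-genome-regression software this
model class comes from. Dosage columns are accepted raw (0–4) and
mean-centered internally; the intercept absorbs the shift, and GEBV
contrasts — hence Pearson accuracies — are unchanged.

Posterior inference is single-site Gibbs: μ from its normal full
conditional; each β_j from `N(rhs_j/c_j, σe²/c_j)` with
`c_j = x_j'x_j + σe²/σβ²` and single-site residual updating; then
`σβ² ← (β'β + df_β·S_β)/χ²(df_β + p)` and
`σe² ← (e'e + df_e·S_e)/χ²(df_e + n)`. The sweep is compiled with numba;
the chain is seeded inside the kernel, so identical inputs give
bit-identical chains. No thinning; posterior means average all
post-burn-in samples. Defaults are 45,000 iterations with 15,000 burn-in —
full-analysis settings; tests and the demo run reduced chains (stated in
each config), which is safe for this model because the posterior is
unimodal and mixing is fast at these sizes. Monte-Carlo standard errors
use batch means (20 batches), which calibrate well against across-seed
empirical standard errors for these chains.

Two identities anchor correctness: with both variances fixed, the
posterior mean of β is exactly the closed-form ridge estimator
`(Xc'Xc + (σe²/σβ²)I)⁻¹Xc'(y − ȳ)` (exposed as `ridge_solution`); and
marker-model predictions equal kernel GBLUP built from `K = Xc Xc'·σβ²`.
The test suite checks the first to Monte-Carlo precision and the second to
1e-6. Unphenotyped individuals are excluded from the likelihood and
predicted afterwards — equivalent to missing-response handling for point
predictions.

## Variance components and H²

The trial model has a fixed intercept and independent identity-covariance
random terms: genotype, location, genotype×location, and
replicate-within-location (the last optional). Estimation is EM-REML on
Henderson's mixed-model equations: at current variance ratios solve the
MME, then update each component from its BLUP sum of squares plus σe²
times the trace of the corresponding block of the inverse coefficient
matrix, and σe² from the residual quadratic form over n − rank(X).
Stopping: maximum relative change < 1e-8 or 500 iterations. EM's linear
convergence is slow near the zero boundary, so every five sweeps each
component is Aitken-extrapolated; components whose extrapolated fixed
point is at or below zero are pinned at the boundary (and reported as 0
with a logged warning). On balanced designs with interior estimates the
result equals the expected-mean-squares ANOVA solution, which the tests
assert to 1e-6. Component standard errors are out of scope.

Broad-sense heritability is on the entry-mean basis,
`H² = σg² / (σg² + σg×e²/Hm1 + σE²/Hm2)`, with Hm1 the harmonic mean of
replicate counts over genotype×location cells and Hm2 the harmonic mean of
total replicate counts per genotype — division by the harmonic means, the
standard unbalanced-design correction (the alternative reading,
multiplication, would make H² shrink with better replication, which is
not a heritability).

## Accuracy evaluation

Accuracy is always Pearson r between observed location-adjusted genotype
means and GEBVs; negative values are reported as computed and flagged
"not predictable", never clipped. Cross-generation partitions are
deterministic from the generation labels, optionally appending the T1
parents/grandparents to the training set. Cross-family evaluation trains
on one full-sib family and predicts the other, both directions, after
re-filtering markers by MAF within the two families. Repeated k-fold CV
randomizes fold membership per replicate, predicts every individual from
a model that never saw its phenotype, and computes **one r per replicate
on the assembled prediction vector** (not per fold) — matching the
convention of repeating until every individual has a predicted value —
then reports the mean and the across-replicate standard deviation.

A methodological caveat the test suite encodes: under a permutation null,
the assembled-fold r for one *fixed* permuted phenotype vector carries a
realization-specific offset that repartitioning alone does not remove.
Null calibration therefore redraws the permutation each replicate; with
100 fresh permutations the mean accuracy is within ±0.1 of zero.

## Pipeline and reproducibility

`run-all` derives one seed per stage from the single top-level seed (via
`SeedSequence`), records derived seeds, package version and SHA-256
checksums of all inputs in `manifest.json`, and writes only delimited
text. Re-running a config reproduces every output byte for byte. Problem
sizes in the shipped demo (≈500 clones × 2,000 markers, 1,500-iteration
chains, 5 CV replicates) are chosen so the whole pipeline completes in
well under a minute while exhibiting every structural feature of the
full-scale analysis.

## Known limitations

* No linkage or recombination map; cross-cohort accuracy here cannot decay
  with LD-phase differences as it would with real panels.
* Additive genetic values only; broad-sense H² on simulated data has no
  non-additive component to absorb.
* EM-REML handles the identity-covariance random terms of the stated trial
  model only — no spatial models, pedigree kinship, or heterogeneous G×E
  covariances.
* Mode imputation is the analysis convention implemented; it is known to
  bias allele frequencies toward the major class at high missingness
  (the 10% missingness filter runs first for exactly that reason).
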