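# Methods

## The analysis model

`cnvsig` treats each recurrent CNV (deletion/duplication at 1q21.1, 15q11.2,
16p11.2, 22q11.2) as inducing a characteristic whole-brain pattern of
grey-matter volume change. The analysis has four stages.

**Confound adjustment.** Parcel volumes are residualized per region by
ordinary least squares on a fixed-effect design: intercept, intracranial
volume, age, age², sex and acquisition-site indicators for the clinical
recipe; additionally body-mass index and head motion for the population
recipe. Site is a categorical fixed effect rather than a random factor —
this gives a deterministic closed-form residualization that is equivalent in
expectation for balanced designs, and the `design` argument lets a caller
swap the site handling. Coefficients fit on one subject set can be applied
to another (`apply_confound_model`); by default each cohort is adjusted with
its own fit. An optional total-grey-matter column can be added to the
design; it is off by default because it has no appreciable effect on the
downstream statistics. Discriminant models consume adjusted (not z-scored)
volumes; z-scoring (sample SD, n−1) is applied per carrier-plus-control
comparison only for the Cohen's d analysis.

**Effect maps.** Cohen's d per region uses the pooled-SD form
`(x̄₁−x̄₂)/√((s₁²+s₂²)/2)` with n−1 SDs. Map pairs are compared with
Pearson's r; significance comes from a spin permutation null: Haar-uniform
3-D rotations (QR of a Gaussian matrix with sign correction) are applied to
the parcel centroids, and each parcel takes the value of the parcel whose
original centroid is nearest to its rotated position. Nearest-centroid
reassignment can duplicate values — the simplest well-defined parcel-level
spin. The test is two-sided on |r| with p = (1 + #{|r_null| ≥ |r_obs|}) /
(n_perm + 1); pairwise matrices are corrected with Benjamini-Hochberg FDR.
Lin's concordance uses population (n-divisor) moments, so it equals Pearson's
r exactly when the two vectors share mean and variance.

**Signature ensembles.** The intermediate phenotype of a CNV is the average
of B sign-aligned, unit-normalized LDA discriminants fit to stratified
bootstrap resamples (class counts preserved, as in the study design). The
covariance estimate is the maximum-likelihood (n-divisor) pooled
within-class covariance shrunk toward a scaled identity,
`Σ(α) = (1−α)S + α(tr S/p)I`; the decision rule is
`w'x > w'(μ₀+μ₁)/2 − log(π₁/π₀)` with empirical priors. Per bootstrap, α is
selected on the in-bag set by exact leave-one-out over the grid
{0.0, 0.1, …, 1.0}: all LOO predictions are pooled into one confusion
matrix scored by MCC (the selection metric matches the evaluation metric),
ties break to the smallest α, and α = 0 scores −∞ whenever the reduced-set
covariance is singular. The LOO refits are exact but cheap: in the
eigenbasis of the full pooled scatter, dropping one subject turns every
shrunk system into a diagonal-minus-rank-one matrix solved by
Sherman-Morrison in O(p) (verified against literal per-sample refits).
Performance is the mean out-of-bag MCC; an iteration whose out-of-bag set
misses a class is redrawn up to 10 times and otherwise excluded (counted
and reported). Discriminants are aligned by the sign of their correlation
with the group's Cohen's d map (ties to +1) and unit-L2-normalized before
averaging, so high-variance fits cannot dominate the mean; per-region
2.5/97.5% bootstrap percentiles give the significance mask. The
permutation null shuffles labels and reruns the entire bagged procedure —
including per-bootstrap shrinkage selection — n_perm times (B_null
configurable below B for desk-scale cost); observed performance above the
null's 97.5th percentile counts as above chance.

**Transfer, PheWAS, convergence.** Expressions are dot products of adjusted
population volumes with each signature. Tukey fences (linear-interpolation
quartiles, 1.5·IQR) flag outliers per signature column; a subject flagged on
any column leaves all scans (union rule — one discarded set, matching the
study's single outlier count). Carrier/non-carrier expression differences
use a two-sample bootstrap mean test with the null enforced by recentering
both groups on the pooled mean; the replicate default is 10,000 with 1,000
available via configuration (the source reports both). PheWAS correlates
each expression with each phenotype on pairwise-complete cases, treating
binary and ordinal phenotypes as numeric scores; phenotypes with fewer than
10 complete pairs are untestable and excluded from multiplicity counts.
Two-sided p-values come from the t distribution (df = n−2); Bonferroni uses
α divided by the testable count, BH-FDR runs within each CNV's scan (so
Bonferroni hits are always a subset of FDR hits). Profile similarity
between CNVs is the Pearson correlation of their per-phenotype r vectors,
with significance by phenotype-label permutation because the P entries are
mutually dependent. `condition_out` regresses each expression column on
the other seven (OLS with intercept) to isolate CNV-unique associations;
note the residual of column j is orthogonal to the *original* other
columns, so a second application is not a no-op. The convergence report
pairs the 28 off-diagonal |r| values of the volumetric and phenotypic
similarity matrices, computes Lin's concordance between them and counts
pairs where phenotypic similarity wins.

## The synthetic-data generator

The generator's defaults are the study conditions: clinical group sizes
(24, 15, 112, 146, 80, 69, 69, 19 carriers; 312 controls — 534 carriers in
total), population carrier counts (12, 14, 117, 155, 4, 7, 5, 47 against
38,731 non-carriers), a 7-network parcellation on a single sphere, and an
11-category phenome.

*Atlas.* Parcel centroids form a Fibonacci lattice on the unit sphere;
network labels come from nearest-of-K random seed directions (contiguous
patches), with a greedy repair guaranteeing non-empty networks. A single
sphere (no hemispheres or medial wall) suffices because the statistics
under test do not depend on bilateral surface topology.

*Effect maps.* Each deletion map is a sum of von-Mises-Fisher-like Gaussian
bumps (default 6 bumps, concentration 10 — smooth enough that the spin
null is meaningfully exercised), multiplied by log-normal per-network gains
(SD 0.5) so effects concentrate in some networks, then centered and
unit-normalized. The duplication map is the exact mixture
`−ρ·β_del + √(1−ρ²)·β_⊥` with a smooth orthogonal map, so the planted
mirror anti-correlation equals −ρ exactly (default ρ = 0.5 per locus,
matching the reported mirror strength scale). `orthogonalize_loci` removes
cross-locus map correlations entirely when a controlled near-orthogonal
condition is needed.

*Subjects.* Every subject carries a latent expression
`t_ik = u_ik + θ_k·1[carrier of k]`, `u_ik ~ N(0, latent_sd²)`, and
volumes are `baseline + site offset + confound loadings +
σ·(√p·t_i·β + ε)`. Two deliberate choices:

- θ is the root-mean-square regional shift in noise-SD units (the √p factor
  compensates for unit-norm maps): with θ = 1 a typical affected region
  shifts by about one noise SD, per-region Cohen's d maps correlate > 0.9
  with the planted map at n = 50/150, and mean |d| is linear in θ.
- `latent_sd = 0.2` plants inter-individual variation along the signature
  directions at 20% of the carrier shift. This keeps classification honest
  (Bayes-imperfect, out-of-bag MCC spreads over θ rather than saturating)
  and — critically — makes phenome couplings detectable population-wide:
  phenotypes couple to the latent expressions `t` (the unambiguous ground
  truth for recovery tests), not to carrier status alone, so a PheWAS over
  thousands of non-carriers has signal, as in the real population cohort.

*Phenome.* `y = t·γ + ε` with coupling rows
`γ_k ∝ c·shared + (1−c)·independent`, rescaled to a configured row norm
(default 6, giving typical planted phenotype correlations near 0.1 — the
scale at which a 4,000-subject scan yields tens of Bonferroni hits);
`c = pheno_convergence` controls cross-CNV profile convergence
monotonically. 25% of phenotypes are binarized at a random quantile
(prevalence 0.2–0.8), 15% binned into 4 ordinal levels; missingness is
completely at random (default 5%) because the downstream
pairwise-complete-correlation contract assumes no informative missingness.
The generator does not model voxel data, genotypes, scanner physics, or
informative missingness — so passing tests certify the statistics, not
robustness to those real-data complications. No quantitative phenome noise
model is available from the motivating study; coupling strengths are free
simulator parameters, not estimates of real effect sizes.

## Problem sizes and numerical choices

Desk-scale defaults (chosen once for minutes-scale runtime while preserving
the imbalance structure): 100 regions, full clinical design, N = 4,000
population subjects, 200 phenotypes, B = 25 bootstraps, 199 spin/profile
permutations. Calibration tests use 40 regions (ensemble null), 200 × 199
repeats (spin), 500 × 999 (bootstrap test), 50 × 8 scans (FWER). The
headline divergence/convergence experiment uses θ = 1.5 and 600 phenotypes:
estimated signatures carry cross-talk (estimation error plus
whitening-attenuated projections onto other loci's maps), which gives
*null* phenome profiles a genuine, structured similarity floor; the
stronger planted effect shrinks both noise floors so that the comparison
between volumetric and phenotypic similarity is decided by the planted
structure rather than by the floors.

Other fixed choices: covariances use the n divisor (maximum-likelihood
form) in the discriminant machinery, Cohen's d and z-scoring use n−1, Lin's
concordance uses n — each follows the dominant convention for that
statistic, stated here to remove ambiguity. PCA/LDA embedding signs are
fixed by making each loading vector's largest-magnitude entry positive.
The multiclass embedding returns min(2, classes−1) dimensions and raises
only when the between-class scatter is exactly degenerate. Permutation
p-values always include the +1 correction, so their floor is 1/(n_perm+1).
Pipeline stages derive their seeds from the master seed through named
`SeedSequence` spawns; identical configurations produce digest-identical
artifacts (floats serialized at 12 significant digits).

## Known limitations

- The bootstrap mean test is mildly anti-conservative at extreme group-size
  imbalance (measured type-I ≈ 0.06 at n = 50/500, α = 0.05).
- Expression cross-talk means a CNV's PheWAS profile partially reflects
  other loci's couplings; `condition_out` mitigates but does not remove
  this (its residuals are orthogonal to the other original columns only).
- Site handling is fixed-effect; a random-factor (REML) site model is out
  of scope, as are raw-image preprocessing, CNV calling and phenotype
  curation from raw population-cohort fields.
- Signature recovery saturates near |corr(W, β)| ≈ 0.8 at the clinical
  sample sizes (p = 100, n ≈ 200–460): the residual is dataset-level
  covariance estimation error, which bagging cannot average away.
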