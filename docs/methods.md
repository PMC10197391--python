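# Methods

This note documents the statistical machinery in `landgen`: what each stage
computes, the modeling choices that were genuinely open and how they were
pinned, the numerical details, and what the synthetic-data tests do and do
not demonstrate about real data.

## Genotypes and filtering

Genotypes are diploid biallelic alternate-allele dosages in {0, 1, 2} with
−1 for missing calls, read from VCF via cyvcf2. Multi-allelic records are
dropped (counted), half-calls become missing (counted). Site filters mirror
the common VCFtools invocation: QUAL ≥ 30, minor-allele frequency ≥ 0.01
computed on non-missing calls, and call rate ≥ 0.7 ("max-missing 0.7" in
that tool's convention is a *minimum* call-rate). Attrition per filter is
reported, and removing every locus is an error, not a silent empty result.

## Diversity statistics

Per population, over loci with at least one called genotype:

- **H<sub>O</sub>**: heterozygous calls / called genotypes, averaged over
  loci.
- **H<sub>E</sub>** (unbiased): per locus (n_g/(n_g−1))(1 − p² − q²) with
  n_g the called gene copies, averaged over loci. The small-sample
  correction matters at 4–5 individuals per population.
- **π**: identical per-site formula, reported separately; it is nucleotide
  diversity *at SNP sites only* and is not comparable to π computed over
  full loci including invariant sites.
- **F<sub>IS</sub>** = 1 − H̄<sub>O</sub>/H̄<sub>E</sub>, the ratio of
  multilocus means (the convention of standard population-genetics
  software); flagged undefined when H̄<sub>E</sub> = 0.

The H<sub>O</sub>-vs-H<sub>E</sub> check pools genotype calls across loci
within a population and compares observed heterozygotes with the
Hardy–Weinberg expectation on a two-cell het/hom partition (1 df). The
expectation uses Levene's unbiased form 2pqn·2n/(2n−1): with p estimated
from the same sample, the naive 2pqn is biased low, and over thousands of
pooled loci that bias alone rejects the null essentially always. With the
correction, the test holds its nominal size on inbreeding-free simulations.
Note the pooled statistic is a diagnostic, not an exact test: correlations
among loci within individuals are ignored.

## Pairwise FST

Two-population Weir & Cockerham (1984) variance components a (among
populations), b (among individuals within populations), c (within
individuals), computed per locus on pairwise-complete calls; loci where
either population has no called genotypes, or with fewer than 3 genotypes
total, are skipped. Two aggregates are reported because the literature is
split: the **weighted ratio** Σa/Σ(a+b+c) (default, the VCFtools/
`weighted` convention) and the mean of per-locus ratios. Negative estimates
are retained, not clamped — clamping biases downstream matrix regressions —
and flagged on the matrix container. Estimates are clamped to [−1, 1]
only against floating-point noise.

## Distances

- **Straight-line**: planar Euclidean on projected x/y, or haversine with
  Earth radius 6371 km for lon/lat input (both exposed; planar is the
  default for the synthetic grids, great-circle is appropriate for real
  lon/lat coordinates).
- **Environmental**: per variable, |x_i − x_j| between population values.
- **Resistance surface**: habitat suitability s ∈ [0, 1] maps to per-cell
  conductance. Whether good habitat should be conductive is a modeling
  choice with no single right answer; the default is conductance =
  max(s, ε) (the circuit-theory tool convention for habitat data), the
  alternative resistance = 1 − s + ε is exposed by flag. ε = 10⁻³ keeps
  zero-suitability cells traversable but costly. Both transforms are
  monotone in s, so they rank cells identically; they differ in profile.
- **Least-cost distance**: Dijkstra on the 8-neighbor grid graph; the edge
  cost between adjacent cells is the arithmetic mean of the two cell
  resistances × cell size × √2 for diagonal moves. The arithmetic-mean and
  √2 conventions are pinned choices (grids only say "8-neighbor").
- **Circuit distance**: effective resistance on the same grid with edge
  conductance = mean cell conductance / move-length factor. One node is
  grounded, the reduced Laplacian is factorized once (sparse LU), and one
  solve per source population gives all pairwise R_ij =
  (e_i − e_j)ᵀ L_g⁻¹ (e_i − e_j); grounding at the target and injecting
  unit current at the source is algebraically the same computation. The
  dense pseudoinverse appears only as a test oracle. Populations snap to
  the nearest valid cell (ties row-major).

The 500 m analysis cell is a parameter, not a constant.

## Mantel, partial Mantel, RCM

Spearman is the default statistic (rank-transform the off-diagonal vectors,
then product-moment correlation); Pearson is exposed. The permutation null
relabels the *genetic* matrix (simultaneous row/column permutation) and the
two-sided p carries the add-one correction p = (1 + #{|r*| ≥ |r|})/(B + 1),
so p ≥ 1/(B+1) by construction. At n ≤ 7 an exact mode enumerates all n!
relabelings. The partial statistic is the first-order partial correlation
of the (rank) off-diagonal vectors; its null permutes raw labels of the
genetic matrix and recomputes the full statistic each draw — a pinned
choice (residual-permutation variants exist and differ slightly).
Degenerate inputs (zero off-diagonal variance, perfectly collinear control)
yield flagged undefined results, never silent zeros; note that controlling
a predictor for itself is 0/0, not 0.

RCM evaluates, for every unordered pair of candidate matrices,
R<sub>PM</sub>(G, A | B) and R<sub>PM</sub>(G, B | A); the antisymmetric
difference matrix D summarizes which hypothesis survives the other's
control. Eleven candidates (3 geographic + 8 environmental) give 55
reciprocal models / 110 partial tests.

## GDM

Site pairs: one row per unordered population pair; response = pairwise
F<sub>ST</sub> with negatives clamped to 0 and both d and μ clamped to
[10⁻⁶, 1 − 10⁻⁶] inside the deviance; weights 1. Each predictor gets 3
I-spline basis functions of spline order 3 with knots at the min/median/max
of the observed values (pooled site values for environmental predictors,
pairwise distances for the geographic predictor, which enters splined
directly on the distance). The basis uses the cumulative-B-spline identity
I_j = Σ_{m≥j} B_m, giving functions that are exactly 0 at the predictor
minimum, exactly 1 at the maximum, non-decreasing, and constant beyond the
knot span (flat extrapolation). The response is not rescaled beyond
clamping.

Fitting minimizes the continuous-response binomial deviance
2Σw[d log(d/μ) + (1−d) log((1−d)/(1−μ))] for μ = 1 − exp(−η) by IRLS with a
non-negative least-squares inner step (intercept included in the cone, so
μ ≥ 0 always); convergence when the deviance changes by < 10⁻⁶, cap 100
iterations, non-convergence returned with a flag. The null deviance uses
the closed-form optimum μ = weighted mean of d. Predictor importance is the
fitted spline height Σ_s β_ks (each basis function reaches 1), reported raw
and as percent of total. Permutation-based GDM predictor p-values are
deliberately not implemented; the importance ranking and deviance explained
are the supported outputs.

## MLPE

y = β₀ + β₁x + Zu + e over the m = n(n−1)/2 pairs, Z the pair→population
incidence (two ones per row), u ~ N(0, σ_u²I), e ~ N(0, σ_e²I). Full ML
(not REML, so AICs are comparable across fixed-effect candidates): β and
σ_e² are profiled out and the ratio λ = σ_u²/σ_e² is optimized on
log λ ∈ [−25, 10] (bounded Brent); a one-time eigendecomposition of ZZᵀ
(cached per n) turns every likelihood evaluation into diagonal algebra.
The equivalent corMLPE correlation ρ = σ_u²/(σ_u²+σ_e²) is reported, and
optimizer-at-bound fits are flagged. AIC = −2ℓ + 2k with k = 4 (β₀, β₁, two
variances). For ranking, each candidate predictor's off-diagonals are
z-scored (the response stays raw); failed fits are listed with their error,
not dropped.

## Genomic offset

For each grid cell, offset = 1 − exp(−Σ_k |f_k(x_k^fut) − f_k(x_k^cur)|)
over the model's climate predictors; the geographic term is zero because
location is unchanged. GCM ensembles are averaged cellwise on the raw
climate scale *before* transformation, with nodata propagating. Future
values beyond the fitted knot span extrapolate flat (monotone splines are
constant outside their span); the count of such cells is logged. Because
the η-scale vs dissimilarity-scale choice for mapping is not canonical,
both layers are emitted (dissimilarity is the headline). Offsets are
guaranteed in [0, 1), exactly 0 wherever future equals current, and
monotone in each predictor's displacement.

## Synthetic landscapes

The generator emulates a range-wide amphibian RAD-seq design: defaults 21
populations × 5 individuals (≈ the ~4.5/population of the motivating
design), 5000 SNPs, a 100×100 grid of 500 m cells, ~10% missing calls,
QUAL ~ U(25, 60) so the quality filter has work to do, and Wright's F =
0.35 so F<sub>IS</sub> estimates have a realistic known target.

Environmental layers are oriented planar gradients plus seeded
Gaussian-smoothed noise, standardized to unit variance (so phi_env is in
SD units); suitability is a logistic transform of a fixed linear
combination, strictly inside (0, 1). Population allele frequencies follow
a logit-scale Gaussian process: per locus, an ancestral logit uniform on
(logit 0.1, logit 0.9) plus a multivariate-normal deviation with covariance
σ² exp(−d_geo/φ_geo − d_env/φ_env) (jitter 10⁻⁸ before Cholesky;
frequencies clipped to [10⁻³, 1−10⁻³]). The product-exponential form makes
IBD and IBE independently tunable — φ_geo → ∞ gives pure IBE, and
`env_driver` restricts d_env to a single named variable for targeted
recovery tests. Defaults σ² = 3.0, φ_geo = 15 km, φ_env = 2 SD were chosen
once so that realized pairwise F<sub>ST</sub> falls inside the 0.02–0.6
band typical of range-wide amphibian SNP studies (realized ≈ 0.07–0.35,
mean ≈ 0.29). Genotypes are drawn with P(het) = 2pq(1−F), homozygotes
absorbing the remainder. The "future climate" perturbation is a
deterministic west-east-graded shift of alternating sign across layers,
±0.45–1.05 SD.

What the generator does **not** emulate: linkage disequilibrium (loci are
independent), genealogical/coalescent noise (allele frequencies are the GP
draw, not a drift realization), sequencing-depth-dependent genotyping
error, range expansion or any demographic history, and spatially
autocorrelated missingness. Passing recovery tests therefore shows the
inference chain is correct *given* exchangeable-locus data with the stated
covariance structure — not that it is robust to LD pruning choices or
demographic confounding in real datasets.

## Problem sizes and determinism

All randomness descends from a single seed through named substreams, so
identical config + seed reproduces byte-identical outputs (checksummed in
the run manifest). The acceptance script runs the headline pipeline at
21 × 5 × 2000 loci on a 64×64 raster with 199 RCM permutations, 999
permutations for the headline Mantel test and the 1000-replicate size
calibration, 50-case distance oracles, 100-case estimator oracles, and
20-seed (100 for the MLPE slope) recovery suites; the full script runs in
well under a minute on one core. Test-suite simulations are scaled to the
smallest sizes at which the checked property is still sharp (e.g. 5000
loci where a ±0.03 F<sub>IS</sub> tolerance demands it, 400 where bounds
are all that is asserted).

## Known limitations

- The pooled HW diagnostic ignores inter-locus correlation within
  individuals; its p-values are approximate for organisms with few, long
  chromosomes.
- Partial-Mantel permutation p-values are anti-conservative under strong
  spatial autocorrelation of both matrices; RCM is interpreted through the
  sign/magnitude of the reciprocal differences, not through those p-values.
- GDM importance is spline height, which conflates effect size with
  predictor range coverage; correlated predictors share height in
  unidentifiable ways (as in any GDM).
- MLPE is single-predictor by design (ranking, not multiple regression).
- Raster I/O is ESRI ASCII grid only; inputs are assumed co-registered
  (no reprojection/resampling).
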