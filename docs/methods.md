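# Methods

## Response transform and redundancy analysis

The community matrix holds non-negative abundances of S species at n sites.
Before ordination it is transformed (configurable via `RunConfig.transform`):

* `hellinger` (default): y'ᵢⱼ = sqrt(yᵢⱼ / yᵢ·). The Hellinger transform
  makes abundance data suitable for a Euclidean/linear method and
  down-weights the double-zero problem. Sites with zero total are left as
  all-zero rows and a warning is raised; they carry no compositional
  information, and the package deliberately does not drop or impute them.
* `presence_absence`: yᵢⱼ → 1{yᵢⱼ > 0}.
* `none`: raw abundances.

All modes end with column centring. The canonical R² of an RDA of the
centred response Yc on a predictor block X is

    R² = ‖P_X Yc‖²_F / ‖Yc‖²_F

with P_X the orthogonal projector onto the column space of the centred
(and standardized) X. Implementation: predictors are mean-centred, scaled
to unit variance (harmless — R² is scale-invariant — but better
conditioned), and reduced to an orthonormal basis by SVD with the usual
relative rank tolerance. Rank-deficient blocks (duplicated PCNMs, collinear
PCA axes) are therefore handled by projecting onto the column space, and
the *effective rank* is what enters the adjustment below. A model is
rejected as saturated when n ≤ rank + 1.

## Variation partitioning

With A = adjR²(Y~X), C = adjR²(Y~W), T = adjR²(Y~X∪W) and the Ezekiel
adjustment adjR² = 1 − (1 − R²)(n − 1)/(n − m − 1), the fractions are

    [a] = T − C,  [b] = A + C − T,  [c] = T − A,  [d] = 1 − T.

They sum to one by construction. [a] and [c] can be slightly negative
through the adjustment; they are *flagged, never clamped* — clamping would
silently break the conservation identity the tests rely on. m = 0 (empty
block) leaves R² unadjusted, so a partition against an empty block
degrades gracefully. The implementation was cross-checked against the
standard R implementation of this construction (vegan 2.7-1) on a fixed
12×5 fixture; agreement is ~1e-13 on all fractions, and those values are
frozen in the test suite.

For the cascade and the null model the predictor blocks are constant while
the response changes hundreds of times, so the orthonormal bases of X, W
and X∪W are factored once and each re-partition costs two matrix products
(`ordination._Bases`).

## Spatial filters (PCNM)

Distances are Euclidean for planar coordinates and great-circle (haversine,
Earth radius 6371.0088 km) for longitude/latitude. The truncation distance
defaults to the longest edge of a minimum spanning tree of the distance
graph — the smallest threshold that keeps the neighbour graph connected;
with tied edges the multiset of MST edge weights is unique, so the value is
deterministic. Distances above t are replaced by 4t, the matrix is
Gower-centred (−½ J D∘D J), and eigenvectors with eigenvalue >
1e-9 × λ_max are kept, each scaled to norm sqrt(λ). (The common R
implementation scales to unit norm instead; R² and every downstream result
are invariant to column scaling and sign, which the tests assert
explicitly.) Only positive-eigenvalue filters are produced — broad- to
fine-scale spatial patterns suited to modelling positive spatial
autocorrelation.

## Predictor reduction

1. **CV screening.** CV = 100·sd/|mean| (sample sd, ddof = 1). Variables
   with CV < 40 % (uninformative along the gradient) or CV > 80 %
   (zero-inflated, suggesting a sampling artefact) are dropped; boundary
   values are kept, matching the strict inequalities of the rule. A
   numerically zero mean gives CV = +∞ and drops on the high side; |mean|
   is used so the screen is indifferent to a variable's sign convention.
2. **Forward selection.** Greedy inclusion of the candidate with the
   largest canonical-R² increment. Each step is tested by permuting the
   rows of the response residuals given the already-selected block; the
   permutation statistic is the **maximum increment over the remaining
   candidates**, so the test accounts for selecting the best of many and
   the first step is an exactly calibrated α-level test (on pure-noise
   candidates the first-variable selection rate equals α; the suite checks
   the exact binomial interval at α = 0.05 over 200 runs). Selection stops
   when p > α, when the cumulative adjusted R² would exceed the global
   model's adjusted R² (double stopping — applied from the second step
   onward, because a one-variable model cannot overfit past a ceiling
   estimated with every candidate in it, and applying it at step 1 would
   deflate the test's size below α), or when candidates are exhausted.
3. **PCA retention.** Correlation-matrix PCA (the battery mixes units) of
   the selected variables, keeping the smallest k axes whose cumulative
   explained variance reaches the threshold (default 0.90).

Pipeline order is screen → forward-select raw variables → PCA on the
selected set → axes into the partition; the spatial side forward-selects
PCNM filters directly. Selection happens once, on the full community, and
the resulting blocks are frozen for all removal analyses (re-selecting
inside the cascade would confound predictor churn with species loss).

## Removal cascade and ΔR²

Species are ranked rarest → commonest by total abundance (ties: occupancy,
then label — fully deterministic; occupancy ranking is selectable). Step s
removes the first s species of the ranking (or its reversal), re-applies
the transform to the reduced matrix (site totals change under Hellinger),
and re-partitions; the cascade stops at floor(0.5 × S) removals. The
summary statistic defaults to

    ΔR² = explained_total(step 0) − explained_total(final)

which is positive when removal hurt the model. The literal residual-change
reading (frac_d before − after) is exposed as `component="frac_d"` and has
the opposite sign; both are serialized, as are per-component variants.

## Stratified null model

Species are binned into `null_nstrata` (default 4) quantile strata of
log10(total abundance + 1). Each replicate may first draw a stratified
subsample (default: the full community), then removes half of its species
*randomly but proportionally across strata* (largest-remainder allocation,
uniform within stratum), so each null removal preserves the community's
relative-abundance mix — the stated purpose of stratification. ΔR² is
recorded per replicate; replicate r uses an RNG stream spawned from
(seed, r), making the distribution reproducible and order-independent.
Degenerate replicates are redrawn at most 10 times. The p-value is
add-one: p = (1 + #{|δ| ≥ |observed|}) / (nrep + 1) (two-sided default;
one-sided forms available), so nrep = 999 gives min p = 0.001.

Design note: with the default full-richness subsample, a plain uniform
removal would ignore the strata entirely; the proportional allocation is
what makes the null "stratified" in a meaningful sense, and it also bounds
how many same-stratum dominants one replicate can lose, which stabilizes
the upper tail.

## Synthetic metacommunities

The generator emulates a single-campaign stream-survey design: ~10²
sites, several dozen species with strongly right-skewed abundances, and a
large, internally correlated habitat battery.

* **Sites**: uniform in the unit square, or Thomas-like clusters (parents +
  Gaussian offspring, sd 0.05).
* **Gradients**: n_latent Gaussian-kernel random fields (length scale 0.25
  in unit-square units) mixed with white noise by `spatial_share`;
  observed variables are sparse linear mixtures plus noise, rescaled to
  log-uniform spreads and means so realized CVs span ~3–300 % and the CV
  screen has real work to do.
* **Species**: env-driven species follow Gaussian niche curves
  μᵢₛ = Aᵢ exp(−Σ_g (z_gs − o_ig)²/(2 b_ig²)) on the latent gradients;
  space-driven species get an independent autocorrelated log-intensity
  field; the rest are flat noise. Maxima Aᵢ are lognormal with
  σ_logN = 1.5 (top-5 of 100 species hold ≈ 40 % of individuals — strongly
  right-skewed, though short of single-species dominance), counts are
  Poisson by default with a negative-binomial option for overdispersed
  data. One master seed spawns fixed per-component streams, so each module
  can be regenerated independently.

Named scenarios: `env_only`, `space_only`, `mixed` (60 % env / 20 % space,
signal tied to the common species), `exchangeable` (i.i.d. species, no
signal — the null testbed), `common_signal`.

Known mismatches with real data, and hence the limits of what passing
tests show: niche responses are unimodal while RDA is linear, so even
noiseless env-only scenarios cap [a] well below 1; there is no species
interaction, no temporal turnover, and observed variables are linear in
the latent gradients. The generator validates *method* behaviour
(calibration, recovery, direction of effects), not field effect sizes.

## Test problem sizes and numerical choices

The stochastic suite runs at sizes chosen to make each Monte-Carlo check
sharp but cheap: recovery and cascade-asymmetry checks use 80–100 sites and
30–40 species over 100 seeds; calibration checks use 199 permutations or
null replicates per run (the add-one p-value grid then contains α = 0.05
exactly). The null-model type-I check runs on the raw abundance scale,
where i.i.d. species columns are exactly exchangeable — the Hellinger
transform couples columns through site totals and makes ordered-removal
statistics slightly anti-conservative even without signal. The power check
(signal confined to the five most abundant species) uses σ_logN = 2.0:
the common-removal effect is a dominance effect, and in more even
communities random partial signal loss approaches the ordered removal, so
detection necessarily drops.

Other fixed choices: label joins are case-sensitive after whitespace
stripping; missing environmental cells are an error (no imputation rule is
assumed); coincident sites are an error (no silent jitter); MST ties break
lexicographically; eigenvector signs are arbitrary and all downstream
quantities are sign-invariant; all tolerances in the tests are stated at
the call site (1e-10 conservation, 1e-8 against oracles, binomial 95 %
intervals for rates).
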