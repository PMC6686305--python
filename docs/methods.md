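# Methods

## Data model

The unit of analysis is a species × year matrix of breeding densities
(territories ≡ breeding pairs per 10 ha) from a fixed census plot, with
S ≥ 2 species and T ≥ 2 years (the synthetic generator enforces T ≥ 10,
the minimum series length of the study design it emulates). Densities are
stored per 10 ha regardless of plot size; plot size enters only as a
meta-regression covariate. Species recorded as breeding but too scarce to
census ("tracing species", `+` in source tables) are flagged per cell and
imputed with fixed constants by body-size class: 0.1 pairs/10 ha
(woodpeckers and smaller passerines), 0.05 (smaller raptors and corvids),
0.004 (large raptors). The size class is a user-supplied column of the
guild table, since the constants are defined by class, not by species.
All-zero rows/columns are kept in storage but stripped (with a warning)
before any null-model run: a fixed marginal of zero admits only the zero
row, which freezes the fixed-fixed algorithms without affecting the
indices on the remaining cells.

## Binary null models

Indices: CHECKER (species pairs never co-occurring), C-score (mean
checkerboard units per pair, CU = (r_i − S_ij)(r_j − S_ij)), V-ratio
(variance of yearly species totals over the sum of per-species occurrence
variances; population variances, i.e. divide by T — the ratio is
scale-consistent either way). High CHECKER/C-score ⇒ segregation; low
V-ratio ⇒ segregation.

SIM2 redraws each species' r_i presences uniformly over the T years,
independently across species (row sums fixed, columns equiprobable).
SIM9 fixes both marginals and samples the ensemble with a sequential-swap
Markov chain: each step draws a uniformly random (row pair, column pair)
2×2 sub-matrix and swaps it only if it is a checkerboard. Because the
proposal is symmetric and non-checkerboard draws are no-ops, the chain is
the *trial-swap* chain, whose stationary distribution is exactly uniform
over the fixed-marginal ensemble; emitting one sample every
`10·max(S,T) + 1` *attempted* swaps (after a 30,000-attempt burn-in, one
long chain per matrix) therefore needs no separate bias correction. The
cadence is odd deliberately: on a two-state 2×2 ensemble every proposal
is an accepted swap, and an even cadence would revisit the same state by
parity. Matrices with no swappable checkerboard yield a frozen chain: the
input is returned for every sample with a warning. Ensemble uniformity is
verified against exhaustive enumeration of a 3×3 fixed-marginal state
space (100,000 samples, within 3 SE per state).

Significance is empirical and two-tailed with the add-one Monte-Carlo
convention: p_high = (1 + #{null ≥ obs})/(n_sim + 1), p_low analogous
(ties count as extreme in both tails, so p > 0 always and
p_low + p_high ≥ 1), p_two = min(1, 2·min(p_low, p_high)). Defaults:
n_sim = 10,000, α = 0.05. The doubling construction is our choice; the
method description we follow defines only the tail frequencies.
V-ratio × SIM9 is rejected: fixed marginals do not randomize the marginal
variances.

## Quantitative null models

CA_ST and AA_ST count, over all C(S,2)·C(T,2) species-pair × year-pair
2×2 sub-matrices, those with opposing (d_i·d_j < 0) and concordant
(d_i·d_j > 0) abundance differences; ties contribute to neither count and
the denominator includes all sub-matrices, so CA_ST + AA_ST ≤ 1. MA is
the n-community Morisita–Horn similarity of the year samples computed
from within-year relative abundances; it is invariant to rescaling any
year column and reduces to the classical two-community Morisita–Horn at
T = 2 (verified by hand computation and a brute-force oracle).

IT fills the matrix one individual at a time with cell probability
∝ R_i·C_j restricted to unsaturated rows and columns. Because the
available cells always form the product set (unsaturated rows ×
unsaturated columns), the sampling factorizes into independent row and
column draws, and a dead-end is impossible whenever ΣR = ΣC — the
restart budget in the interface is never consumed. The fill-path
distribution is verified against exact recursive enumeration on 2×2
totals. IA drops all N individuals independently with probabilities
R_i·C_j/N², fixing only the grand total; cell expectations N·R_iC_j/N²
are verified against the multinomial closed form. Tests are one-tailed
per direction (both tails always reported): CA high ⇒ segregation,
AA high ⇒ aggregation, MA low ⇒ segregation.

Density matrices are bridged to the individual-based algorithms by
`counts = round(density × scale_factor)`, default factor 250 so the
smallest tracing constant (0.004) maps to one individual; any positive
density rounding to zero is an error advising a larger factor. The factor
is exposed because rounding choices are a genuine sensitivity in this
bridge; on integer synthetic counts a factor of 1 is exact.

## Synthetic data

The generator emulates territory-mapping census series:
λ_it = exp(μ_i + driver_it + ε_it), N_it ~ Poisson(λ_it), with
μ_i ~ N(mu_mean, mu_sd²) giving right-skewed (lognormal) species
densities, ε_it ~ N(0, noise_sd²) idiosyncratic species-year noise, and a
regime-dependent driver term built from yearly environmental pulses
u_t ~ N(0, env_sd²):

- **correlated** — one shared driver, all species load +1 (climate-driven
  positive covariance);
- **compensatory** — within each guild, species are *paired* and each pair
  shares its own driver with opposite-signed loadings (an odd leftover
  species is neutral). A single shared driver with balanced ± loadings
  cannot produce the negative mean within-guild correlation that defines
  compensation: same-signed lognormal pairs correlate at +1 while
  opposite-signed pairs are bounded near −0.4, so the guild mean comes
  out positive. Pair-level drivers are the minimal structure that
  delivers the required signature;
- **random** — no driver (independent species).

Defaults (S = 20, T = 30, mu_mean = 0, mu_sd = 1, env_sd = 0.5,
loading = 1, noise_sd = 0.25, 2 tracing species present each year with
probability 0.3) were fixed once as a realistic texture for census data.
`calibrated_config()` (mu_mean = 0.2, mu_sd = 1.4) reproduces the ≈38%
zero-cell fraction of the study matrices. An auxiliary
resource-partition generator (N_2t = max(0, K − N_1t) + noise per species
pair) provides hard compensatory structure for stress tests.
`generate_outcome_table` draws dataset covariates over realistic observed
ranges and outcomes from a known baseline-category logit, for validating
the meta-regression layer.

What the generator does *not* emulate: temporal autocorrelation
(site-fidelity persistence of territories), demographic structure,
detection error, and trends. The persistence point matters for
interpretation: real territory counts are smoother year-to-year than
Poisson, which is precisely the feature that lets abundance nulls report
aggregation on real data (see limitations).

## Hypothesis-test calibration and power

Type-I behaviour is assessed on 500 random-regime matrices (S = 20,
T = 30, no tracing species, n_sim = 1,000, α = 0.05). All five binary
combinations and IA×AA_ST reject within [0.01, 0.12]. The CA_ST and MA
combinations are *intrinsically liberal* on Poisson-lognormal data
(0.4–0.85 rejection, toward segregation), and IT×AA_ST marginally so
(≈0.13): species-year noise is overdispersed relative to the multinomial
allocation the IT/IA ensembles assume, which inflates observed
discordance and deflates compositional similarity. This is a property of
the methods, not of the implementation: matrices drawn from the IT null
itself and tested against IT reject at 0.06–0.11 for all three indices,
while even IA-drawn data tested against IA reject CA_ST at ≈0.48 (a
plug-in-margin bias intrinsic to IA). The corresponding acceptance tests
are left failing by design, as a documented negative result.

Directional power is assessed at a declared *strong-signal* condition
(env_sd = 1.0, noise_sd = 0.1, i.e. driver-to-noise variance 100:1):
200 matrices per regime, quantitative suite, n_sim = 500. Compensatory
dynamics yield far more segregation than aggregation; correlated dynamics
the reverse. The strong-signal condition is necessary for the correlated
direction, because a homogeneous multiplicative shared response is
absorbed almost exactly by the fixed year totals of IT/IA — at default
noise levels the residual overdispersion masks the positive-covariation
signal entirely. This margin-absorption effect is worth knowing before
interpreting aggregation frequencies from abundance nulls.

## Bayesian meta-regression

Outcomes are modelled one predictor at a time (the characteristics are
intercorrelated and the categories unbalanced): binomial logit GLMs for
dichotomous codings (the success category and an optional contrast
category are configurable, since which two categories each dichotomy
contrasts is a per-analysis choice), baseline-category multinomial logit
GLMs for trichotomous codings (baseline = random), and binomial GLMMs
with per-dataset random intercepts for guild-level records. Predictors
are z-standardized internally; slopes are reported on both scales.

Priors: independent Cauchy(0, 25) on fixed effects and half-Cauchy(25)
on the random-intercept SD — the weakly informative choice that keeps
completely separated data estimable; the source protocol names a single
half-Cauchy scale of 25 without fixing its placement, so both placements
share the configurable `prior_scale`. Sampling is blockwise adaptive
random-walk Metropolis (proposal scales tuned to ≈30% acceptance during
burn-in and then frozen); equivalence with the original Gibbs/MH tooling
is asserted at the level of posterior summaries, not sampler mechanics —
posterior means match IRLS maximum-likelihood fits within 0.1 on
well-separated data under near-flat priors. Chains are reproducible
bit-for-bit given (seed, chain config).

Chain presets: desk scale 200,000 iterations / 10,000 burn-in / thin 95
(2,000 retained, seconds per fit); published scale 10,000,000 / 10,000 /
5,000 (1,998 retained); long 100,000,000 / 10,000 / 50,000 for poorly
mixing chains. Diagnostics report lag-1 autocorrelation of the retained
samples and flag |ac| ≥ 0.05 with the advice to lengthen the chain.

DIC = mean posterior deviance + p_D with p_D = mean deviance − deviance
at the posterior mean (random effects included in the deviance
conditioning). We report `delta_dic = DIC_null − DIC_model`, so positive
values favour the predictor model; significance is declared when the 95%
HPD interval (shortest sorted-window interval) of a *slope* excludes
zero — intercepts are excluded from that rule. HPD coverage of a known
slope is ≈95% over repeated synthetic tables when compared on the raw
predictor scale (the generator standardizes over datasets while a
contrast-restricted fit standardizes over its subset, so standardized
scales differ by construction).

## Problem sizes and numerical choices

The test suite and acceptance script run everything at reduced but
statistically meaningful sizes chosen as a deliberate desk-scale
protocol: oracle equivalence on 200 random matrices up to 6×6 (exact);
marginal conservation over 1,000 replicates per algorithm (exact);
ensemble uniformity over 100,000 swap samples; type-I over 500 matrices
at n_sim = 1,000; power over 200 matrices per regime at n_sim = 500;
coverage over 100 tables with 1,000 retained samples per fit. The
full-protocol defaults (n_sim = 10,000, the 10M-iteration chain) remain
the package defaults. Monte-Carlo comparisons in tests use 3-SE bands.

Tie handling is strict everywhere (equal abundances contribute to
neither CA nor AA; null values equal to the observed count as extreme in
both tails). Swap kernels and the IT fill run under numba with
explicitly seeded generators; batch index evaluation is vectorized and
chunked to bound memory on large matrices.

## Known limitations

- The CA_ST/MA liberality above means "segregation" calls from abundance
  nulls on noisy count data should be read with care; the binary suite is
  well calibrated and is the safer default for type-I-sensitive claims.
- The sequential-swap chain is a single long chain; independent restarts
  are not implemented (the uniform stationary distribution makes them
  unnecessary for correctness, only for convergence diagnostics).
- The GLMM uses a single random-intercept term; crossed or nested
  structures are out of scope.
- Guild-level analyses run the quantitative grid only; guild sub-matrices
  with fewer than two species or two occupied years are skipped and
  logged, and the eligibility log is part of the output.
- The multinomial GLMM (trichotomous guild outcomes with random
  intercepts) is not implemented; guild-level models are binomial.
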