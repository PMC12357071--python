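# Methods

## The model

Let `Y_i` be the tobacco retailer count in census tract `i` with
population `P_i` and covariate row `x_i`. The marginal model is negative
binomial (NB2):

    Y_i ~ NB(mu_i, theta),   Var(Y_i) = mu_i + mu_i^2 / theta
    log mu_i = x_i' beta + log(P_i / 1000)

The offset makes `exp(intercept)` a density per 1000 residents, so the
model is a rate model for tobacco retailer density (TRD). Percentage
covariates (% below poverty, % African American, % Hispanic, % Asian) are
divided by 10 before fitting, so each slope is the change in mean log TRD
per 10-percentage-point increase; `exp(beta)` is the corresponding
multiplicative change in density. Rurality enters as dummies for
Micropolitan, Small Town and Rural against the Metropolitan baseline
(RUCA primary codes collapsed 1–3 / 4–6 / 7–9 / 10). % White is excluded
by default: it is near-collinear with the other composition shares.

Point estimates are independence maximum likelihood: IRLS for `beta`
(working weight `mu/(1 + mu/theta)`), alternating with a bounded-Brent
profile maximization for `theta` on the log scale (search window
`log theta` in [-7, 16]). A step-halving guard (up to 40 halvings) keeps
the log-likelihood non-decreasing; convergence is declared when the
largest coefficient change drops below 1e-8, with a 100-iteration cap and
an explicit `converged` flag. Rank-deficient designs are rejected up
front, naming the collinear columns via pivoted QR.

## Spatial inference

Tract-level residual density is spatially autocorrelated even after
conditioning on covariates. Rather than re-estimating `beta` under a
working correlation (full GEE iteration), the package keeps the
independence point estimates and adjusts only the covariance — a
sandwich `A^{-1} B A^{-1}` with `A = X'WX` the model information.

**Middle matrix.** `B` estimates `Cov(X's)` for the score residuals
`s_i = (y_i - mu_i)/(1 + mu_i/theta)`. The diagonal uses the observed
`s_i^2` (robust to variance misspecification; with an identity working
correlation the estimator reduces exactly to HC0). The off-diagonal
entries are `sigma_i sigma_j R_ij`, where `sigma_i^2` is the model-scale
score variance (the IRLS weight, rescaled by the empirical Pearson
dispersion) and `R` the fitted working correlation. Using the raw
products `s_i s_j R_ij` instead would be wrong: `E[s_i s_j]` already
equals the covariance, so multiplying by `R_ij` counts the correlation
twice and the "adjustment" collapses back to HC0 — we measured exactly
that (coverage stuck at the independence level) before adopting the
model-scale form. A non-positive-semidefinite middle matrix (possible
after the moment fit) is projected to the nearest PSD matrix by
eigenvalue clipping, with a log note.

**Working correlation.** Two kernels are available on tract centroids or
contiguity:

* exponential: `R_ij = sill * exp(-d_ij / phi)` for `i != j`. The sill
  in [0, 1) is essential: for an NB model with a latent multiplicative
  random effect the short-range residual correlation is
  `sigma_b^2 * mu^2 / V`, far below 1, and a pure `exp(-d/phi)` cannot
  fit the empirical decay.
* adjacency indicator: `R_ij = rho` for queen-contiguity neighbors,
  truncated to [0, 1).

Parameters are fitted by pair-count-weighted least squares to empirical
correlations of centered Pearson residuals in 10 distance bins spanning a
quarter of the maximum pairwise distance (bins with fewer than 30 pairs
are dropped; fewer than two usable bins triggers a fallback to the
adjacency kernel with a warning).

**Attenuation correction.** Pearson residuals are `(I - P_Z) eps` with
`P_Z` the orthogonal projection onto the weighted design
`Z = diag(mu/sqrt(V)) X`. When covariates are themselves spatially smooth
(poverty fields, rurality rings, the intercept), that projection absorbs
a large share of the residual correlation — on the default synthetic
scenario roughly half of it. The kernel fit therefore pushes each
candidate correlation matrix through `(I - P_Z) C (I - P_Z)` before
matching the empirical bins, recovering the unattenuated parameters the
sandwich needs. The (sill, phi) pair is only weakly identified
individually on a single dataset — a flatter, longer-range kernel can fit
the bins about as well as a sharper, shorter one — but the fitted
correlation profile, which is what enters `B`, is stable; the
coverage study below is the operative check.

**Validation.** On the default 30×30-lattice scenario (200 replicates),
mean estimates of every coefficient fall within 2 Monte-Carlo SEs of
truth; 95% sandwich intervals achieve 0.925 pooled coverage while
independence-based (HC0) intervals cover 0.829. These numbers are
recomputed, not quoted, by `scripts/acceptance.py` and the test suite.

Wald per-coefficient `z` tests and joint chi-square tests take either
covariance; interaction blocks are screened by their joint sandwich-Wald
test at the 0.05 level.

## Contrasts and effects

Rurality density ratios are exponentiated coefficient differences, with
`Var = var_a + var_b - 2 cov_ab` from the sandwich covariance (the
Metropolitan baseline has coefficient 0). Families of pairwise contrasts
— all C(k,2) pairs among the k levels present in a state, never pooled
across states — get Bonferroni-simultaneous intervals at `alpha/m`. A
level with no tracts yields an "absent" contrast rendered as a dash.
Conditional Appalachia effects are `exp(b_app + b_int * poverty/10)` with
a delta-method (linear-combination) variance. Effect curves evaluate
`exp(beta * (x - ref)/10)` on a grid strictly inside the observed
covariate range, with pointwise bands; the reference value defaults to 0
so the curve reads directly as `exp(beta * x/10)`.

Reconstructed ratios from published coefficient tables (3 printed
decimals) can differ from internally computed ones by up to ±0.01; the
worked-example checks compare at 2 decimals with that tolerance. Two
statements in the source analysis's own text do not match its tables and
are surfaced here without adjudication: an Ohio Appalachia factor
reported as 1.22 where the tabled coefficient gives exp(0.115) = 1.12,
and Hispanic-composition effects described as "lower" density alongside
printed factors of 1.09 and 1.07.

## Descriptives

TRD distributions are summarized by median and IQR (linear interpolation
between order statistics, the common "type 7" quartile rule — no
convention was prescribed), plus an aggregate density
`1000 * sum(counts) / sum(population)`. Marginal correlations use
log(TRD + 0.01); the 0.01 offset guards against log of zero and is used
*only* here, never in model fitting. Correlation p-values use the t
transform with n − 2 degrees of freedom.

## Diagnostics

Deviance residuals are
`sign(y - mu) * sqrt(2[y log(y/mu) - (y + theta) log((y + theta)/(mu + theta))])`
with the `y = 0` limit handled analytically; their squares sum to the
model deviance. Moran's *I* uses queen contiguity, row-standardized, on
deviance residuals by default (the choice of residual is a documented
default, not a prescription). The permutation test is two-sided on |I|
with the +1 Monte-Carlo correction, reproducible given a seed; an
exhaustive mode enumerates all n! relabelings for n ≤ 9. Normal-mode
p-values use the classical randomization moments. Neighborless tracts
are dropped from the statistic with a logged count; zero-variance
residuals are an error.

## Synthetic data

The generator lays unit-square tracts on an `n_x × n_y` lattice:

| parameter | default | meaning |
|---|---|---|
| lattice | 30 × 30 | 900 tracts |
| beta | intercept −0.4; poverty 0.2; Black 0.0; Hispanic 0.05; Asian −0.1; micro 0.2; small town 0.3; rural 0.4 | per-10-point log-TRD scale |
| theta | 5 | NB dispersion |
| spatial_sd | 0.3 | SD of the latent Gaussian field |
| spatial_range | 2.0 | exponential-covariance range, lattice units |
| pop_range | 300–8000 | log-uniform tract populations |

Poverty is a smooth Gaussian field (range 3) pushed through its CDF onto
[0, 60]%; race/ethnicity shares are county-block Dirichlet compositions
(counties are 5×5 tract blocks); rurality is assigned deterministically
by distance from the lattice center (concentric rings), guaranteeing all
four levels except in the `ct_like` scenario, which omits the small-town
ring to exercise absent-level handling; a right-hand block of counties is
flagged Appalachian. Counts are gamma-Poisson draws with mean
`(P/1000) exp(x'beta + b)` where `b` is a zero-mean Gaussian field with
covariance `spatial_sd^2 exp(-d/spatial_range)` (dense Cholesky — exact,
and comfortable for lattices up to 50×50). All randomness flows from one
seeded generator; identical configs give byte-identical output.

Because the random effect is multiplicative, the population-averaged
intercept is the latent one plus `spatial_sd^2 / 2` (the lognormal mean);
slopes are unaffected because covariate fields are drawn independently of
`b`. The truth record carries both `beta` (latent) and `beta_marginal`
(shifted intercept); recovery and coverage checks target the marginal
vector, which is what a marginal NB model estimates.

What the generator does *not* emulate: real state geographies, ACS
covariate marginals and their mutual correlations, retailer-count
heaping, irregular tract shapes and sizes, or edge effects of real
boundaries. Passing tests show the estimators are correct under the
assumed data-generating process, not that any particular real dataset
satisfies those assumptions.

Scenario library: `paperlike` (defaults), `null_spatial`
(`spatial_sd = 0`), `ct_like` (no small-town ring),
`appalachia_interaction` (Appalachia main effect 0.25, poverty-by-
Appalachia interaction −0.15).

## Data handling choices

* The minimum-population filter keeps tracts with population ≥ 100
  (inclusive reading of "minimum").
* RUCA code 99 / missing is treated as unclassifiable; such tracts are
  excluded from models with a logged count.
* Retailer de-duplication merges points within a caller-set radius
  (default 25 m in projected units) that share a normalized source label,
  keeping the lexicographically smallest id — deterministic regardless of
  input order. No radius convention exists for this step; 25 m is a
  conservative same-address merge.
* All point-in-polygon work assumes a single planar CRS supplied by the
  caller; the package performs no reprojection.
* Boundary points are assigned to the first covering tract in sorted
  tract-id order; points in no tract go to an "unassigned" bucket so
  points are always conserved.
* Per-tract retailer counts may be supplied directly in the CSV,
  bypassing point assignment entirely.

## Problem sizes

The validation studies use 200 replicates of the 30×30 lattice for
recovery/coverage, 200 replicates × 999 permutations for Moran
calibration, 100 replicates for range recovery, and 25–100 replicates
for interaction sign recovery — sizes chosen to put Monte-Carlo error
comfortably inside the assertion bands while keeping the full suite
around two minutes.

## Known limitations

* Variance-only adjustment: point estimates are independence-ML, so no
  efficiency is gained from the spatial structure, only honesty of SEs.
* A single (sill, phi) pair summarizes a residual correlation whose
  amplitude actually varies with `mu` across pairs; coverage is nominal
  on average but could drift for extreme density gradients.
* The exponential kernel is isotropic and stationary.
* Bonferroni simultaneous intervals are conservative relative to
  max-|z|-based alternatives.
* Exhaustive Moran enumeration is limited to n ≤ 9.
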