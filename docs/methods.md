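# Methods

## The statistical model

The response for field *i* is the square root of the area-weighted proportion
of weevil-infested tubers,

    y_i = sqrt( (p_edge,i · A_edge,i + p_center,i · A_center,i) / (A_edge,i + A_center,i) ),

transformed *after* weighting (the reverse order differs numerically; the
transform is applied to the final field-level percentage).  All regressions
are ordinary least squares on this scale:

    y_i = β0 + Σ_j β_j x_ij + ε_i,   ε_i ~ N(0, σ²).

Candidate predictors span chemical control, cultural practice, geography,
host cultivar, soil chemistry and landscape composition, plus indicator
terms for the four field observers (data-collection facilitators), which
enter every candidate pool as ordinary competitors.  Encodings: binary
variables are 0/1 with the reference level ("no", "potato", the modal
cultivar) at 0; the observer factor becomes three full-rank indicators
against the first observer; elevation enters as sqrt(elevation); ordinal
counts (e.g. number of hillings) enter numerically.  Interaction terms are
out of scope.

Model comparison uses the Gaussian AIC

    AIC = n ln(RSS/n) + 2K,   K = (#coefficients incl. intercept) + 1,

with the additive constant n(ln 2π + 1) omitted — only differences matter
downstream, and the tests verify the differences agree with the full
log-likelihood version.  K counts the residual variance as a parameter;
this shifts all models of equal size by a shared constant and nothing else.
The small-sample correction 2K(K+1)/(n−K−1) is available behind a
`corrected` flag, since the convention of the original software is unknown;
every downstream stage accepts either flavour.

## Global model: forward walk with a 2.0-AIC tolerance

Starting from the intercept-only model, the variable whose addition lowers
AIC most enters at each step (ties broken by pool order).  The walk
deliberately continues past the AIC minimum: an addition is admitted as long
as the resulting AIC is at most 2.0 above the lowest AIC reached so far
(the running minimum over the whole trajectory).  With tolerance 0 this is
classical forward selection.  Zero-variance candidates (e.g. a month in
which no field was treated) are dropped up front with a warning; candidates
that are collinear with the current model are skipped with a warning.

One behaviour worth knowing: with many truly-null candidates, chance AIC
reductions can extend the walk a few steps beyond what a clean dataset would
give, so the selected count varies around the nominal 17 (roughly 14–21 on
default synthetic data).

## All-subsets averaging

Every non-empty subset of the selected variables is fitted with an
intercept (2^k − 1 models; 17 variables give 131,071).  Fits are solved from
a single precomputed Gram system (X'X, X'y, y'y), batched by subset size,
with a column-normalized Cholesky factorization whose smallest pivot guards
conditioning (pivot < 3e-7 flags a collinear subset).  RSS comes directly
from the factor via ||L⁻¹b||²; an exhaustive independently-coded lstsq
enumeration is the test oracle.  Enumeration refuses more than 20 variables
(2²⁰ ≈ 10⁶ models) unless overridden; in the orchestrated pipeline a longer
selection is truncated to the first 20 variables in entry order — the
forward procedure's own importance ranking — with a warning.

The confidence set keeps models with ΔAIC ≤ 2.0 **inclusive** ("within 2
AIC" read as inclusive).  Akaike weights are exp(−Δ/2) normalized within the
set.  Parameter weights are computed as a ratio of exact float sums
(`math.fsum`) of the unnormalized exp(−Δ/2) masses, so a parameter present
in every model has weight exactly 1.0 in IEEE arithmetic.

For a parameter p with weight w_p: the natural average conditions on the
models containing it, `β̄ = Σ_{i∋p} (w_i/w_p) β̂_i`; its unconditional
standard error pools estimation variance and model-selection spread,

    SE = sqrt( Σ_{i∋p} (w_i/w_p) [ var(β̂_i) + (β̂_i − β̄)² ] ),

with a normal-approximation 95% CI (±1.96·SE); the shrinkage average is
β̄·w_p, used for all predictions.  The shrinkage identity
(shrinkage = natural × w_p) holds bitwise by construction.

## Class comparison

Local and landscape predictors are compared by running the full
build-enumerate-select procedure three times — local-only, landscape-only
and combined pools, each including the observer controls — and weighting the
three class-best models by exp(−ΔAIC/2).  Landscape variables are the three
100-m-radius composition metrics (current-season potato %, previous-season
potato %, storage-unit count); everything else, including perimeter/area
ratio, is local.

## Derived analyses

*Standardized impacts.*  The averaged model is anchored at a baseline field:
sample means for continuous variables, sample modes for binary/ordinal ones
(ties to the lower level), and zero monthly insecticide treatments — the
no-pesticide baseline deliberately overrides the mean rule for treatment
counts, since the two conflict there.  Each variable is perturbed on its own
scale (+1 sample SD continuous, applied on the raw scale and re-encoded;
+1 unit counts/ordinals; the number of hillings −1 unit, the only direction
that keeps predictions within observed bounds; binaries flip away from the
mode) and the impact is reported in percentage points as the difference of
*squared* sqrt-scale predictions — simple squaring, no retransformation bias
correction (an open choice, made for transparency).  Negative sqrt-scale
predictions clamp to zero with a warning.  Because predictions use shrinkage
estimates, impacts of parameters with w_p < 1 are attenuated.

*Insecticide efficacy.*  One joint OLS of the response on the four monthly
treatment counts; constant columns are dropped (rank protection) and
reported as NaN.

*Harvest adaptation.*  Simple regression of harvest day on the averaged
model's back-transformed predicted infestation (df = n − 2, two-sided t
test) — the post-hoc check that farmers expecting more damage harvest
earlier.

## Spatial autocorrelation

Residuals of the best combined model (configurable) are tested with a
binned Moran's I correlogram: half-open 250 m bands (0,250], …, (2750,3000],
planar Euclidean distance, self-pairs excluded.  Expectation under no
autocorrelation is −1/(n−1).  Significance is a two-sided permutation test
with the plus-one rule, p = (1 + #{|I*| ≥ |I|}) / (n_perm + 1); sidedness is
taken on the magnitude of I because the direction was not prespecified.
One set of shuffles scores all bands, so bands share null draws.

## The synthetic-data generator

The generator emulates the *statistical* structure of the 138-field study —
marginal covariate distributions, effect sizes, observer design and spatial
layout — so that the whole pipeline is testable without the (undeposited)
raw records.

- **Covariates** are drawn independently with the published means/SDs/modes.
  Bounded continuous variables use truncated normals whose underlying
  parameters are solved so the *post-truncation* moments match the targets;
  right-skewed non-negative variables (CV > 0.6: chemical fertilizer, soil K
  and P, neighbouring current/previous potato) use moment-matched gammas,
  because a left-truncated normal cannot reach CV near or above 1.  Counts
  are Poisson (truncated above 6); binary and ordinal variables are drawn
  from their published frequencies.  An optional Gaussian-copula correlation
  hook exists for the continuous block; the default is independence because
  only marginal moments were reported.
- **True effects** are the published model-averaged estimates (perimeter/area
  0.519, storage units 0.044, current potato −0.004, previous potato 0.007,
  December/January insecticides −0.054/−0.053, clay 0.005, elevation −0.031
  per sqrt-m, number of hillings 0.127, 2007 rotation −0.096, …), acting on
  the encoded variables; unsupported covariates have effect 0.  Observer
  offsets default to (0, −0.043, −0.070, 0): two observers sit at the
  reference so exactly two non-zero observer effects are estimable.
- **Intercept**: the published intercept is itself a model-averaged estimate
  and does not generate sensible data when combined with the natural
  effects; the generative intercept is instead solved so the expected
  sqrt-scale response at covariate means equals sqrt(0.183), the observed
  mean infestation.
- **Response**: sqrt-scale linear predictor plus N(0, σ) noise, clipped to
  [0, 1] and squared into a field proportion; the edge stratum is inflated
  by 25.1/18.3 and the center deflated by 16.1/18.3 (the observed stratum
  means), renormalized so the area-weighted average recovers the field value
  exactly.  Field areas are gamma with mean 424.6 m², SD 282.4 m²; the edge
  share is Beta with mean ≈ 0.244, the value implied by the three published
  stratum means.
- **Design**: observers are assigned in near-equal blocks (35/35/34/34) and
  each observer's fields form one Gaussian village cluster (SD 300 m,
  centers within 3 km), supporting the 250 m / 3 km correlogram design.
- **Noise calibration**: σ defaults to 0.202, obtained with
  `calibrate_sigma`, which bisects σ until the median best-model R² — the
  R² of the minimum-AIC model along the forward walk, a cheap and nearly
  identical stand-in for the all-subsets best — falls inside the published
  40.2–46.4% variance-explained band.

What the generator does **not** emulate: covariate correlations (e.g.
elevation vs landscape composition), spatial structure in the residuals,
within-field tuber-level sampling of the 40 inspected plants (field-level
proportions are emitted directly), soil texture closure (clay+loam+sand is
not constrained to 100%), and any observer-by-covariate interaction.
Passing tests therefore demonstrate that the *procedures* are correct and
that the study's qualitative conclusions are recoverable under its stated
effect sizes — not that real Andean field data would reproduce them.

## Numerical and design choices

- Plain AIC is the default; AICc behind a flag (convention of the original
  software unknown).
- Confidence-set boundary inclusive; enumeration deterministic (by size,
  then lexicographic), seed-free given the table.
- Ties: forward-selection ties go to the earlier pool entry; baseline mode
  ties go to the lower level.
- Missing values are rejected, never imputed (the study reports no
  missingness handling); proportions are stored in [0, 1], percentages
  divided by 100 at ingest.
- Degenerate inputs raise typed errors: zero total area, σ ≤ 0, unknown
  effect names, rank-deficient designs (with offending columns named),
  n ≤ p, zero RSS (Gaussian AIC undefined), zero-variance Moran inputs.
- Reported problem sizes in the test suite: 20 pipeline replicates at
  n = 138 for the study-level checks; 200 replicates of a 7-covariate
  design for coverage; 100 random instances (p ≤ 10) for the enumeration
  oracle; 25 × 12 band p-values at 999 permutations for the permutation
  null; 40 replicates at 199 permutations for the false-positive rate.

## Known limitations

- With many null candidates the tolerance walk can admit a handful of
  chance variables, so the enumerated set size fluctuates around 17; the
  20-variable enumeration cap then truncates in entry order.
- Model-averaged CIs are normal approximations conditional on the selected
  confidence set; coverage is verified empirically only for parameters with
  w_p ≥ 0.9.
- The class-comparison weight of the combined model fluctuates more than
  the published single realization suggests: with the published landscape
  effect sizes the combined model's AIC advantage over the best local model
  is a noncentral-χ²₃ quantity with λ ≈ 15, whose lower tail dips below the
  "decisive dominance" threshold in roughly a third of replicates.
- Back-transformed impacts use simple squaring; a smearing-type correction
  would shift them slightly upward.
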