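# Methods

## The model

`likertsim` studies what is lost, statistically, when an ordinal k-point
Likert (LKS) response is analysed as if it were continuous. The continuous
benchmark is a **rectified normal (RTN)** variable: a latent normal draw
Z ~ N(μ, σ²) clipped to a finite range,

    X = min(max(Z, lower), upper).

Clipping — as opposed to truncation — leaves point masses P(Z ≤ lower) and
P(Z ≥ upper) *at* the limits. Those masses are the model's floor and ceiling
effects: respondents whose latent intensity exceeds the scale's range pile
up at the extreme response. The truncated normal (renormalized, no boundary
mass) is deliberately not offered as a latent model; it appears only as a
contrast in the documentation of `RTNSpec`.

Defaults fix the latent scale at σ = 1 and the limits at ±2, so a centered
latent variable keeps 95.4% of its mass strictly inside the range
(2Φ(2) − 1 ≈ 0.954). Shifting μ moves mass onto one boundary and skews the
observed distribution, which is how the model represents easy/hard items.

A **k-point Likert variable** is the equal-interval discretization of the
RTN range: cut [lower, upper] into k bins of width (upper − lower)/k and map
bin j to the integer level j ∈ 1..k. Bins are half-open on the left,
(e_{j−1}, e_j] → j, with the lower limit absorbed into level 1. Interior
edges carry zero probability under any continuous latent law, so this
convention is statistically immaterial; fixing it makes `discretize`
deterministic and testable. Level values 1..k are cosmetic — every
downstream statistic (t-test, correlation, standardized effect size) is
location/scale invariant.

All RTN and LKS moments are available in closed form
(`rtn_moments`, `lks_moments`): standard-normal CDF/PDF terms for the
interior plus the boundary masses, and level probabilities

    P(1) = Φ((e_1−μ)/σ),  P(j) = Φ((e_j−μ)/σ) − Φ((e_{j−1}−μ)/σ),
    P(k) = 1 − Φ((e_{k−1}−μ)/σ),

with the boundary masses folded into the extreme levels. Both are verified
against adaptive quadrature (1e−8) and 10⁷-draw Monte Carlo oracles.

## Effect sizes and calibration

Two-group comparisons use the heteroscedasticity-aware standardized mean
difference

    d = (μ₁ − μ₂) / sqrt((n₂σ₁² + n₁σ₂²)/(n₁ + n₂)),

in which each group's variance is weighted by the *other* group's sample
size (with n₁ = n₂ this is the familiar sqrt((σ₁²+σ₂²)/2) pooling). Effect
sizes are always *stated on the RTN scale*: `calibrate_shift` finds the
latent shift δ of group 2 whose RTN-scale d equals the target, by bisection
on an auto-expanding bracket (|f| ≤ 1e−10; the shift→effect-size map is
continuous and strictly increasing, so bisection is robust and
derivative-free). Group 1 sits at latent mean 0 and only group 2 is
shifted; a symmetric ±δ/2 placement would give identical statistics for the
symmetric baseline but is not the default.

The **attenuation ratio** of a Likert type is the LKS-scale d (from exact
LKS moments of the two calibrated groups) divided by the RTN-scale d. It is
computed without simulation noise. Two structural facts the tests assert:
the ratio is increasing in k and nearly constant in the target effect size
(spread < 0.02 over d ∈ [0.1, 0.5]) — discretization loss is a property of
the *scale*, not of the effect being measured. Numerically, the 2-point
ratio is ≈ 0.80 and the 5-, 6-, 7-point ratios exceed 0.95.

## The synthetic-data generator

Multi-item data use an exchangeable latent correlation structure built from
one common and p unique standard normal factors,

    X_j = sqrt(ρ)·C + sqrt(1−ρ)·U_j + μ_j,   ρ ∈ [0, 1],

which is exact at both endpoints (ρ = 1 duplicates a single item without
any special-casing, which a Cholesky construction would need). The stated
pairwise correlations are interpreted as correlations of the *latent*
normals, injected before clipping; clipping and discretization then
attenuate the observable correlations, and that attenuation is itself one
of the quantities under study.

Within a replicate, every variable type is a deterministic view of the same
latent draw (clip → discretize per scheme): a `CoupledDataset`. Coupling
mirrors how a survey instrument would have produced all the views of the
same respondents and removes between-type Monte Carlo noise from type
comparisons.

What the generator does **not** emulate: non-normal latent families,
negative or non-exchangeable correlation structures, item-specific scale
lengths within an instrument, or respondent-level behaviours (acquiescence,
straight-lining). Conclusions from passing tests are therefore statements
about the rectified-normal world; with latent distributions far from
normal the detailed numbers would change even if the qualitative ranking of
scale lengths does not.

## The four experiments

All experiments reject at α = 0.05 two-sided and default to 10,000
replicates, giving a rejection-proportion standard error of at most
sqrt(0.25/10000) = 0.5 percentage points; estimates are reported as
percent ± SE with a normal 95% CI.

1. **Single-response power** (`run_single_response_power`): t-test power per
   (effect size {0, 0.2, 0.5}, per-group n {30, 50, 100, 300, 500}, type
   {RTN, 2..7-point}). The unequal-variance (Welch) t statistic with
   Satterthwaite df is used throughout: the groups genuinely differ in
   variance once the shifted group presses against a boundary, which is also
   why the effect-size definition above is heteroscedasticity-aware. A
   pooled-variance flag exists for sensitivity runs; at these ns the two
   tests are numerically indistinguishable.
2. **Merged scores** (`run_merged_power`): p ∈ {2, 3, 5, 10} items at latent
   ρ ∈ {0, 0.25, 0.5, 0.75, 1}, per-item RTN effect size 0.2, n = 100/group;
   the p columns of one type are summed into a total score and Welch-tested.
   Each Likert cell also reports the per-group n needed to match the
   same-cell RTN power: the pooled merged-score standardized mean
   differences d̂ are recovered from the simulated moments (pooling across
   all replicates, so d̂ is far more precise than the rejection
   proportions), and n_req = ceil(100·(d̂_RTN/d̂_LKS)²) by the
   normal-approximation power inversion.
3. **Correlation preservation** (`run_correlation_similarity`): per
   replicate (n = 200, ρ < 1), the sample correlation matrix A of the
   clipped items and B of their k-point transforms are compared by GFI and
   SRMR; means ± SEs over replicates. Replicates with a constant column, or
   with A = I where GFI's denominator vanishes, are dropped from the
   affected summary and counted.
4. **Regression power** (`run_regression_power`): q ∈ {1, 2, 3, 5, 10}
   explanatory variables, latent exchangeable ρ = 0.2 across all q+1 items,
   n = 200; column 1 (in the response type) is regressed on the rest (in
   the explanatory type, types capped at 5 points) and the overall F-test
   of all slopes is evaluated. Likert-explanatory cells report the total n
   matching the RTN-explanatory power for the same response type, by
   inverting the noncentral-F power function at the cell's mean adjusted R².

### Fit indices

SRMR is the fully specified formula
sqrt(2·Σ_{i}Σ_{j≤i}(a_ij−b_ij)²/(p(p+1))) over the lower triangle including
the (vanishing) diagonal. For GFI = 1 − F(A,B)/F(A,I) the difference
measure F is taken as the squared Frobenius distance over all p² entries,
which makes GFI = 1 iff A = B and GFI(B=I) = 0 exactly. This is the
package's single most uncertain numerical choice: F is not pinned down by
the index's usual presentations, and under the squared-Frobenius form the
per-replicate GFI is a ratio with a random denominator ‖A−I‖² that becomes
heavy-tailed when the true correlation is 0 (the reference matrix is then
itself nearly the identity). GFI output is therefore meaningful as a
relative/ordinal measure — higher k, higher GFI; ρ = 0 markedly lower — and
the test suite treats it that way, while SRMR carries the numeric
reproduction targets.

### Random streams and variance reduction

A single master seed drives everything. Grid cells draw from independent
streams derived via `numpy.random.SeedSequence(seed, spawn_key=(experiment,
cell))`, so results are invariant to cell evaluation order. Two drivers
additionally share **common random numbers across their factor grids**: the
merged driver draws one common and p_max unique factors per replicate and
remixes them per (p, ρ) cell, and the regression driver draws q_max+1
coupled columns and slices the leading q+1 per cell. Marginal cell
distributions are unchanged; monotone patterns across ρ and q are compared
on common draws, where they are far less vulnerable to Monte Carlo
inversions near the power ceiling. Replicates where a test is degenerate
(zero variance in both groups — possible for coarse scales at small n)
count as non-rejections and are tallied in the `n_degenerate` column.

### Required sample size (single response)

`required_n_for_power` inverts the normal-approximation formula
n = ceil(2·(z_{1−α/2} + z_power)²/d²) on the attenuated effect size
(d = es_RTN × ratio); an optional simulation refinement walks the answer by
single steps against simulated power. At RTN effect size 0.1 and 80% power
this gives 1,570 per group for the RTN variable and 2,442 for the 2-point
type; the requirement scales as 1/d², so n·d² is constant across effect
sizes up to integer rounding.

## Problem sizes

The full grids at 10,000 replicates complete in a few minutes on one core
(all kernels are vectorized over replicates, processed in chunks of 2,000
to bound memory). The test suite's reproduction checks run the same grids
at 2,000 replicates and widen tolerances by the corresponding sqrt(5)
factor — every published-value comparison is phrased as ±3 Monte Carlo
standard errors at the replicate count actually run.

## Known limitations

- The rectified-normal latent family is an assumption, not an estimate; see
  the generator section for what it leaves out.
- GFI depends on an under-determined choice of F (above); its absolute
  values are not comparable across implementations.
- Required-n values are normal-approximation inversions (optionally
  simulation-refined); for very coarse scales at small n the t-test's
  discreteness makes "the" required n fuzzy at the ±1–2% level.
- Exchangeable correlation only, ρ ∈ [0, 1]; arbitrary correlation matrices
  and negative ρ are out of scope.
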