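# Methods

This note records the statistical model, the estimators, the numerical
choices and the limits of what the test battery demonstrates.

## Data model and conventions

Subjects carry an observation window `(entry, exit]`, an event indicator and
an optional covariate vector. The at-risk convention is
`Y_i(t) = 1 iff entry_i < t <= exit_i`: a case is at risk at its own failure
time, so the partial-likelihood denominator at t_k contains the case. With
`entry = 0` this is the usual time-on-study convention; positive entries
express delayed entry (age-scale analyses), and every risk-set computation,
fit and influence function respects it.

Case times are assumed untied. Ties are a hard error by default; an opt-in
deterministic jitter (rank-preserving, relative magnitude 1e-9, tied cases
ordered by id) is available for real data where clock resolution creates
ties. Missing covariates are first-class — an NCC data file only carries Z
for sampled subjects — and any estimator that would read a missing value
raises instead of silently dropping the subject, since silent dropping
changes the design.

## Generative model

The simulator draws (Z₁, Z₂) bivariate standard normal with correlation ρ
(default 0.25), survival times by inversion from the Cox model with constant
baseline hazard λ₀ = −log(0.95)/10 per time unit (5% cumulative incidence at
the study end τ = 10 for a referent subject), log-relative hazards
β = (0.5, 0.9), and independent exponential dropout with rate
α = −log(1 − p_c)/τ so that exactly a fraction p_c drops out by τ
(default p_c = 0.2); administrative censoring applies at τ. Latent (T, C)
are retained in the simulator output for distributional oracle tests but are
never written to cohort files.

The defaults are the package's reference study conditions; all reported
benchmark quantities in the test battery are computed under them at
N = 5000. What the simulator does **not** emulate: covariate-dependent
censoring, non-constant baselines, time-varying covariates, additional
matching criteria (strata), or measurement error in Z. Passing tests
therefore demonstrate correctness of the sampling/weighting/estimation
machinery under clean proportional hazards, not robustness to violations of
it.

## Sampling designs

Both designs draw m distinct controls uniformly at each case time using a
permutation draw from the ascending-sorted pool, so results are reproducible
across platforms given a seed. If a pool holds fewer than m candidates the
whole pool is taken and the shortfall is recorded; inclusion probabilities
then use the realized per-time draw count m_k.

The coupled sampler draws the standard matched set first, drops the members
already present in the modified design's control history, and replaces them
with fresh draws from the modified pool excluding the retained ones. "Already
selected" is interpreted as membership in the modified history (which by
induction contains every standard control drawn so far) — the only reading
that yields s_std ⊆ s_mod. The coupled standard component is marginally the
exact standard design (checked by a contingency test against the pure
sampler); the coupled modified component is provided for paired design
comparison, with the pure modified sampler as the reference implementation.

## Inclusion probabilities

For a non-case i, π_i = 1 − ∏_{k: R_k ∋ i} (1 − m_k/r_k) over the case times
where i is at risk, with realized pool sizes r_k (standard) or r_k\*
(modified). Cases have π = 1 by convention and zero design covariance. The
joint probability of two non-cases uses the unified complement form

    π_ij = π_i + π_j − 1 + ∏_k f_k,

with f_k = 1 − 2m/r_k + m(m−1)/{r_k(r_k−1)} when both are at risk at t_k,
f_k = 1 − m/r_k when exactly one is, and f_k = 1 otherwise. This single
formula reproduces both the shared-time expression and the independence
product π_i π_j for subjects with disjoint at-risk spans, and matches the
exhaustive enumeration oracle to 1e-12 on cohorts whose pool sizes are
path-independent.

Two caveats are intrinsic to the modified design and documented rather than
resolved. First, r_k\* varies across sampling paths (it depends on which
earlier controls are still at risk); following the estimator's definition,
π\* is computed from the r_k\* realized in the observed sample, and the
enumeration oracle quantifies the (small) gap between that conditional
quantity and the unconditional marginal on test cohorts. Second, uniformity
of the sampling distribution over outcomes holds exactly only conditionally
on the realized pool sizes.

### Vectorized pair products

The design-variance term needs π_ij for every sampled non-case pair —
O(n²) pairs each with a product over up to D case times. Because each
subject's at-risk case times form one contiguous run in the sorted schedule
(interval censoring), every per-pair product collapses to prefix-sum
differences of log-factors over the overlap of two index ranges, giving an
O(n² + D) kernel. Exact zero factors (a pool taken whole forces π = 1) are
clamped to a log value whose exponential underflows to exactly 0, which the
per-case analysis shows reproduces the correct limits (σ = 0 wherever an
index is included with certainty). The pair matrix is assembled as
M_ij = w_i w_j (1 − π_i π_j / π_ij), algebraically identical to
w_ij w_i w_j σ_ij but free of cancellation-prone intermediate σ values; a
scalar exact routine covers degenerate small-pool cases and serves as the
unit-test oracle for the kernel.

## Estimation

Both β optimizers are Newton–Raphson with analytic score and information,
initialization β = 0, convergence at max|score| < 1e-8, at most 50
iterations and up to 20 step-halvings per iteration (the likelihoods are
concave; step-halving only engages near degenerate configurations).
Candidate steps that push |β| beyond 50 are halved, and persistent failure
to increase the likelihood raises a separation error. A non-identifiable
direction (zero score component) leaves β at its initial value. Risk-set
sums use two sorted suffix-sum structures (by exit and by entry), so a fit
costs O((n + D) log n) per Newton iteration including delayed entry.

The weighted Breslow increments dΛ̂₀(t_k) = 1/S⁽⁰⁾(t_k; β̂) solve their
estimating equation exactly at each case time; cumulative hazards over
`(τ₀, τ₁]` are sums of increments with τ₀ < t_k ≤ τ₁. The Langholz–Borgan
estimator needs only the cohort's follow-up skeleton outside the sample
(risk-set sizes), never unsampled covariates. A subject sampled as a control
who later fails enters the pooled estimator once, as a case with weight 1.

## Influence functions and variance

Writing S⁽ʳ⁾ for the weighted at-risk sums at the converged fit,
Z̄(t) = S⁽¹⁾/S⁽⁰⁾ and dΛ(t) = 1/S⁽⁰⁾(t), each sampled subject's
*complete-data* influence is

    IF_i(β̂)  = I⁻¹ [ δ_i{Z_i − Z̄(t_i)} − e^{η_i} Σ_k Y_i(t_k){Z_i − Z̄(t_k)} dΛ(t_k) ],

with I the total observed pseudo-information (the derivative of the weighted
score), and

    IF_i(dΛ̂(t)) = {dN_i(t) − e^{η_i} Y_i(t) dΛ(t)}/S⁽⁰⁾(t) − dΛ(t) Z̄(t)′ IF_i(β̂).

The sampling weight deliberately does **not** enter the influence itself: it
enters the variance once, as the Horvitz–Thompson estimation factor. With
this convention the weighted sum of influences is exactly the score (zero at
convergence), the full-cohort limit is the classical Cox influence (the
estimator reproduces lifelines' robust sandwich variance to ~7 significant
digits), and the design term is correctly scaled — a double-weighted variant
was measured to overestimate the design variance by more than an order of
magnitude against a resampling calibration. The two-component estimator is

    v̂ar = N/(N−1) Σ_{i∈s} w_i IF_i IF_i′ + Σ_{i,j∈s} w_ij w_i w_j IF_i IF_j′ σ_ij,

restricted in the second term to non-case pairs with σ_ij ≠ 0 (an exact
restriction, not an approximation). Because the influences here are
unnormalized (total-information inverse), the expression estimates
var(θ̂) directly. The conditional estimator instead uses the inverse
observed information of the stratified likelihood, with a Taylor-series
variance (increment variances dΛ_k² plus a propagated-β gradient term) for
its Langholz–Borgan baseline hazard. Interval CIs for Λ₀ are plain Wald on
the hazard scale.

On a fixed cohort the mean of the design component over repeated
modified-design samplings tracks the empirical sampling variance of β̂₁
within a few percent at m = 5 (N = 2000, 500 draws). At m = 1–2 the
agreement degrades to ~15–20% because the linearization error of the
estimator itself grows with the weights — a property of the method, not of
the implementation; the calibration test is therefore run at m = 5.

## Simulation study driver

Each replicate generates a cohort, fits the full-cohort model, draws both
designs with coupled randomness and evaluates all requested
estimator/design/m cells. Replicate b of scenario s uses the independent
substream `SeedSequence([master, s, b])`, so any cell is reproducible in
isolation. Metrics follow the paired definitions: design bias
DB = |mean(θ̂_ncc) − mean(θ̂_full)|, design variance
DV = var(θ̂_ncc) − var(θ̂_full) with divisor B−1 (reported as-is when
slightly negative at small B, since truncation would bias the ratio), the
efficiency ratio R = DV_std/DV_mod, empirical SD, mean estimated SE and
Wald coverage against the generative truth.

The benchmark battery runs the 20%-censoring scenario at N = 5000 with
B = 1000 replicates (fitting per replicate the full cohort, the conditional
estimator on the standard design at m = 1, and the IPW estimator on the
modified design at m = 5): at B = 300 the √DV statistic still carries
~8–10% Monte Carlo error, which is material against the quantities being
checked, while B = 1000 brings it to ~5%. The standalone reproduction
script uses B = 300 replicates for the two full-cohort quantities it
reports, whose Monte Carlo error is far smaller.

## Known limitations

* Additional matching criteria (e.g. sex or ethnicity strata),
  counter-matching and quota sampling are out of scope.
* Time-varying covariates, competing risks and interval censoring are not
  modeled.
* Variances of derived quantities (absolute risk, survival probability) are
  not implemented, though the interval-hazard influence functions provide
  the needed building block.
* The delete-one jackknife overestimates the Cox estimator's variance at
  small n (by ~25% at n = 50, shrinking as 1/n); comparisons of the
  influence-function variance against the jackknife are only tight for
  cohorts with several hundred subjects.
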