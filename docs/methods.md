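# Methods

## Model

The observation model is Gaussian on the log scale: y_kt, the log annual
emission intensity (kg/km²) of county k in period t, has mean
x_kt'β + U_kt γ + ψ_kt and variance σ².  U_kt is the urban-expansion
measure (ULDI or luminosity density); x_kt collects an intercept,
greenness, available construction land, a coastal dummy and two
log-distances.  Interactions (e.g. ULDI × coastal) are ordinary product
columns appended by the design builder.

The latent field ψ is a K-vector per period.  Spatially it follows the
Leroux CAR prior with unscaled precision Q(ρ, W) = diag(1 − ρ + ρw+) − ρW
on the binary rook-contiguity matrix W; temporally the vectors follow a
first-order autoregression with coefficient λ and innovation covariance
τ²Q⁻¹.  The full conditional of one site is
N(ρ Σ_{l~k} ψ_l / (1 − ρ + ρw_k+), τ² / (1 − ρ + ρw_k+)) — the defining
property of the Leroux form.  Some presentations print the precision as
τ²(L_W − W); that form both double-counts τ² against the covariance
τ²Ω⁻¹ and drops ρ from the W term, so the package uses the unique matrix
whose conditionals are the ones above: full precision Q(ρ, W)/τ².

Assumptions worth stating: the likelihood is Gaussian and homoscedastic
across counties and periods; W is binary (no distance-decay or
row-standardised weights); ψ is not sum-to-zero constrained, because the
Leroux prior is proper for ρ < 1 — the cost is weak identifiability
between the intercept and the field mean, visible as slow intercept
mixing, accepted and documented rather than constrained away.

## Contiguity

Two polygons are neighbours iff their boundaries intersect with positive
length (rook rule); corner touches do not count.  Degree-0 units
(islands) are permitted with a warning — the conditional collapses to
N(0, τ²/(1−ρ)) and the joint stays proper for ρ < 1; ρ = 1 is refused.
Adjacency can equally be supplied as an edge-list CSV.

## Sampler

A Gibbs cycle per iteration:

1. (β, γ): conjugate Gaussian given ψ and σ².
2. ψ_t for t = 1..T: Gaussian block with precision (1/σ²)I + c_t(1/τ²)Q,
   c_t = 1 + λ²·1[t<T], solved in the eigenbasis of the graph Laplacian
   L = diag(w+) − W.  Because Q(ρ) = (1−ρ)I + ρL shares L's eigenvectors,
   one eigendecomposition serves every (ρ, t): each update is two K×K
   matrix–vector products.
3. σ² ~ IG(a + KT/2, b + RSS/2).
4. τ² ~ IG(a + KT/2, b + S/2), S the sum of Q-quadratic forms of the
   AR(1) innovations.
5. λ: closed-form Gaussian full conditional truncated to (0, 1).
6. ρ: random-walk Metropolis on the logit scale.  The quadratic form
   decomposes as (1−ρ)s_I + ρs_L, and log det Q(ρ) = Σ log(1−ρ+ρe_k)
   from the cached Laplacian eigenvalues, so each proposal is O(K).  The
   proposal scale adapts toward ~0.4 acceptance in 50-iteration windows
   during burn-in only, then freezes (preserving detailed balance);
   post-adaptation acceptance outside [0.1, 0.6] raises a warning.

Initialisation: least squares for the coefficients, ψ = 0, the residual
variance split evenly between σ² and τ², ρ = λ = 0.5.  Hard invariants —
ρ, λ ∈ (0,1) and positive variances — are asserted every iteration.
Chain defaults mirror the study protocol (2 chains × 70,000 iterations,
20,000 burn-in, thin 10); tests and examples use reduced runs.

The sampler was validated two independent ways: with (ρ, λ, τ², σ²)
pinned, the joint posterior of (coefficients, ψ) is Gaussian in closed
form and the Gibbs means and covariances match it; and a from-scratch
single-site sampler (dense conditionals, griddy-Gibbs ρ) targets the
same posterior as the block implementation on small lattices.

## Priors

Coefficients get N(0, 10⁶) defaults.  Both variances get IG(0.001, 0.001),
which is close to flat on log σ².  This default is deliberate: a
fixed-scale choice such as IG(1, 0.01) has prior median ≈0.014 and
almost no mass below 0.002, and when the observation variance is weakly
identified — a nugget of order 10⁻³ beneath a latent field with variance
of order 10⁻¹ — that prior visibly biases σ² upward and breaks nominal
interval coverage.  With the scale-free default the replicated recovery
study attains nominal coverage for γ, ρ, λ, τ² and σ².  ρ and λ are
Uniform(0, 1) throughout.

## DIC

Deviance is conditional on the latent field:
D = −2 log N(y | Xβ + Uγ + ψ, σ²I), DIC = mean(D) + p_D with
p_D = mean(D) − D(posterior means).  Conditioning on ψ (rather than
marginalising) matches common practice for this model family; with a
small σ² the Gaussian density exceeds one and DIC is legitimately
negative.  The log-likelihood at the posterior means is reported
alongside.

## Synthetic data

The generator draws ψ exactly (eigen-factorisation of Q, chained AR(1)),
then covariates, then noise, from three independent sub-streams of one
root seed, so the panel is a pure function of (W, parameters, seed) and
adding covariates never perturbs the field.  Defaults emulate the study
conditions: K = 85 on a 5 × 17 rook lattice, T = 5 periods, γ = 1.5,
ρ = λ = 0.9 (the high-dependence regime), τ² = 0.3, σ² = 0.002; ULDI is
positive with a per-county base near 0.08 trending up ≈60% across the
window; greenness and construction-land densities vary per county-year;
the coastal dummy (~41% of units) and the two log-distances are constant
in time.  What the generator does *not* emulate: real county geometries
(areas are uniform), spatially clustered covariates, measurement error in
the areal-weighting step, and any misalignment between the assumed and
true dependence structure — so passing recovery tests demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to their violation.

## Areal integration

Grid-to-county transfer treats cell values as extensive: a cell's value
is split among intersecting counties in proportion to overlap area, which
conserves mass exactly under any tiling (asserted to 1e−9 relative).
Intensive surfaces are refused rather than silently averaged.  Monthly
county totals are summed to annual totals with an explicit
missing-month error.  Indicators follow their definitions: log intensity
(natural log by default, base configurable; zero totals raise unless a
floor intensity is supplied), ULDI = urban land area / county area,
LD = total luminosity / county area.  No reprojection is performed —
geometries must arrive in one equal-area CRS.

## Numerical and test-design choices

- Log-determinants and field draws run through one symmetric
  eigendecomposition of L; no per-iteration factorisations.
- The simulator's distributional check compares the sample covariance of
  10⁵ replicate fields against the analytic Kronecker-form covariance on
  a 2 × 3 lattice at ρ = 0.9, λ = 0.8.  These settings come from a power
  analysis: the worst entry's 5% tolerance band is then ≈4.5 Monte-Carlo
  standard errors wide, so the check has negligible false-failure
  probability, whereas weak-dependence settings leave the smallest
  covariance entries statistically indistinguishable at that sample size.
- Conjugate-limit checks bound deviations by Monte-Carlo standard errors
  computed from measured effective sample sizes, since the intercept
  mixes slowly (see above).
- Percent-effect translation defaults to the linear rule 100·γ·Δ with
  one-decimal rounding — the convention the reported tables use — with
  the exact 100·(exp(γΔ)−1) available via `scale="exp"`.
- Temporal-trend curves are the cross-county 25/50/75-percentiles of the
  per-cell posterior median of ψ (intercept optionally added); the
  spatial-pattern export time-averages the ψ medians (last-year variant
  via flag).  Both are definitional choices where the reporting
  convention is ambiguous.
- Significance flags follow the credible-interval rule: a parameter is
  flagged iff its [2.5%, 97.5%] interval excludes zero.

## Limitations

Gaussian likelihood only (no Poisson/binomial variants); no missing-data
handling; binary contiguity only; the "likelihood value" printed by some
reports of this model family has no standard definition — the package
exposes the log-likelihood at posterior means without claiming
equivalence.  Reduced-length chains in tests and examples (5,000
iterations) are adequate for the synthetic conditions but real analyses
should use the full protocol defaults.
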