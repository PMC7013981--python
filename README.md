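# stcar

Bayesian spatio-temporal modelling of county-level pollutant-emission
intensity against urban-expansion indicators.

## The problem

Regional studies of urbanization and air quality work with *areal panels*:
for each of K counties and a handful of time points, an emission intensity
(annual pollutant mass per km², analysed on the log scale) and a set of
urban-development covariates — the urban land development intensity (ULDI,
the fraction of a county covered by urban construction land), a night-light
luminosity density (LD), greenness, available construction land, and
locational variables.  Naïve regression on such data ignores two strong
dependence structures: neighbouring counties pollute alike, and each
county's emissions evolve smoothly in time.  Both inflate false confidence
in covariate effects.

`stcar` implements the standard remedy — a Gaussian panel model with a
latent spatio-temporal field carrying a Leroux conditional-autoregressive
(LCAR) prior in space and a first-order autoregressive process in time —
together with everything around it: contiguity-weight construction from
polygons, areal-weighted transfer of gridded emission / land-use /
night-light surfaces onto counties, a synthetic-panel generator with known
ground truth, MCMC inference with DIC model comparison, and the reporting
conventions (credible-interval tables, percent-effect translations,
temporal-trend quantiles, spatial-pattern maps).

## The model

For county k = 1..K and period t = 1..T,

    y_kt ~ N(x_kt' β + U_kt γ + ψ_kt, σ²)
    ψ_1 ~ N(0, τ² Q(ρ, W)⁻¹)
    ψ_t | ψ_{t-1} ~ N(λ ψ_{t-1}, τ² Q(ρ, W)⁻¹)       t = 2..T

where W is the binary rook-contiguity matrix, w+ its row sums, and

    Q(ρ, W) = diag(1 − ρ + ρ w+) − ρ W

is the Leroux precision: ρ = 0 gives independent effects, ρ → 1 the
intrinsic CAR.  λ ∈ (0,1) measures temporal persistence.  Priors are
diffuse normal on (β, γ), vague inverse-gamma on (σ², τ²) and Uniform(0,1)
on (ρ, λ).  Inference is a Gibbs cycle with conjugate updates for
coefficients, per-period latent blocks (solved in the eigenbasis of the
graph Laplacian), variances and λ (truncated normal), plus a logit-scale
random-walk Metropolis step for ρ with an eigenvalue-cached
log-determinant.

## Worked example

```sh
python examples/02_fit_synthetic.py
```

fits a reduced chain (2 × 5000 iterations) to a synthetic 85-county,
5-period panel generated at γ = 1.5, ρ = 0.9, λ = 0.9, τ² = 0.3,
σ² = 0.002 and prints

```
           median  lower  upper  significant
parameter
intercept   5.085  4.698  5.556         True
uldi        1.902  1.044  2.618         True
green      -0.031 -0.100  0.037        False
tau2        0.273  0.235  0.318         True
sigma2      0.002  0.000  0.007        False
rho         0.915  0.826  0.970         True
lambda      0.908  0.828  0.980         True

DIC -1238.9 (p_D 287.8), log-likelihood at means 907.3
rho acceptance rates: [0.43, 0.4]
```

Every 95% credible interval covers its true value; `uldi` is the
urban-expansion coefficient γ.  Because the response is a log intensity, a
coefficient translates to a percent effect: `effect_percent(1.574, 0.05)`
→ `7.9`, i.e. a +0.05 ULDI increase is associated with ≈7.9% higher
emissions.  The negative DIC is normal for a Gaussian likelihood with a
small residual variance.  The other examples cover panel simulation
(`01`), grid-to-county areal weighting (`03`) and effect translation
(`04`).  A thin CLI (`stcar simulate | aggregate | fit | report`) wraps
the same pipeline for shell use.

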