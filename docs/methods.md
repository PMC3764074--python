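# Methods

## The two-stage model

Stage one treats square-root-transformed annual-average concentrations at
N\* monitors and N subject locations as one Gaussian field

    [X; X*] = [T; T*] α + [η; η*],   cov(η_joint) = τ² I + σ² ρ(d/φ),

where T\* = R\*H are k partial-least-squares scores of the standardized
geographic covariates R\* (H maximizes covariance with X\*), α are mean
coefficients (an intercept is always included), τ² is the nugget
(non-spatial residual variance), σ² the partial sill (spatially structured
variance) and φ the range in km. Supported correlation families:
exponential ρ(h) = e^(−h); spherical and cubic, both reaching the sill
exactly at d = φ. Exposure predictions at unmonitored sites are conditional
means T α̂ + C(θ̂) Σ(θ̂)⁻¹ (X\* − T\*α̂), with no nugget in the
cross-covariance C, back-transformed as W = max(pred, 0)² (negatives are
floored and counted; no lognormal-style variance correction is applied).

Stage two is OLS of the outcome on W and adjustment covariates Z,
E(Y) = β₀ + Wβₓ + Zβ_z, with classical homoskedastic SEs ("naive"
inference) and normal 95% intervals using z = 1.96.

## Estimation choices

* **PLS**: univariate-response NIPALS (via scikit-learn, `scale=False` on
  covariates already standardized by the preprocessing stage). The k = 1
  weight direction is pinned in tests to the cross-covariance vector, which
  is algorithm-independent. The collapsed weight vector m satisfies
  R m + intercept ≡ PLS-only fitted values.
* **Profile maximum likelihood**: α is profiled out by GLS at each θ; the
  profile objective is minimized over (log τ², log σ², log φ) by L-BFGS-B
  started from the best points of a 3 × 3 × 3 grid built from the OLS
  residual variance and the maximum inter-site distance (objective
  tolerance 1e-10; covariance factorizations get an escalating jitter of
  1e-10–1e-7 of the mean diagonal before failing). Plain ML, not REML.
* **Parameter covariance**: the joint covariance of (α̂, log θ̂) is the
  pseudo-inverse of a central-difference Hessian of the joint negative
  log-likelihood at the optimum. Eigenvalues of the covariance are clipped
  to [0, 25]: directions the data do not constrain (e.g. log σ² when
  σ̂² sits on the zero boundary) would otherwise produce unbounded
  bootstrap draws; a cap of variance 25 on the log scale leaves identified
  directions untouched.
* **Cross-validation**: random folds balanced to within one monitor;
  screening decisions, standardization statistics, PLS weights and kriging
  parameters are all re-estimated inside each training fold. Metrics are
  computed on the sqrt (modeling) scale; R² uses the n-denominator variance
  and is floored at 0, so R² = 1 − RMSEP²/var(obs) exactly when no flooring
  occurs. Selection minimizes RMSEP with ties broken toward fewer
  components, then the simpler method.
* **Distance preprocessing**: distances are floored at 1 m before the log
  (the data contain exact zeros); truncation at 10 km with natural log is
  the default and 25 km with log₁₀ is available — both conventions appear
  in practice and the choice is recorded in the preprocessing report.
  Compiled minimum-distance variables are built from raw (pre-log) member
  distances and then face the same screens as original covariates.

## Parameter bootstrap and SIMEX

Replicate j draws (i) one joint field realization at monitors + subjects
from the fitted stage-one model at the point estimates, (ii) outcomes from
the fitted stage-two model with residual SD σ̂_resid taken from the naive
health fit, and (iii) parameters (α_j, θ_j) from N((α̂, log θ̂), λ·Cov) —
drawn as mean + √λ·L·z so the λ = 0 run is exactly the point estimate while
consuming an identical random stream. Subject exposures are re-predicted by
kriging the *simulated* monitor data with the *drawn* parameters and the
health model is re-fit, giving draws β̂ₓ,j. Bias_λ = mean_λ − mean_0 over
paired replicates (common random numbers, so the bias contrast is not
dominated by Monte Carlo noise), the corrected estimate is
β̂ₓ − Bias_λ, and the bootstrap SE is the replicate SD. Replicates whose
covariance factorization fails are dropped and counted; more than 5% drops
aborts. SIMEX evaluates Bias_λ on a shared-stream λ grid
({0, 0.5, 1, 1.5, 2} by default) and fits a quadratic in λ; the fitted
value at λ = 1 refines the direct bias estimate.

Default B = 1000 with Monte Carlo errors reported alongside every
bootstrap quantity (MC-SE of the SE is SE/√(2(B−1)), about 2% at B = 1000);
B is a configuration knob for larger runs.

## Synthetic studies

The generator emulates a national-scale study on a 4000 km projected
square: monitors (default 288) on a jittered stratified grid ("evenly
dispersed"), subjects (default 500) mostly in six tight urban clusters
(SD 30 km, clustered fraction 0.9). Geographic covariates are loadings on
two smooth latent fields (sums of low-frequency plane waves) plus
independent noise (SD 0.5), with five positive heavy-tailed
"distance-like" columns for the preprocessing stage; the exposure mean is
linear in the latent factors (α = (0.70, 0.10, 0.05) on the sqrt scale,
matching sulfur-like concentration magnitudes), so the PLS assumption holds
by construction unless the `misspecified` toggle adds a quadratic factor
term. Spatial residual regimes: sulfur-like θ = (0.0007, 0.0251, 2145 km,
exponential; strongly spatial), elemental-carbon-like
θ = (0.0074, 0.0025, 413 km; weakly spatial), and a nugget-only scenario
(0.0099, 0, –). Outcomes use β = (0.68, 0.055, 0.02) and noise SD 0.19,
matching a subclinical-atherosclerosis-style outcome scale.

What the generator does *not* emulate: real GIS feature geometry (roads,
NDVI imagery), non-Gaussian concentration fields, preferential monitor
siting, shared confounding between exposure and outcome, and missing-data
structure beyond complete-case handling. Passing tests demonstrate the
estimators' internal correctness and the error-propagation phenomenology
under the assumed model, not performance on any particular real network.

## Known limitations

* With a range comparable to the study region (the sulfur-like regime,
  φ = 2145 km on a 4000 km square), σ² and φ are not separately
  identifiable — only their ratio is well estimated (median relative error
  ~15% at n = 300). The marginal ML distribution of σ̂² is strongly
  right-skewed and its median sits ~35% below the generating value; this is
  a property of the likelihood geometry, not the optimizer (the optimum is
  reproduced exactly by an independent GLS implementation, and the same
  estimator recovers σ² within ~12% when the range is well inside the
  domain).
* Under a true nugget-only field, ML with a free range fits a small
  spurious spatial component in roughly half of realizations rather than
  returning σ̂² = 0 (the usual boundary behavior when φ is unidentified
  under the null); the fitted total sill remains accurate. Model selection
  by cross-validation, not θ̂ alone, should decide whether kriging is
  retained.
* The bootstrap-vs-naive SE comparison fluctuates across study
  realizations because the realized exposure contrast in a handful of
  urban clusters varies; validation experiments therefore average over
  three independent study realizations.
* Dense covariance factorizations cap practical problem sizes at a few
  thousand total sites. Validation experiment sizes: 20 × 30-site oracle
  instances; 3 × 50-site likelihood-grid fields; 20 recovery replicates at
  n = 300 (strong-range) and n = 150 (nugget-only); bootstrap scenarios
  with 150 monitors, 500 subjects, B = 1000.
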