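# Methods

## Scope and data model

The package analyzes areal (district-level) percentage data: one polygon
per administrative unit, a numeric attribute table keyed by unit ID, and a
contiguity weight matrix `W` connecting units that share boundary points.
Because the motivating district microdata are distributed only on request,
the pipeline is developed and validated entirely on synthetic lattices
whose generating process is known; nothing in the statistical machinery is
lattice-specific, and real GeoJSON + CSV inputs run through the identical
code path.

## Spatial weights

Queen contiguity declares units i and j neighbors when their boundaries
come within a snap distance of each other, so shared edges and single
shared corners both qualify. The snap tolerance (default 1e-7 map units)
absorbs the coordinate slivers common in administrative boundary files; the
criterion is purely topological, so coordinate reference systems are taken
as given and never reprojected. Binary weights are symmetric by
construction. Row standardization divides each row by its degree; it is the
default style for every statistic and model here, as in the spatial
econometrics tradition, because it makes the spatial lag an average of
neighbors, pins the upper stationarity bound of autoregressive parameters
at 1, and keeps Moran's I in its familiar range. Units with no neighbors
(islands) keep empty rows, are excluded from S0, are always labeled
non-significant in local analysis, and are dropped — with a logged count
and ID list — only inside ML model fitting, where a disconnected unit would
make the autoregressive transform degenerate. Weights serialize to the GAL
text format with the style recorded in a comment header.

The spectrum of the row-standardized `W` is computed by the similarity
trick: `D^{-1}A` (A symmetric binary, D the degree matrix) shares its
eigenvalues with the symmetric `D^{-1/2} A D^{-1/2}`, so a symmetric dense
eigensolver applies and the spectrum is exactly real. The stationary
interval for spatial parameters is `(1/ω_min, 1/ω_max)`, upper bound 1
for row-stochastic `W`. Dense eigendecomposition is exact and cheap to a
few thousand units, which covers district systems comfortably; sparse or
series approximations of the log-determinant are deliberately out of scope.

## Global and local Moran

Global Moran's I is evaluated as the literal double sum
`(n/S0) Σ w_ij z_i z_j / Σ z_i²` (implemented as one sparse quadratic
form, verified against an O(n²) loop to 1e-12). Inference is Monte-Carlo:
values are randomly permuted across units, and the pseudo p-value is
`(M+1)/(R+1)` with M the permutations at least as extreme as the
observation *in the direction of its deviation from* `E[I] = −1/(n−1)`.
This directional p is the reporting convention of the GIS software
tradition; note that thresholding it at α rejects in either tail and so
has empirical size near 2α under the null. Where a calibrated decision is
needed — including the package's own size study — the `two_sided` option
doubles the p-value, and the Monte-Carlo size then sits at the nominal
level (measured 0.044 over 2000 spatially random datasets, nominal 0.05).

The local Moran is reported in the scaled form `I_i = (z_i/m₂) Σ w_ij z_j`
with `m₂ = Σz²/n`, whose total is exactly `S0·I`; the bare cross-product
`z_i Σ w_ij z_j` is available by flag since both appear in the applied
literature. Local inference is conditional permutation: `z_i` stays fixed
while the other n−1 values are drawn without replacement onto i's neighbor
positions. Each unit consumes its own counter-keyed RNG stream
(`default_rng([seed, i])`), so results are independent of evaluation order
and reproducible unit-by-unit. Quadrants (HH/LL/HL/LH) come from the signs
of the centered value and the centered lag (lag of z, not raw x), matching
the Moran scatter plot; zero deviations count as "high" for deterministic
labeling. Significant units keep their quadrant label at level α (default
0.05, per-unit, uncorrected — the convention of the applied work this
follows); an optional FDR flag is deliberately off by default. Islands are
always NS.

## Regression models

**OLS** is solved by least squares with the Gaussian likelihood
`logL = −(n/2)(ln 2πσ̂² + 1)`, `σ̂² = e'e/n`; coefficient standard errors
use the unbiased `e'e/(n−k)` scale and two-sided normal tests. VIFs come
from auxiliary regressions, `1/(1−R²_j)`. AIC counts `k = #β + 1`
parameters (σ²).

**LM diagnostics** use the standard Rao-score forms on OLS residuals. With
`s² = e'e/n`, `T = tr(W'W + WW)`, `d_e = e'We/s²`, `d_l = e'Wy/s²`, and
`D = (WXb)'M(WXb)/s² + T`:

- LM-error `= d_e²/T`, LM-lag `= d_l²/D` (χ²(1));
- robust LM-error `= (d_e − T d_l/D)² / (T(1 − T/D))`,
  robust LM-lag `= (d_l − d_e)²/(D − T)` (χ²(1));
- SARMA `=` robust-error `+` LM-lag `=` robust-lag `+` LM-error (χ²(2)),
  an algebraic identity the tests verify to 1e-8.

The source study prints these statistics but no formulas; the forms above
are the universal convention in spatial econometrics. Under a spatially
random generating process the empirical 95th percentile of LM-error over
1000 replicates at n = 640 lands within a few percent of the χ²(1)
quantile 3.84.

**SEM and SLM** are fitted by maximizing the log-likelihood concentrated in
the scalar spatial parameter. For SEM, `A = I − λW` whitens both sides;
β and σ² are profiled out by least squares on `(Ay, AX)` and
`logL(λ) = −(n/2)(ln 2πσ̂² + 1) + ln|A|`. For SLM the profile regresses
`y − ρWy` on X. The log-determinant is the eigenvalue sum
`Σ ln(1 − aωₖ)` — exact given the precomputed real spectrum, which is
cached on the weights object so replicate studies pay for one
eigendecomposition. The scalar search is bounded Brent over the stationary
interval clipped by 1e-6 at each end, tolerance 1e-8; boundary solutions
trigger a warning. Standard errors come from the negative inverse
central-difference Hessian of the *full* likelihood in (β, a, σ²) at the
optimum. Reported residuals are the innovation estimates (ξ̂ = A(y−Xβ̂)
for SEM, ε̂ = Ay − Xβ̂ for SLM): these are the quantities the model claims
are white, so their Moran statistic is the natural declustering check. LR
tests against OLS use χ²(1); the studentized (Koenker) Breusch-Pagan is
`n·R²` from regressing squared innovations on X, χ²(#covariates). AIC
counts `k = #β + 2`; ties in model ranking break toward fewer parameters.
At a spatial parameter fixed to 0 (`at_param=0`) both models reduce
algebraically to OLS, which the tests assert to machine precision — the
freely estimated fit differs from OLS by the sampling noise of the spatial
parameter, as it must.

## Synthetic data generator

The generator emulates the study conditions: a 20×32 lattice of unit
squares (n = 640, the real district count) whose queen graph has the
familiar {corner 3, edge 5, interior 8} degree structure; covariates drawn
independently normal at the published district-level means and SDs
(cervical screening 21.96 ± 14.62, rural 71.57 ± 21.66, and so on),
clipped to [0, 100]; and outcomes generated under one of

- CSR: `y = Xβ + ξ`;
- SEM: `y = Xβ + (I − λW)^{-1}ξ`, default λ = 0.69 (the published
  cervical spatial-error estimate);
- SLM: `y = (I − ρW)^{-1}(Xβ + ε)`, default ρ = 0.59;

with i.i.d. Gaussian innovations (sparse-LU solve of the autoregressive
system). Draw r of a replicate set uses the stream `(seed, r)`, so
individual replicates are reproducible regardless of batch size, and fixed
seeds give bitwise-identical output. The default true slopes are the
published cervical spatial-error coefficients; the intercept is solved so
the outcome mean sits at 21.96 on the percentage scale; and the innovation
SD (9.4) comes from a closed-form calibration — the unexplained outcome
SD implied by the published fit (14.62·√(1−0.389) = 11.43) divided by the
square root of the exact SEM variance amplification tr((A'A)^{-1})/n =
1.467 at λ = 0.69 on this lattice. The obesity covariate is absent from
the published summary table; its spec (20.7 ± 9.0) is an implementer
choice, flagged in the source.

Two features of real district data are deliberately **not** reproduced,
because the study reports only marginals: the inter-covariate correlation
structure (a hook accepts a correlation matrix, but no default is
invented), and the covariates' own spatial autocorrelation. Consequently
the synthetic outcome's global Moran (≈0.14 at the default settings) is
well below the published 0.61 — in the real system both the covariates and
the error are clustered, here only the error is. Passing tests therefore
demonstrate the estimators' correctness and calibration under a known
process at the study's scale, not a reconstruction of the study's maps.
Outcomes are never clipped to [0, 100]: recovery studies need the stated
process exactly, and censoring would bias the spatial-parameter estimates.

## Validation design

Because no independent spatial-econometrics implementation is available in
the package's environment, verification is triangulated: brute-force
double-loop oracles for Moran/lag/contiguity at small n; frozen reference
values for global Moran computed with R's `ape` package
(`ape::Moran.I`, regenerable via `scripts/make_r_reference.R`); live
statsmodels agreement for OLS and the studentized Breusch-Pagan; and, for
the ML fits, a deliberately different estimation route written only in the
tests — joint Nelder-Mead/golden-section optimization of the full
likelihood with dense `slogdet`, sharing no code with the
concentrated-eigenvalue search — agreeing to 1e-5 at n = 640. Monte-Carlo
studies (sizes chosen to keep the full suite in minutes on one CPU: 500
datasets for test size, 100 replicates for recovery and declustering, 1000
for LM null calibration) check size, bias, Wald coverage, and the
OLS→SEM residual-declustering behavior that motivates the error model.

## Known limitations

- Geometry input is GeoJSON only; there is no shapefile reader among the
  package's dependencies.
- Dense spectral machinery bounds practical problem size at a few thousand
  units.
- The directional pseudo-p convention is reported as-is; users wanting
  size-α decisions should use the two-sided option (the pipeline's
  significance counts use the reported p at the configured α, matching the
  applied convention).
- No survey weighting, no aggregation from microdata, no multiple-testing
  correction by default, no rook/k-NN/distance weights, no spatial Durbin
  or GMM estimators.
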