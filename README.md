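# spatscreen

District-level spatial analysis of health-indicator uptake: queen-contiguity
weights, global and local Moran autocorrelation with Monte-Carlo permutation
inference, and maximum-likelihood spatial error/lag regression.

## The problem

Percentages aggregated over administrative districts — here, the share of
women who have undergone cervical or breast cancer screening, together with
socio-demographic covariates — are almost never spatially independent:
neighboring districts resemble each other. Ordinary regression then
understates standard errors and misleads inference. The standard remedy in
spatial epidemiology is a three-step procedure:

1. **Detect** spatial structure. Global Moran's I over a contiguity weight
   matrix `W`,

   `I = (n / S0) * Σᵢ Σⱼ w_ij z_i z_j / Σᵢ z_i²`,  `z_i = x_i − x̄`,

   with significance from random permutation of the values across districts
   (pseudo-p = (M+1)/(R+1) over R permutations). The local decomposition
   (LISA), `I_i = (z_i/m₂) Σⱼ w_ij z_j`, classifies each district into
   Moran-scatter quadrants — HH/LL clusters and HL/LH spatial outliers —
   with conditional-permutation inference.

2. **Diagnose** the dependence type. Lagrange-multiplier score tests on the
   OLS residuals distinguish error-type from lag-type dependence (plus
   robust variants and the joint SARMA test).

3. **Model** it. Maximum likelihood for the spatial error model (SEM)
   `y = Xβ + u, u = λWu + ξ` and the spatial lag model (SLM)
   `y = ρWy + Xβ + ε`, via the log-likelihood concentrated in the scalar
   spatial parameter, with `ln|I − aW| = Σₖ ln(1 − a ωₖ)` over the
   eigenvalues of the row-standardized `W`. Models are compared by
   likelihood ratio against OLS and ranked by AIC.

The district microdata behind the motivating study are access-restricted,
so the package ships a first-class synthetic-data module: square-cell
lattices (default 20×32 = 640 cells, the real district count) with
covariates drawn to the published district-level marginal means/SDs and
outcomes generated under known CSR/SEM/SLM processes. Every estimator can
therefore be validated against the truth that generated its input.

## Worked example

```python
import spatscreen as ss

# synthetic study-scale fixture: 640 districts, SEM outcome at lambda=0.69
ids, geoms = ss.make_lattice(ss.LatticeSpec())           # 20x32 lattice
w = ss.build_queen_weights(geoms, ids).row_standardized()
tab = ss.simulate_covariates(ss.default_variable_specs(), 640, seed=7)
x, beta_true, names = ss.study_design(tab)
y, truth = ss.simulate_outcome(w, x, ss.DgpConfig("sem", tuple(beta_true),
                                                  spatial_param=0.69, seed=11))

print(round(ss.moran_i(y, w), 3))                        # 0.139

design = ss.RegressionDesign(y, x, names)
ols = ss.fit_ols(design)
sem = ss.fit_spatial_error(design, w, ols=ols)
print(round(ss.moran_i(ols.residuals, w), 3))            # 0.295
print(round(sem.spatial_param, 3))                       # 0.652
print(round(ss.moran_i(sem.residuals, w), 3))            # 0.01
print(ss.compare_models(ols, sem)["preferred"])          # sem
```

OLS leaves strongly clustered residuals (Moran's I = 0.295, permutation
p = 0.001); the spatial error model recovers the generating λ = 0.69 to
within sampling error and collapses the residual autocorrelation to 0.01
(non-significant) — the model has absorbed the spatial structure.

The same workflow runs from the shell:

```bash
spatscreen fixtures --rows 20 --cols 32 --process sem --seed 11 --output-dir fixture
spatscreen run --geometry fixture/lattice.geojson --attributes fixture/attributes.csv \
    --outcome cervical_screening \
    --covariates literate,currently_married,hindu,general_caste,rural,rich,oral_contraception,tobacco,multiple_partners,parity_gt3,insurance \
    --seed 11 --output-dir out
```

which writes summary statistics, the per-variable Moran table, the LISA
cluster GeoJSON, OLS/SEM/SLM tables with diagnostics, residual maps, and a
machine-readable `report.json`. The numbered scripts under `analysis/`
(`01_simulate_fixture.py` … `04_validation.py`) run the complete study
narrative and write their tables under `results/`.

## Layout

- `src/spatscreen/` — the library: `synthetic_data`, `geo_io`, `weights`,
  `autocorrelation`, `spatial_models`, `experiments`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite, including brute-force oracles, calibration
  simulations, and cross-implementation checks
- `docs/methods.md` — models, assumptions, numerical choices, limitations
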