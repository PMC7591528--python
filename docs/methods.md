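# Methods

This note documents the models and procedures implemented in `ptjplfuse`,
the assumptions behind them, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## The PT-JPL partitioning model

Total evapotranspiration is the sum of soil evaporation (ES), canopy
interception evaporation (EI) and transpiration (T). Each component is the
Priestley-Taylor potential rate α·Δ/(Δ+γ) applied to its share of
available energy — soil (R_ns − G) for ES, canopy R_nc for EI and T —
scaled by multiplicative, dimensionless eco-physiological constraints in
[0, 1]:

| symbol | meaning | form |
|---|---|---|
| f_wet | relative surface wetness | RH⁴ |
| f_g | green canopy fraction | f_APAR / f_IPAR, clipped to [0, 1] |
| f_T | plant temperature constraint | exp(−((Ta − T_opt)/T_opt)²) |
| f_sm | soil moisture constraint | RH^(VPD/β), 1 when VPD ≤ 0 |
| f_M | plant moisture constraint | f_APAR / f_APARmax, clipped to [0, 1] |

Radiation is partitioned by Beer-Lambert extinction,
R_ns = R_n·e^(−k_Rn·LAI); the absorbed/intercepted PAR fractions are
saturating exponentials of LAI with asymptotes b₁, b₂ and extinction
coefficients k₁, k₂.

Assumptions and conventions:

* **Δ and e_s** use the FAO-56 Tetens closed forms. The model names Δ but
  no formula fixes it; Tetens is the convention of the FAO-Penman
  net-radiation forcing this model is normally driven with. Valid range
  Ta ∈ [−40, 60] °C, enforced.
* **RH is a fraction** in [0, 1] everywhere in memory. The
  exponentiations RH⁴ and RH^(VPD/β) are meaningless for percent values,
  so files that plainly carry percent (max > 1.5) are converted on read.
* **G (ground heat flux) defaults to zero.** At the 8-day compositing
  scale soil heat storage approximately cancels; a gridded G layer can be
  supplied to override.
* **Non-negativity.** Negative available energy (e.g. R_ns − G < 0 under
  dense canopy) clamps the affected component at zero rather than
  producing negative evaporation; ET is defined as the sum of the clamped
  components, so ET = ES + EI + T holds exactly (bitwise) everywhere.
* **Degenerate guards.** f_g = 0 where f_IPAR = 0 (no canopy); f_sm = 1
  at saturation (RH^0 limit); f_APARmax is floored at 0.01 so f_M cannot
  blow up on never-green pixels; T_opt = 0 is rejected (it divides the
  f_T exponent).
* **T/ET** is reported only where ET > 10⁻⁶ mm per period; below that the
  ratio is noise (winter shutdown) and is written as fill.

### Biome parameters

The packaged look-up table carries per-biome calibrated values
k₁ = {forest 0.57, shrub 0.56, crop 0.59, grass 0.59},
k₂ = {0.81, 0.91, 0.84, 0.80}, β = {1.28, 1.17, 1.43, 0.80} kPa.
b₁, b₂ (1.0) and k_Rn (0.6) keep canonical PT-JPL values — they are not
biome-calibrated here but remain exposed in the YAML and in the
calibration interface. T_opt is derived per pixel as the air temperature
at the record maximum of LAI·Ta·f_APAR (earliest index on ties); the rule
is applied to every biome. f_APARmax is the per-pixel maximum of f_APAR
over the full multi-year record (not per year): it is meant to represent
the pixel's attainable canopy, and a per-year definition would reset f_M
to 1 every summer regardless of interannual condition.

## Forcing I/O

Grids are regular lat/lon, cell-center registered, latitude stored
descending (N→S); ascending files are normalized on read. The temporal
axis is the MODIS-style 8-day compositing calendar: 46 periods starting
at day-of-year 1, 9, …, 361, the last period 5 days (6 in leap years).
Regridding is conservative (area-overlap weights, separable in lat/lon):
continuous fields take the valid-weighted mean, categorical fields the
class with the largest overlap area (ties → lowest class code). A field
regridded onto its own grid is returned unchanged, and overlap slivers
below 10⁻⁶ of a cell are discarded — both guard against floating-point
edge noise manufacturing data in missing cells. Missing data are NaN in
memory and `_FillValue = −9999` on disk; files are NetCDF classic
(written via the scipy backend), CF-style, with per-period start/end
day-of-year coordinates.

## Sobol' sensitivity analysis

Saltelli cross-sampling design (A, B, A_B^(i), B_A^(i); n_base·(2d+2)
evaluations) over a scrambled Sobol' sequence, with the Saltelli (2010)
first-order estimator, the Jansen total-order estimator, and the closed
second-order identity for pairwise indices. Negative estimates are
reported as-is with bootstrap percentile intervals (200 resamples of
design rows) so a statistical zero is distinguishable from estimator
bias. Default bounds: b₁, b₂ ∈ [0.5, 1.0]; k₁, k₂ ∈ [0.1, 1.5];
β ∈ [0.1, 3.0] kPa; T_opt ∈ [5, 35] °C; k_Rn ∈ [0.2, 1.0].

The scalar model output fed to the decomposition is, by default, the sum
of squared mismatches between simulated and observed annual T and ET over
the site set (the same multivariate data that drive calibration); mean
annual T or mean annual ET are available as alternative outputs.

## DEMC calibration

Likelihood: datasets (annual T, annual ET) multiply; within a dataset the
residuals Δ_i(t) are Gaussian with SD σ_i. σ_i is the RMSE of the current
residuals, recomputed at every likelihood evaluation (the definition is
self-referential, so this plug-in/profile reading is the only consistent
one; it makes σ data- and parameter-dependent). A perfect fit is kept
finite by a σ floor of 10⁻⁹. With plug-in σ the log-likelihood reduces to
−Σ_i T_i(log(√(2π)σ_i) + ½).

Sampler: ter Braak's DEMC. Proposal θ* = θ_i + γ(θ_a − θ_b) + ε with two
distinct partner chains; γ = 2.38/√(2d) with 10% of generations at γ = 1
(mode jumps); ε ~ N(0, 10⁻⁶·(upper − lower)). Priors are independent
uniforms on the parameter bounds; only the sensitive parameters
(k₁, k₂, β, T_opt by default) are sampled, the rest stay pinned.
Defaults: n_chains = max(3d, 8), 5000 generations, first 50% discarded as
burn-in. Convergence is reported per parameter as split-chain
Gelman-Rubin R-hat; a run with any R-hat > 1.1 is returned flagged
`converged=False`, never silently discarded. The point estimate written
to the parameter table is the posterior median (robust to the skewed,
sometimes one-sidedly identified marginals); the MAP is also emitted.
Identical seeds give bit-identical chains.

A note on identifiability: in humid climates the annual fluxes are nearly
insensitive to β above ~1.5 kPa (f_sm ≈ 1 when VPD is small), so β's
posterior can be sharp below the truth and flat above it. The credible
intervals report exactly that.

## Gridded simulation and products

Each vegetated pixel is evaluated independently with its biome's
parameters and its per-pixel T_opt/f_APARmax (grid results are bitwise
identical to per-pixel scalar calls). Fluxes in W m⁻² are converted to mm
per compositing period with λ = 2.45 MJ kg⁻¹ (1 W m⁻² day = 0.0864 MJ
m⁻²), weighting the short final period by its true length. Annual T and
ET are sums over the 46 periods with gap periods contributing zero (the
gap rule of the emulated product); a gap-fraction diagnostic layer
records how much was filled that way, and pixels with no valid period
(non-vegetated, all-gap) stay missing. Annual T/ET is the ratio of annual
sums — not the mean of period ratios, which differs whenever fluxes
covary with the ratio.

Files follow the product layout: `Annual_VVVV.nc` with one layer per
year, `Daily_VVVV_TTTT.nc` with 46 layers per year and per-period
start/end day-of-year coordinates, fill −9999, float32. The writer
refuses to overwrite without an explicit flag and returns a manifest of
paths and layer counts.

## Validation statistics

R² is the squared Pearson correlation (the 1 − SSE/SST variant is
computed alongside; the two differ under bias, and squared correlation is
the flux-validation convention). RMSE is reported absolutely and as a
percentage of the observation mean. The Mann-Kendall test uses the
tie-corrected variance and continuity correction with a two-sided normal
approximation; significance defaults to α = 0.01. Sen's slope is the
median of all pairwise slopes. Regional T/ET is the ratio of regional
mean T to regional mean ET over valid cells; the mean of per-pixel ratios
is returned alongside, labeled as the discouraged alternative, because it
over-weights low-flux pixels.

## Synthetic data

The generator builds the statistical world the pipeline assumes: a
0.05° grid split into five biome bands (forest/shrub/grass/crop/
non-vegetated), 8-day forcing with seasonal sinusoids (temperature
amplitude ~12 °C peaking near day 200, net radiation coupled to the
temperature season, relative humidity lowest when the VPD season peaks,
clipped to [0.2, 1.0]), a weak meridional temperature gradient, small
Gaussian driver noise, biome-specific LAI phenology, an optional
multiplicative greening trend (default 0.5% a⁻¹), and random forcing gaps
(default 2%). Observations are sampled at pixel centers: up to 10 ET
sites per biome with 1–4 site-years each, of which the first 6 also
report annual T (sap-flow data are scarcer than eddy covariance in
practice); noise is multiplicative lognormal with mean one and CV 5% —
flux magnitudes are positive and errors scale with magnitude. The truth
uses fixed per-biome T_opt values (forest 20, shrub 22, grass 18,
crop 24 °C) so parameter recovery can be scored against known numbers.

Two stock configurations: the desk-scale default (10×10 cells × 3 years;
the full calibrate-simulate-validate loop runs in seconds to minutes) and
a trend configuration (6×6 cells × 35 years) for multi-decade
experiments. These sizes were chosen so that a single calibration
replicate carries ~50–130 site-year records, comparable to the data
volumes such calibrations see in practice.

What passing tests on this world do **not** show: robustness to sensor
artifacts and orbital drift, to spatially correlated forcing error, to
site-footprint/pixel scale mismatch, or to energy-balance closure error
in the observations — none of which are emulated.

## Known limitations

* No snow/frozen-soil physics and no Penman-Monteith alternative; winter
  fluxes are whatever the constraint functions yield, and T/ET is simply
  masked where ET is negligible.
* The per-pixel T_opt rule is deterministic from the forcing record;
  under a warming or greening trend it shifts with the record analyzed.
* The plug-in σ likelihood under-propagates observation-error uncertainty
  relative to sampling σ as a parameter; with the default data volumes
  the practical effect on the parameter posteriors is small.
* Regridding supports regular geographic grids only (no projections, no
  curvilinear grids).
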