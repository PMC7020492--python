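# Methods note

This note records the model structure, the parameter defaults and their
rationale, what the synthetic data does and does not emulate, the numerical
choices, and the open design decisions behind `leafsim`.

## 1. Model and assumptions

### 1.1 Leaf energy budget (`leafsim.energy_budget`)

Steady-state balance for a single leaf: absorbed radiation is dissipated by
longwave emission, sensible heat and transpiration. The production path uses
the standard linearization around air temperature,

```
T_l = T_a + [γ*/(s + γ*)] · [ R_ni/(g_Hr·C_p) − D/(P_a·γ*) ]
```

with

- `R_ni = α_SW·SW + LW_in − ε·σ·T_a⁴` — isothermal net radiation (W m⁻²),
  i.e. the net radiation a leaf *at air temperature* would absorb;
- `g_Hr = g_Ha + g_r` — combined boundary-layer + radiative conductance for
  heat, `g_r = 4εσT_a³/C_p`;
- `γ* = γ·g_Hr/g_v` — apparent psychrometric constant, `γ = 6.66e-4·P_a/101.3`;
- `s` — slope of saturation vapor pressure at `T_a` divided by `P_a`;
- `D` — air vapor pressure deficit (kPa).

Assumptions: steady state (no heat storage), uniform leaf temperature,
forced convection only (no free-convection switch at low wind; instead a
0.1 m s⁻¹ wind floor), both leaf faces exchange longwave and sensible heat.
Vapor conductance follows the leaf's stomatal arrangement: amphistomatous
leaves (grasses) combine stomatal and boundary-layer conductances in series
on both faces, `g_v = 0.5·g_s,ab·g_va/(g_s,ab+g_va) + 0.5·g_s,ad·g_va/(g_s,ad+g_va)`;
hypostomatous leaves use the abaxial face only. At `g_s = 0` the latent term
vanishes (`γ* → ∞` limit handled analytically).

Boundary-layer conductances use flat-plate relations with an outdoor
turbulence factor of 1.4: `g_Ha = 1.4·0.135·√(u/d)`,
`g_va = 1.4·0.147·√(u/d)` (mol m⁻² s⁻¹), where the characteristic dimension
is `d = 0.72 ×` maximum leaf width.

Longwave input depends on the environment: `chamber` assumes black walls at
air temperature (`LW_in = σT_a⁴`, so `R_ni` reduces to absorbed shortwave);
`field` uses a clear-sky apparent emissivity `ε_a = 9.2e-6·T_k²`.

A fully nonlinear balance (`energy_balance_oracle`) solves
`R_abs − εσT_l⁴ − C_p·g_Ha·(T_l − T_a) − λ·g_v·(e_sat(T_l) − e_air)/P_a = 0`
by Brent's method and serves as the accuracy reference for the
linearization (tested to ≤ 0.5 °C over a 500+ point grid; observed worst
case ≈ 0.03 °C for 5 mm grass leaves).

### 1.2 Pasture model (`leafsim.pasture_model`)

Daily time step, single point, one state each for heat stress, soil water
and standing biomass:

```
growth_C = max(0, p_max · f(T_mean) · GLF_W · HT)
```

- `f(T)`: trapezoid 0 at 5 °C → 1 at 15 °C → 1 at 23 °C → 0 at 35 °C.
- `HT`: 1 for `T_max ≤ 30 °C`, linear to 0 at 35 °C; stress begins strictly
  above 30 °C. After a stress episode the coefficient climbs linearly back
  to 1 as heat units `max(0, 25 − T_mean)` accumulate on stress-free days;
  full recovery when their sum reaches `T_sum`. Worked default: `T_sum` =
  100 and a constant post-stress mean of 20 °C give 5 units/day and exactly
  20 days to full recovery. A new hot day during recovery deepens (never
  shallows) the stress level and zeroes the accumulator.
- `GLF_W = min(1, AW/(0.5·PAWC))`: the bucket limits growth (and scales AET)
  once available water drops below half of plant-available capacity.
- Water balance: `AET = min(PET·GLF_W, supply)` with start-of-day GLF;
  storage above PAWC drains. Closure `ΔAW = rain + irrigation − AET −
  drainage` is exact (tested to 1e-9 mm).
- Management: irrigation applies 50 mm when the trailing 5-day `PET − rain`
  deficit strictly exceeds 25 mm; cutting on the last calendar day of each
  month removes biomass above a 1.4 t DM ha⁻¹ residual.

The growth-driving temperature is `T_mean = (T_max + T_min)/2`. This is the
lever the coupling uses: replacing `T_max` with a midday leaf temperature
shifts both the stress bookkeeping (driven by `T_max`) and the temperature
response (driven by `T_mean`).

### 1.3 Coupling (`leafsim.coupling`)

Two passes. Pass 1 runs on air temperature and yields a daily `GLF_W`.
A lookup table maps `GLF_W` to midday stomatal conductance (right-closed
deciles, 0.005 mol m⁻² s⁻¹ for the driest bin up to 0.4 for unlimited
water; irrigated swards are pinned at 0.4). The energy budget is evaluated
at the day's maximum temperature with midday irradiance reconstructed from
daily shortwave totals assuming a half-sine diurnal course
(`SW_midday = MJ·1e6·π/(2·daylength)`), daylength from solar geometry.
Pass 2 re-runs the model with `T_max` replaced by the leaf temperature.
Because `GLF_W` depends only on the prescribed PET and rain, not on
temperature, further iteration reproduces pass 2 exactly; an optional
fixed-point loop is provided and converges immediately.

### 1.4 Evaluation (`leafsim.evaluation`)

Mean bias (`obs − pred`; over-prediction negative), RMSE/MAE, mean
prediction error `MPE = 100·RMSE/mean(obs)`, modelling efficiency
`MEF = 1 − SSE/SS_obs`, variance ratio `v = sd_obs/sd_pred`, Lin's bias
correction `C_b = 2/(v + 1/v + u²)` and concordance `CCC = r·C_b`
(cross-checked against the covariance form
`2·s_xy/(s_x² + s_y² + (x̄−ȳ)²)` to 1e-12). `homeothermy_test` regresses
leaf on air temperature and t-tests the slope against 0 and against 1; a
slope strictly between 0 and 1 indicates limited homeothermy (leaves
buffering air-temperature swings).

## 2. Parameters: defaults, units, rationale

| Parameter | Default | Units | Why |
|---|---|---|---|
| `p_max` | 40 | kg C ha⁻¹ d⁻¹ | Potential net positive photosynthesis of a well-watered temperate sward; scales out of all response-ratio results. |
| `t_min_growth`, `t_opt_lo`, `t_opt_hi` | 5, 15, 23 | °C | Perennial-ryegrass trapezoid breakpoints. |
| `ht_onset`, `ht_full` | 30, 35 | °C | Heat-stress onset (exclusive) and full-stress thresholds for ryegrass. |
| `t_sum` | 100 | heat units | Default recovery requirement; 50 and 20 are faster-recovering parameterizations, ~200 emulates summer dormancy. |
| `recovery_base` | 25 | °C | Days with mean ≥ 25 °C contribute no recovery. |
| `residual` | 1.4 | t DM ha⁻¹ | Post-cut residual of a monthly defoliated sward. |
| `pawc` | 80 | mm | Plant-available water capacity of a moderate loam root zone. |
| `dm_per_c` | 2.5 | kg DM (kg C)⁻¹ | ≈ 40 % carbon content of dry matter. |
| `max_leaf_width` | 0.005 (tests) | m | Narrow grass leaf; `d = 0.72·width`. |
| `emissivity` | 0.97 | – | Typical leaf thermal emissivity. |
| `sw_absorptivity` | 0.5 | – | Whole-spectrum shortwave absorptivity (PAR + NIR average). |
| `gs` endpoints | 0.005–0.4 | mol m⁻² s⁻¹ | Measured range from fully stressed to unlimited water. |
| irrigation | 50 mm per event, 25 mm / 5-day trigger | mm | Management rule; see §5 on the carried deficit. |
| wind floor | 0.1 | m s⁻¹ | Keeps √(u/d) finite and acknowledges indoor air mixing. |

## 3. Synthetic data: what it does and does not emulate

**Chamber** (`chamber_weather`): deterministic 35-day protocol, five 7-day
phases (pre-treatment, heat 1, recovery 1, heat 2, recovery 2). Day/night
regimes 25/15 (control), 30/20 (moderate), 35/25 (severe); elevated
temperatures apply **only during the treatment weeks** — recovery weeks run
at control conditions, so a recovery week accumulates 5 heat units per day
(mean 20 °C). Fixed 70 % RH, 900 µmol m⁻² s⁻¹ PPFD, 2 m s⁻¹ fan wind.
Daily `tmax`/`tmin` are the day/night setpoints; the symmetric ramp profile
makes the daily mean their midpoint. Watering arms: WW holds GLF_W at 1;
WS ramps it linearly (or exponentially) from 1 to 0.05 across each
treatment week and restores it in recovery. It emulates the *shape* of a
controlled stress/recovery experiment, not chamber physics: no ramp-time
thermal lag, no VPD feedback on watering, no pot-size effects.

**Field** (`field_weather`): seeded daily weather for cool-temperate
(lat −38.25°, mean tmax 18 °C, seasonal amplitude 7 °C) and warm-temperate
(−36.37°, 21.5 °C, 9 °C) sites. Sinusoidal seasonal cycle plus AR(1)
anomalies (φ = 0.6, σ = 3 °C), two-state Markov rain occurrence with
exponential amounts, PET from a seasonal cycle modulated by temperature
anomaly, vapor pressure `0.95·e_sat(tmin)` (near-saturation at dawn).
It reproduces seasonality, warm spells of realistic persistence and
drought sequences; it does **not** reproduce observed station records,
spatial correlation, rain–temperature coupling on synoptic scales, or
climate trends. Columns are rounded to typical reporting precision so
files round-trip exactly.

**Measurements** (`noisy_measurements`): adds seeded Gaussian noise to
model output to exercise the evaluation statistics (e.g. recovering a
planted leaf-vs-air slope of 0.88 at n = 294).

## 4. Numerical choices

- Linearized budget is closed-form; the oracle uses `scipy.optimize.brentq`
  on `[T_a − 20, T_a + 20]` with the residual verified < 1e-3 W m⁻².
- Saturation vapor pressure: Tetens form `0.611·exp(17.502·t/(t+240.97))` kPa,
  consistent between budget, oracle and generators.
- PPFD → shortwave: `W m⁻² = PPFD/4.6·(1 + nir_fraction)`; chamber lamps
  default to `nir_fraction = 0` (PAR-only accounting with α = 0.5).
- Midday irradiance from daily totals assumes a half-sine diurnal course;
  daylength from the standard sunset-hour-angle formula.
- Conductance lookup uses `np.searchsorted(..., side="left")` on bin edges
  (0.1 … 1.0) to get right-closed deciles exactly.
- All simulations are deterministic given inputs and seed; stochastic
  generators take explicit `numpy.random.default_rng` seeds. Reruns are
  byte-identical (tested).
- Problem sizes: the full test suite runs ~200 tests in about 3 s; a
  10-year two-pass field run takes ~1 s; 56 years of weather generate in
  well under a second.

## 5. Open design decisions and deviations

- **Carried irrigation deficit.** The windowed rule alone (5-day deficit
  > 25 mm) never fires when PET sits below 5 mm day⁻¹, so an "irrigated"
  sward would still dry down through shoulder seasons. `simulate` therefore
  also carries the cumulative unmet deficit since the last event and
  triggers the same 50 mm application when it exceeds 25 mm. This keeps
  irrigated `GLF_W` at 1 year-round — the intended meaning of irrigation
  "as required so that no water stress occurs" — while the pure windowed
  rule remains available and tested as `irrigation_rule`.
- **Recovery heat units** are `max(0, 25 − T_mean)`: cool days recover
  faster, hot days contribute nothing. (An additive reading, `25 + T_mean`,
  would contradict the 20-day worked example and make recovery faster in
  heat; it was rejected.)
- **Chamber heat only in treatment weeks.** Applying the elevated regime
  to all five weeks would leave severe-regime recovery weeks at a 30 °C
  mean, accumulating zero heat units and never recovering; restricting heat
  to the treatment weeks reproduces the intended dip-and-recover pattern.
- **`T_mean` convention** is the `(tmax + tmin)/2` midpoint everywhere,
  including after leaf-temperature substitution — the simplest way to let
  a cooler (or warmer) canopy propagate into growth.
- **Two-pass vs. fixed point.** Because soil water is driven by prescribed
  PET, the coupling converges after one substitution; the iterative option
  exists for forcings where ET would feed back on the surface state.

## 6. Limitations

- Single leaf, not a canopy: no profile of radiation, wind or humidity,
  and one conductance per day (midday) drives the substituted maximum.
- The daily model has no phenology, nutrition, grazing selectivity or
  senescence; biomass is a pure accumulator between cuts.
- The stress coefficient is empirical; it encodes observed regrowth
  suppression, not a mechanistic damage/repair model.
- Synthetic weather supports method development and order-of-magnitude
  comparisons, not site-specific prediction; conclusions about real sites
  require observed forcing through `cli_io.read_weather`.
- The linearization degrades for wide leaves in still air at extreme
  vapor deficits; the oracle is the fallback there.
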