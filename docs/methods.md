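# Methods

## Model

The loaf is an infinite homogeneous cylinder of radius *r* = 0.061 m with
constant volume (no shrinkage, no porosity evolution). Heat enters the
surface by convection and radiation and moves inward by conduction:

```
rho Cp(T, W) ∂T/∂t = (1/r) ∂/∂r ( r k ∂T/∂r ),
-k ∂T/∂r |_R = h (Ts - T_oven) + eps sigma (Ts^4 - T_oven^4).
```

Moisture (dry basis, kg water per kg dry solid) moves by Fickian diffusion
with an evaporative surface flux:

```
∂W/∂t = (1/r) ∂/∂r ( r D_liq ∂W/∂r ) - (W/tau) S(T),
-D rho_s ∂W/∂r |_R = kg (Ps - Pinf),  Ps = a_w(Ts, Ws) P_sat(Ts).
```

Both fields are symmetric at the axis and start uniform (T0, W0). Crust,
crumb and the evaporation front are diagnostic labels on the temperature
field (crust: T > 373.15 K); the front itself is implicit in the apparent
specific heat below.

### Apparent specific heat

`Cp(T, W) = Cp_s(T) + W Cp_w(T) + lambda_v(T) W delta(T)`. The delta term
is the apparent-heat-capacity treatment of the evaporation front: the
latent heat of the water present is released over a narrow temperature
band instead of at a tracked moving boundary. By default `delta` is a
normalized Gaussian at 373.15 K with standard deviation 0.5 K (unit
integral over temperature, so integrating `Cp - Cp*` across the peak
recovers exactly `lambda_v(373.15) · W`). A `literal` mode replaces the
peak with the tabulated constant delta = 1; it spreads the latent heat
over every kelvin of heating, which suppresses all warming while the loaf
is moist, and is retained for comparison only.

Submodels (temperatures in kelvin):

- solid matrix: `Cp_s = 5 T + 24` J/(kg K);
- liquid water: `Cp_w = (5.207 - 73.17e-4 T + 1.35e-5 T²) · 1000`
  J/(kg K). The printed source of this correlation is typographically
  corrupted; the adopted reading is the standard quadratic-in-T shape for
  liquid water (4.19-4.36 kJ/(kg K) over the baking range) and the
  coefficients are exposed as an argument so alternate readings can be
  evaluated. Valid 200-600 K;
- latent heat: `lambda_v = 2502535.259 - 212.56384 (T - 273)` J/kg.

### Water activity

`a_w = [(100 W exp(-0.0056 T + c))^(-10.38) + 1]^(-1)` with `c = 55` as
printed (configurable; `c = 5.5` is a plausible alternate). Computed in
log space so extreme arguments cannot overflow. With either constant the
large exponent makes `a_w` a near-step in W: essentially 1 for any moist
surface and 0 only at complete local dryness. Solver behavior therefore
never relies on the shape of `a_w` between its plateaus; the dry-out
endpoint is regularized separately (below).

### Surface transfer

`kg` is obtained from the Chilton–Colburn analogy with `Sc = nu/D`,
`Pr = nu/alpha`, and the empirical correction `kg = 7.83e-3 kg*`. The
analogy's air-side constants (M_air = 0.028966 kg/mol, M_w = 0.018015
kg/mol, P_atm = 101325 Pa, Cp_air = 1006 J/(kg K)) are standard values and
configurable. With the tabulated inputs, Sc = 0.2405, Pr = 246.67 and
kg ≈ 4.9e-8 kg/(Pa m² s).

`P_sat` has two closures. The surface default is an Antoine correlation
(two standard constant sets, switching at 99 °C), so that drying
accelerates as the crust heats — with the tabulated constant 0.98e5 Pa the
drying rate would be independent of oven temperature, which contradicts
the reported trend. The oven-air term `Pinf = (RH/100) P_sat` keeps the
tabulated constant reference by default: saturation pressure *at the oven
temperature* exceeds 1 MPa, and an ambient vapor pressure referenced to it
would condense water into the loaf for the entire bake. Physically, oven
air humidity is set by the oven's moisture load, not by saturation at air
temperature.

Because `Pinf` = 9.8 kPa corresponds to a dew point near 45 °C, the cold
loaf condenses a little water during the first ~2 minutes (moisture may
transiently exceed W0 by a fraction of a percent) before the surface warms
through the dew point and drying begins. This is physically expected and
numerically harmless.

### Moisture closure: crumb and crust

The tabulated moisture diffusivity D = 12e-5 m²/s has the magnitude of
water-vapor diffusion in air, not of liquid water in dough (typically
1e-10 to 1e-8 m²/s). Used as a single uniform liquid diffusivity it
empties the loaf in ~20 minutes regardless of oven setting and removes
every qualitative trend in the bake-loss data. The default closure
therefore follows the stated transport picture — liquid diffusion in the
crumb, vapor diffusion in the crust:

- liquid diffusion with `D_crumb` (default 5e-8 m²/s control, 3e-8 m²/s
  guar — guar gum binds water and lowers liquid mobility; both values sit
  in the effective-diffusivity range reported for doughs, and were
  calibrated once against the published 40-min crust temperatures at 190
  and 230 °C);
- water that crosses the boiling point vaporizes and vents through the
  porous crust as a first-order sink with time constant `tau = 60 s`,
  blended in over a 2 K band. At the tabulated vapor diffusivity the
  transit time across a centimeter of crust is about one second, so the
  venting is effectively instantaneous on bake timescales; 60 s is a
  conservative choice that keeps the stiffness mild. (An explicit
  phase-switched diffusivity field was tried first; a five-order-of-
  magnitude diffusivity jump at a moving front is numerically intractable
  for a general-purpose stiff integrator, and the sink formulation is the
  same physics.)
- the surface evaporative flux carries latent heat out of the energy
  balance (`q_evap = lambda_v(Ts) · J` for outgoing J). Without this term
  water removed through the boundary costs no energy at all, which lets
  the dried loaf overheat by ~30%.

The literal published closure — single uniform D as tabulated, constant
P_sat on both sides, no surface latent term — remains available via
`printed_config()` (CLI: `simulate --printed`) and is exercised by the
test suite: it reproduces the total-drying weight-loss bound of 36.71%
for the control loaf.

### What the model can and cannot reproduce

With the default closure the simulated 40-min crust temperatures agree
with the published ones to within 3% (the acceptance script computes
them), and all published qualitative orderings hold on the full sweep:
crust temperature and weight loss increase with oven temperature, and the
control formulation exceeds the guar formulation in both at every oven
setting.

The published weight-loss *percentages* (35.11% control / 20.37% guar at
190 °C) are not reproduced, and a surface energy budget shows they cannot
be under the stated surface coefficients: with h = 10 W/(m² K) and
eps = 0.9, the integrated surface heat input over 40 min at 190 °C is
roughly 5-7 MJ/m², while evaporating 35% of the loaf's mass requires
about 12 MJ/m² of latent heat alone, before any sensible heating. The
default model evaporates as much water as the energy supply allows
(≈ 12.8% control, 11.0% guar); configurations that do reach the published
percentages (the literal closure) only do so by removing water with no
latent-heat cost, and then fail every other comparison. Both numbers are
computed, not asserted: the acceptance suite runs the default model
against the published endpoints and deliberately leaves the two
weight-loss checks failing.

### Weight loss

The published work does not define its weight-loss percentage; the
package uses the mass-based definition on the initial wet mass,
`WL = 100 (W0 - Wbar) / (1 + W0)`, with `Wbar` the volume-weighted
cross-section mean of W. `W0` is read from the parameter file as
dry-basis by default; a `wet` basis mode converts it first. Total drying
of the control loaf (W0 = 0.58) gives the bound 36.71%.

### Initial temperature

The parameter table lists 293 K, but every reported crust-temperature
curve starts at 24 °C; the default initial temperature is therefore
297.15 K so that t = 0 reporting matches, with the tabulated value
selectable (`T0=293.0`).

## Numerics

Node-centered conservative finite volumes on a uniform radial grid
(default 101 nodes): cell measures are exact annulus integrals `∫ r dr`,
the axis node is a half-cell (which handles the 1/r singularity without
special-casing), and interior face fluxes are second-order central
differences. The semi-discrete system is integrated with SciPy's BDF
method (rtol 1e-6, atol 1e-8, max step 5 s so the narrow Cp peak cannot
be stepped over), with an analytical Jacobian sparsity pattern
(tridiagonal blocks plus the local Cp(W) and surface Ps(Ts) couplings).
Implicit-stage trial values are clamped to the property correlations'
domains before evaluation. A default 40-minute bake solves in about one
second.

Degenerate-input handling: the evaporative exchange is multiplied by a C1
smoothstep in `Ws` (ramp width 0.1% of W0) so the flux vanishes
continuously at local dry-out — without this, the near-step water
activity makes the boundary flux discontinuous at W = 0 and the
integrator stalls. Moisture driven below zero by discretization error is
clipped in the stored fields and counted in the result metadata
(`w_clip_events`; zero in all default runs). Grid convergence is asserted
in the tests (halving the spacing changes the 40-min crust temperature by
< 0.1%), and a sealed-boundary run conserves volume-integrated water to
1e-8 relative. A constant-property, convection-only configuration is
checked against the classical Bessel-series solution for an infinite
cylinder with a Robin boundary (60 series terms, agreement to 0.5%).

## Lab reductions

Calorimetry follows the three-stage mixing method: flask calibration
`Hf = [Mcw Cw (Te-Tcw) - Mhw Cw (Thw-Te)]/(Thw-Te)`, capsule calibration
`Hc = (Hf + Mcw Cw)(Te-Tcw)/(Tc-Te)`, and sample reduction
`Cp = [(Hf + Mcw Cw)(Te-Tcw) - Hc(Tm-Te)]/[Mm (Tm-Te)]`. The bracket
placements in the source are ambiguous; the implemented ("tight")
grouping treats `Hf + Mcw Cw` as the combined flask-plus-water heat
capacity, which is the physically meaningful aggregate, and a "loose"
alternate is selectable. Every reduction is validated by a synthetic
generator that inverts it exactly.

Hot-wire conductivity is `k = I² R' / (4 pi S)` with `R'` the resistance
per unit length (derived from the 235 mm / 11.49 Ω wire by default;
dimensional analysis of the line-source solution requires a per-length
power, and a literal total-resistance mode is retained). `S` is the OLS
slope of temperature against ln(t); the automatic window search scans all
contiguous windows of at least half the samples and keeps the highest-R²
window (earliest on ties), which excludes the early lag and late
saturation flanks of real traces. The slope is invariant to the time
unit.

## Synthetic data

The generator reproduces the study design — 5 oven temperatures × 8
sampling times (5-40 min) × 2 formulations × 3 replicates (240 replicate
rows) — by sampling the deterministic model and adding independent
Gaussian noise per replicate (defaults sd 1.5 K for crust temperature,
0.8 percentage points for weight loss; chosen at the scale of
thermocouple and balance repeatability, and nothing downstream depends on
the exact values). Hot-wire traces follow the line-source model at the
logger's 3 s cadence with the line power inside the instrument's 2.5-6
W/m range and the total rise clamped to the observed 5-14 K band;
calorimetry records are constructed by inverting the reductions. All
randomness flows from one explicit seed.

What this does and does not show: passing round-trip tests demonstrate
that the reductions are exact inverses of their measurement models and
that the pipeline is deterministic and correctly plumbed; they cannot
validate the model against real ovens or real dough, which exhibit sensor
drift, spatial oven nonuniformity, batch-to-batch dough variability, and
volume/porosity changes that the generator (and the model) deliberately
omit.

## Validation

Predicted-vs-experimental quality is summarized by quadratic least
squares `predicted = a2 x² + a1 x + a0` with x the experimental value,
pooled across the five oven settings, one fit per formulation and target;
`R² = 1 - SSres/SStot` about the mean (a constant predicted series
reports R² = 0). On noiseless model-generated pairs the fit recovers the
generating coefficients to 1e-6 with R² ≥ 0.999999. The percent-increase
summary is `100 (high - low)/low`; the published guar figure 37.12% is a
rounding of 37.13 and is matched to ±0.02 points. The endpoint report
compares a sweep's 40-min summaries with the packaged published table,
one row per formulation and oven temperature, with explicit gap rows for
unmatched keys.

## Known limitations

- One-dimensional radial geometry; no volume change, porosity evolution,
  or internal pressure-driven vapor flow.
- `h` is constant over the bake and shared by both formulations; `kg`
  follows from it by one analogy with a single empirical correction.
- `D_crumb` is a calibrated effective parameter (two values, one per
  formulation), not an independently measured one.
- The water-activity relation is used as printed; its near-step shape
  means sorption equilibrium plays no role except at complete dryness.
- The published weight-loss percentages are energetically inconsistent
  with the published surface coefficients (see above) and are not
  reproduced by any energy-consistent configuration of this model.
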