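# Methods

This note documents the model behind `wadertherm`: the equations, the
parameter defaults and their provenance class (measured quantities vs
modelling choices), the numerical machinery, and the limits of what the
test suite demonstrates.

## Body geometry

An animal is a set of primitive shapes: an ellipsoidal torso, a
cylindrical (elliptical cross-section) neck and legs, and truncated-cone
head and beak.  Surface areas use the Thomsen approximation for
ellipsoids (p = 1.6075, error < 1%) and Ramanujan's first perimeter
approximation `C ≈ π[3(a+b) − √((3a+b)(a+3b))]` for elliptical
cross-sections (within 0.5% of the exact integral up to aspect ratio 5,
verified against quadrature).  The elliptical frustum volume is
`(h/3)(S₁ + √(S₁S₂) + S₂)`, which reduces correctly to the cylinder and
cone limits.

**Density adjustment.**  Morphometry measured from photographs carries
foreshortening error, while body mass is weighed directly.  If the
implied whole-body flesh density differs from 633.3 kg/m³ (plucked-bird
flesh density) by more than 5%, every linear flesh dimension is scaled
by the single cube-root factor that restores the target exactly.  A
common factor preserves all aspect ratios and is idempotent; per-part
adjustment is not identifiable because part masses are themselves
allocated by volume.  Feather depths are measured directly and are not
scaled.

**Night posture.**  While roosting the bird stands on one leg with the
head, neck, beak and second leg tucked into the torso plumage.  The
model collapses the plan into an enlarged ellipsoid holding the summed
flesh volume of those parts (torso axis ratios and torso feather layer
retained) on one unchanged leg.  Flesh volume is conserved to 1e-9
relative; the posture is applied between 20:00 and 5:59.

## Microclimate

Hourly series come either from directly measured hourly records (passed
through unchanged) or from daily extremes expanded by piecewise-cosine
interpolation between consecutive extremes: the minimum at
sunrise + offset, the maximum at solar noon + offset, wrap-around to the
next day's minimum.  Values never leave [min, max].  Relative humidity
is anti-phased with temperature.

Solar flux is a clear-sky solar-position model: declination and hour
angle give the zenith angle; the horizontal global flux is
`S₀ · τ^m · cos Z` with S₀ = 1361 W/m², broadband transmittance
τ = 0.72 and Kasten–Young air mass m; cloud multiplies the flux by
`1 − 0.65 c²`.  Treating the transmitted flux as the global (direct plus
diffuse) total keeps the overhead-sun limit at `S₀τ` exactly.  Sky
radiant temperature uses Idso's vapour-pressure clear-sky emissivity
(monotone in humidity) blended linearly to blackbody at full cloud.
Wind is interpolated to animal height with a log profile (roughness
0.02 m, reference 2 m).  Ground-surface temperature defaults to air
temperature — the validation scenarios are birds standing on pond water
or saturated shoreline, and no soil heat-conduction submodel is
attempted.

## Feather-layer insulation

The coat is characterised by element diameter d (18.75 µm), areal
element density n (14 400 cm⁻²), feather length and resting layer depth
(dorsal/ventral, per part).  Effective conductivity is a parallel
combination:

* still-air conduction weighted by the air volume fraction,
* keratin conduction (k = 0.20 W m⁻¹ K⁻¹) weighted by the element
  volume fraction `f = n·(πd²/4)·(ℓ/D)`,
* a radiative term `4σT³·L` with photon free path
  `L = 1/(β + 1/D)`, extinction `β = (n·ℓ/D)·d`, so an empty layer
  reverts to unobstructed radiation across the depth D.

If f would exceed 0.95 the element density is reduced to fit and a
warning is emitted.  In the realistic plumage regime (d ≥ 15 µm,
n ≥ 10⁴ cm⁻²) conductivity is monotone non-decreasing in diameter,
density and temperature, and layer resistance D/k is monotone in depth;
for very thin, sparse elements the radiative-blocking effect can
marginally dominate the added conduction, so the property tests pin the
realistic regime only.

**Ptiloerection** interpolates layer depth linearly from the resting
depth (level 0) to the full feather length (level 1) with areal density
unchanged; the diluted coat always has higher thermal resistance.  The
physical bound depth ≤ feather length is the only cap.

The torso keeps separate dorsal (sky-facing) and ventral
(ground-facing) resistances in parallel; other parts use the mean
layer.  Coat conduction uses the geometric mean of the skin and outer
surface areas, which is exact for spherical shells and within ~2% for
the cylindrical ones at these thicknesses.

## Heat balance

Each part solves `(T_core − T_s)/R_internal = Q_out(T_s)` for the outer
surface temperature T_s by bracketed root finding, where R_internal
stacks the distributed-generation flesh term (`R²/4kV` cylinder-like,
`c²/6kV` ellipsoid), the torso fat slab (thickness = fat mass /
(900 kg/m³ · torso area), conductivity 0.2 W m⁻¹ K⁻¹ — a standard
adipose value, exposed in config), and the coat.  Q_out comprises:

* convection `h·A·(T_s − T_air)`.  h is the larger of the Hilpert
  cylinder-in-crossflow correlation and the Churchill–Chu free-convection
  correlation at film-temperature fluid properties, multiplied in air
  by a surface-texture enhancement of 1.5: measured convection from
  rough, irregular animal shapes exceeds smooth-cylinder engineering
  correlations by roughly 1.3–1.7×, and the mid-range value is adopted
  once for all air-side exchange.  Wetted skin in water is smooth and
  the water-side coefficient carries no enhancement.
* grey-body long-wave exchange (ε = 0.98) split by configuration
  factors 0.5 to sky, 0.3 to ground, and the remaining 0.2 to
  surroundings at air temperature.
* absorbed solar `(1 − reflectivity) · 0.5 A · S` (orientation-averaged
  silhouette of half the surface area).
* cutaneous evaporation over the 0.2% free-water skin fraction via the
  Lewis analogy mass-transfer coefficient.

Respiratory evaporation closes a small fixed point with the metabolic
rate: ventilation = O₂ demand (20.1 kJ/L O₂) / (extraction × 20.95%),
exhaled air saturated at core temperature (no nasal counter-current
recovery is modelled), inhaled at ambient.  Panting is a drop of
extraction efficiency from 31% to ~2.1%, moving more air per unit
oxygen.

**Heat ↔ metabolic rate.**  The activity increment of the target rate
releases 80% of its energy as heat (20% leaves as external work);
thermogenesis demanded beyond the target's heat output is produced at
unit efficiency, since shivering does essentially no external work.  In
chamber conditions with a basal target this makes metabolic rate and
heat production identical, which is also how the minimal-conductance
statistic `MR/(T_core − T_a)` is computed.

## Counter-current appendages and wading

Appendage (leg, beak) average temperature follows
`clamp(T_ambient_local + ΔT_min + elevation, floor, ceiling)` with
ΔT_min = 1 °C (legs track air to within ~1 °C in thermal images down to
~4 °C air), floor 3 °C (freezing protection) and ceiling = body core
40.7 °C.  The elevation term represents venous shunting away from the
counter-current vessels and is raised body-wide during heat stress.
Appendages are treated as near-isothermal (tendon and bone, 1.3–1.7 cm
diameter): a 1 mm conductive tissue shell separates core from skin.

A wading leg is split at the waterline: the submerged segment takes
water temperature as its local ambient and exchanges by water-phase
convection only; the emergent segment keeps full air-side exchange.
The hour's energy mixes the wading and dry solutions by the fraction of
the hour spent wading.  Salt water alters only the fluid property
table.

## The thermoregulatory cascade

Each hour has a target metabolic rate (activity multiplier × BMR while
the sun is up, BMR at night).  The achieved rate must land within ±5%
of the target; mechanisms engage strictly in order, each bisected to
the band or saturated before the next starts:

* cold side: ptiloerection (0→1) → vasoconstriction (flesh conductivity
  0.5→0.4 W m⁻¹ K⁻¹) → core drop (40.7→37.7 °C).  If all saturate, the
  residual requirement is a thermoregulatory cost.
* hot side: vasodilation (0.5→2.5 W m⁻¹ K⁻¹) → appendage elevation up
  to the 40.7 °C ceiling (appendages warm before any other body part).
  If those saturate the bird is flagged **heat-stressed**; the reported
  rate is the maximum sustainable without a core rise, while panting
  (no simulated energy cost) and, as a last resort, a core rise to
  44 °C balance the remaining heat.  Raising the flag at this point —
  before panting rather than after a core rise — is what makes the
  upper critical temperature "the point where basal metabolism cannot
  be held without panting", the conventional reading of chamber
  curves.

The vasomotor conductivity range [0.4, 2.5] W m⁻¹ K⁻¹ brackets the
resting flesh value 0.5 and is exposed in configuration; only the
resting value is a measured quantity.  The solver is deterministic
(pure bisection, ≤ 60 whole-body evaluations per hour, results cached
by cascade state) and bit-reproducible.

## Energetics

Behavior proportions exclude out-of-sight records from numerator and
denominator and are normalised; activity multipliers are the
cost-weighted mean (reported to two decimals), with behavior costs in
×BMR: rest-sleep 1, rest-alert 1.9, forage 1.95, walk 3.5, comfort
1.95, calls 1.15, dance 3.  An aggregated "social" category is priced
at the call cost by default, with dance separable when raw behaviors
are recorded.  The whole-day multiplier assumes a 15 h active / 9 h
rest split (`(15m + 9)/24`, one decimal); daily energy is
multiplier × BMR × 86.4 kJ.

The DLW reduction is the one-pool model
`rCO₂ = (N/2.078)(k_o − k_d) − 0.0062·k_d·N` (N in moles, rates per
day), with decline rates from log-linear washout of background-corrected
enrichments, pool size by the intercept (dilution) method, and energy
via a diet-derived respiratory quotient using per-gram substrate
equivalents (carbohydrate 17.5 kJ/g at RQ 1.0, fat 39.6 at 0.71,
protein 18.1 at ~0.81).

## Experiments

Chamber sweeps run −50…50 °C in 1 °C steps at wind 0.01 m/s, RH 5%, no
sun, all radiant surfaces at air temperature; wading options submerge
the legs fully or to half length in water at air temperature floored at
0.1 °C (ice water).  LCT is the lowest air temperature whose achieved
rate is within +5% of basal; UCT the lowest at which the heat-stress
flag is set; both are reported at the 1 °C sweep resolution without
sub-degree interpolation.  Minimal conductance is the mean of
heat/(40.7 − T_a) over −25…0 °C.

Sensitivity runs freeze the cascade (counter-current offsets stay
active) and report the mean metabolic-rate change over −25…35 °C under
one-at-a-time perturbations; non-positive-rate points are excluded from
the mean.

The validation driver couples hourly weather, per-day activity targets,
wading schedules and the night posture, integrates achieved rates to
daily kJ, and compares against the time-energy-budget expectation
computed with the same active/rest split.

## Synthetic study conditions

The generator emulates the validation study's envelope: clear
late-September days with air spanning 0.5–27.6 °C, pond water
15–20 °C, overnight roosting in shin-deep water (0.094 m) at wading
fraction 1, daytime wading fractions up to 0.5, and 30-s instantaneous
behavior sampling (1 800 samples/day) with a 5.8% out-of-sight rate.
Day one pins the stated temperature envelope exactly; later days jitter
inside it.  Everything is driven by one `numpy` generator seed and is
bit-reproducible.  What it does **not** emulate: weather fronts and
cloud, wind gustiness, within-hour behavioral thermoregulation, or any
spatial microhabitat choice — so passing validation shows the model's
internal consistency under study-like conditions, not fidelity to any
particular field season.

## Numerical choices

* Surface balances: `scipy.optimize.brentq`, bracket ±60–80 °C around
  the driving temperatures, xtol 1e-9 — energy closure at a converged
  part is better than 1e-6 of the flux scale.
* Cascade bisection stops on band entry or an interval below 1e-6;
  mechanism saturation is checked before bisection, which also audits
  the engagement ordering.
* Respiration fixed point: ≤ 8 iterations, convergence ~1e-10 W.
* Free convection at zero temperature difference uses a 0.1 K floor in
  the Rayleigh number to keep coefficients finite.
* The chamber curves, and hence LCT/UCT, are deterministic; the
  validation scenario uses 4 synthetic days at 1 h resolution — enough
  for the period-mean energy comparison while keeping a full test run
  in seconds.

## Known limitations

* The saturated-coat minimal conductance of the 5 kg configuration
  computes to ≈ 0.37 W/°C, below typical non-passerine allometric
  predictions (≈ 0.42 W/°C for this mass); the critical temperatures
  and all wading/counter-current contrasts are nevertheless in their
  expected ranges.  A mean conductance much above 0.4 W/°C cannot
  coexist with a −1 °C LCT on a near-linear sub-thermoneutral curve,
  so the low value is an internally consistent consequence of the coat
  model rather than a free parameter.
* No wind penetration of the coat, no wet plumage, no heat storage
  (every hour is steady-state), no ground conduction through the feet,
  and no tucked-leg resting posture.
* Panting carries no energy cost, so above the UCT the reported
  sustainable rate declines instead of rising as a real
  Scholander–Irving curve would.
* The leg is isothermal along its length; the real gradient down a
  counter-current leg is not resolved, only its average.
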