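# Methods

## The model

`mpsink` simulates the vertical fate of biologically active microplastic
(MP, roughly the 0.1–5 mm fraction) in independent one-dimensional ocean
columns. Three MP tracers are carried, all in particles m⁻³:

* **MP** — free (unattached) particles,
* **MP_A** — particles aggregated in marine snow,
* **MP_Z** — particles bound in zooplankton faecal pellets.

Each tracer obeys d(MP)/dt = T + S, with T the vertical transport terms and
S the local sources minus sinks:

```
S(MP)   = Emis − S(MP_A) − S(MP_Z) + w_p ∂(F_R·MP)/∂z
S(MP_A) = A_upt − A_rel − w_D ∂MP_A/∂z
S(MP_Z) = P_upt − P_rel − w_D ∂MP_Z/∂z
```

Uptake into marine snow is a Monod (saturating) function of the free-MP
concentration applied to the rate of marine-snow formation,

```
A_upt = MP/(k_P + MP) × source(D_A) × F_A,
```

where `source(D_A)` (mmol N m⁻³ d⁻¹) is converted to a maximum number of
newly formed aggregates using Redfield C:N = 106:16 and a characteristic
aggregate carbon content of 8.8 µg C — each new aggregate can capture at
most one particle. Release is first-order at the temperature-dependent
detrital remineralisation rate, `A_rel = μ_D(T)·MP_A`, and identically for
pellets, `P_rel = μ_D(T)·MP_Z`.

Zooplankton ingestion extends the Holling type-II grazing response with MP
as an additional prey item. Free MP is converted to the grazing currency
(mmol N m⁻³) via particles → grams (236×10³ t ≡ 51.2×10¹² particles) →
grams of displaced food (the substitution ratio R_F:MP) → mol N (Redfield
organic matter, 222.1 g per mol N). The grazed amount G_MP is converted
back to particles for the tracer update (P_upt); 100 % of ingested MP is
egested into MP_Z — nothing is retained or metabolised. Because grazing
preferences must sum to one, raising ψ_MP lowers the preference for real
food: MP ingestion reduces zooplankton food intake. The diazotroph
preference is held at 0.1 and the remainder is split equally over the
other four prey classes.

Bound MP sinks with the detritus; a fraction F_B of the particle flux
reaching the seafloor is returned to the bottom-layer free pool, the rest
is a permanent sedimentary loss recorded in a ledger. A fraction F_R of
free MP below the surface layer rises at w_p = 1.9 cm s⁻¹; particles
arriving in the surface layer accumulate there (nothing exits through the
sea surface).

## The stand-in ecosystem

The MP equations only consume a handful of biological fluxes: marine-snow
production, pellet production, μ_D(T), NPP and grazing. These are supplied
by a deliberately minimal NPZD model with three phytoplankton classes
(mixed phytoplankton, small phytoplankton/calcifiers, diazotrophs — no
calcite tracer; calcite-ballasted detritus is assumed not to interact with
MP), one zooplankton, and two detritus classes. Functional forms: Monod
nutrient limitation with Eppley temperature scaling and a prescribed
exponential light profile; linear phytoplankton mortality; Holling-II
grazing with the zooplankton maximum growth rate capped above 20 °C
(metabolic limitation in very warm water); linear + quadratic zooplankton
mortality; linear excretion. Half of zooplankton particulate losses
(unassimilated grazing plus mortality) become pellet detritus, the rest —
with phytoplankton mortality — becomes marine snow; excretion is treated
as dissolved. Both detritus classes share one sinking law, so their sum
evolves exactly as a single-detritus model, and detritus reaching the
seafloor is remineralised into bottom-layer nutrient, which closes the
column nitrogen budget exactly.

This stand-in reproduces the *interfaces* of a full ocean biogeochemistry
model, not its dynamics: there is no seasonality, no explicit light
attenuation by biomass, no iron/phosphorus limitation, no microbial loop
pools, and the three phytoplankton classes compete for one nutrient (in
long runs the fittest class dominates). Passing tests therefore show that
the MP mechanics respond correctly to the biological fluxes, not that the
ecosystem matches any observed ocean.

## Grid, transport and numerics

The default grid has 19 layers: 50 m surface layer, 80 m second layer (so
the second interface — where export is diagnosed — sits at 130 m), then
geometrically widening layers to a 5000 m bottom. A column carries a
nominal horizontal area; single-column runs default to the global ocean
surface area (3.6×10¹⁴ m²) so that the globally scaled emission
(F_T × waste generation × particles per tonne) maps to a realistic areal
emission flux. Waste generation starts at 2×10⁶ t yr⁻¹ in 1950 and
compounds at 8.4 % yr⁻¹ (annually; the forcing is piecewise-constant
within a calendar year).

Numerics: explicit Euler with operator splitting — (1) ecosystem sources,
(2) MP sources/sinks, (3) vertical transport, (4) seafloor exchange — at
dt = 0.5 d. Sinking and rising use first-order upwind in flux form; the
fast rise (1641.6 m d⁻¹) is sub-cycled internally to meet its CFL limit
while the user-facing step stays 0.5 d. Vertical mixing is a constant
diffusivity (2×10⁻⁴ m² s⁻¹, enhanced to 4×10⁻⁴ above 100 m) — this also
stands in for the nutrient supply that upwelling/deep mixing provide in
the real ocean. Every sink is limited so no pool can be overdrawn within
a step; any residual clipping is logged to a conservation audit, and the
global particle budget (inventory + sediment loss − emission) closes to
floating-point accuracy in stable runs. Non-finite tracers abort a run
with an "unstable" flag that the ensemble filter consumes.

Temperature is prescribed: an idealised thermocline profile (surface mixed
layer at the column's surface temperature, exponential decay to 2 °C at
depth) plus an optional linear warming trend after 2000 applied to the
upper ocean, standing in for a high-emission warming projection.

## Calibrated stand-in constants

The detrital sinking law w_D(z) = w_D0 + m_w·z and remineralisation
μ_D(T) = μ_D0·Q10^(T/10) control how much of the bound MP taken up above
130 m survives to be exported. Their source model's constants are not
published alongside the MP formulation, so they were calibrated once
against the two reported export anchors: in the tropics roughly one in
three ingested particles is exported past 130 m (uptake:export ≈ 3), and
over most of the cooler ocean at most one in two (ratio ≥ 2). The
uptake:export ratio turns out to depend almost only on the effective
remineralisation rate above 130 m, so the two anchors jointly fix the
temperature sensitivity; the result is w_D0 = 14 m d⁻¹, m_w = 0.04 d⁻¹,
μ_D0 = 0.10 d⁻¹, Q10 = 1.5 (tropical ratio 3.2, mid-latitude 2.2). These
are package defaults, configurable in the `ecosystem`/`transport` config
blocks.

## Parameters that matter

| name | meaning | default/range | units |
|---|---|---|---|
| F_T | waste fraction entering as MP | sampled 0–1 | – |
| F_R | free-MP fraction with rise rate | sampled 0–0.1 | – |
| F_A | marine-snow aggregation fraction | sampled 0–1 | – |
| k_P | snow-uptake half-saturation | sampled 0–1000 | particles m⁻³ |
| F_B | seafloor return fraction | sampled 0–1 | – |
| ψ_MP | grazing preference for MP | sampled 0.1–0.3 | – |
| R_F:MP | food:MP substitution ratio | sampled 0.5–1.5 | g food / g MP |
| w_p | rise speed | 0.019 | m s⁻¹ |
| w_D0, m_w | sinking law | 14, 0.04 | m d⁻¹, d⁻¹ |
| μ_D0, Q10 | remineralisation law | 0.10, 1.5 | d⁻¹, – |
| dt | time step | 0.5 | d |

The packaged fixtures `no_bio`, `test_lo`, `test_hi`, `test_med` are the
published sample parameterisations (e.g. TestMed: F_T 0.276, F_R 0.011,
F_B 0.528, F_A 0.092, k_P 615.508, ψ_MP 0.193, R_F:MP 0.993).

## Hypercube screening

The seven parameters are sampled with a Latin-hypercube design: n
equal-probability strata of a truncated normal centred mid-range
(sd = range/4 — the published description says "a normal distribution"
without parameters, so the shape is a documented package choice), one
draw per stratum, strata permuted per parameter. k_P is additionally split
across the sub-ranges 0–1, 1–100, 100–1000 particles m⁻³ with equal
member counts. Complexity is increased incrementally: `no_bio` (F_T, F_R
only), `snow_only` (plus F_A, k_P, F_B), `full` (all 7). Members are
screened with six plausibility criteria — numerical stability, inventory
below time-integrated input, a pollution-rate band (~4 % ocean-entry
estimate with a 10× guard), a generous aggregation-rate band, order-of-
magnitude agreement with an independent 2010 inventory, and the
entrainment/release profile signature (a subsurface maximum below a local
minimum). All bands are configurable; the defaults are wide because the
source statements are qualitative, and no particular surviving-member
count is claimed.

## Scale of the shipped experiments

Tests and the acceptance script run single columns for 70–150 years at
dt = 0.5 d with a 10–20 year ecosystem spin-up, and desk-scale ensembles
(a handful of members over a few years); the full 700-member,
multi-century screening is supported through the same API and CLI
(`mpsink ensemble --n 700`). These problem sizes are the package's chosen
desk-scale defaults.

## Known limitations

* One-dimensional columns: no horizontal transport, so basin-scale
  accumulation patterns are out of reach by construction.
* The ecosystem is a stand-in; absolute PON export efficiencies are
  plausible but not tuned to any observed field.
* No size classes, polymer types, explicit biofouling, photodegradation,
  or MP effects on aggregate/pellet sinking speeds.
* Emission enters the surface layer only, with a user-supplied column
  weighting instead of a gridded coastal/shipping source map.
* The warming scenario is an idealised prescribed trend, not a coupled
  climate response.
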