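# Methods

`ecosink` implements a diagnostic (satellite-LAI-driven) terrestrial
carbon-cycle model and the factorial experiment machinery used to attribute
the accumulated land carbon sink to its drivers. This note documents the
model equations, the synthetic world the package simulates, the numerical
choices, and what the test suite does and does not establish.

## Canopy photosynthesis (two-leaf upscaling)

Daily gross primary productivity is computed per pixel as

    GPP = GPP_sun · LAI_sun + GPP_shaded · LAI_shaded
    LAI_sun = 2 cosθ · [1 − exp(−0.5 Ω LAI / cosθ)],  LAI_shaded = LAI − LAI_sun

where Ω ∈ (0, 1] is the foliage clumping index and θ the daily mean solar
zenith angle (cosine-weighted over daylight; polar night is flagged and
yields zero GPP). Leaf net assimilation follows the standard C3
biochemical model, `A = min(Wc, Wj) − Rd`, with Michaelis constants,
CO₂ compensation point and dark respiration at 25 °C scaled by Arrhenius
activation energies (Bernacchi-type constants; see
`src/ecosink/params/default.yaml`). Stomatal conductance is Ball–Berry,

    gs = g0 + g1 · max(A, 0) · h / ca · β,

with h the relative-humidity fraction and β ∈ [0, 1] the soil-moisture
scalar; defaults g1 = 8, g0 = 0.01 mol m⁻² s⁻¹. The coupled (A, gs, ci)
system — Farquhar A(ci), Ball–Berry gs(A), diffusion A = (ca − ci) gs/1.6 —
is solved by vectorized bisection on ci (45 halvings of [10⁻⁶, ca + 400],
locating ci far below 10⁻⁶ p.p.m.; the residual is monotone increasing in
ci on the physical branch).

Numerical/structural choices, made where the underlying description is
open:

* **Daylight integration**: 3-point Gauss–Legendre quadrature over the
  diurnal cycle, with instantaneous shortwave distributed ∝ cos(zenith);
  the daily mean θ enters only the LAI partition.
* **Direct/diffuse split**: two-piece linear in the daily clearness index
  (fully diffuse below 0.35, 23 % diffuse above 0.75). Shaded leaves
  receive the canopy-mean absorbed diffuse PAR; sunlit leaves additionally
  the mean direct beam (spherical leaf-angle distribution, G = 0.5).
* **Sunlit/shaded Vcmax**: exponential nitrogen extinction with depth at
  kn = 0.3, sunlit leaves at mean depth LAI_sun/2, shaded at
  LAI_sun + LAI_shaded/2.
* **Leaf temperature** equals daily mean air temperature; no energy-balance
  iteration (a stated fidelity limit).
* **C4 vegetation** is treated as C3 with an elevated effective Vcmax per
  land-cover class — a flagged limitation, adequate for a synthetic world.
* GPP per leaf class is gross assimilation max(0, A + Rd); leaf dark
  respiration is then accounted inside maintenance respiration, avoiding
  double counting.

## Carbon–nitrogen pool model

Carbon is tracked in 4 biomass pools (leaf, stem, coarse root, fine root)
and 9 soil/litter pools (surface structural/metabolic litter, soil
structural/metabolic litter, coarse woody litter, surface microbe, soil
microbe, slow, passive), Century-style. Each day, per pixel:

1. autotrophic respiration: maintenance `Σ r_i B_i Q10^((T−20)/10)` plus
   growth respiration as **25 % of GPP** (taken literally; a config switch
   `growth_respiration_basis` offers the more common 25 % of
   GPP − maintenance, since the literal reading is unusual);
2. NPP = GPP − AR, allocated to biomass pools by fixed coefficients
   (0.30/0.30/0.15/0.25); negative NPP draws pools down proportionally,
   and maintenance is capped so the drawdown is always fundable — this
   keeps the daily carbon closure ΔC = NPP − HR exact;
3. litterfall by base turnover, plus the disturbance pathway: when LAI
   drops day-over-day by more than the seasonal climatological drop plus a
   5 % threshold, the excess fraction of *each* biomass pool transfers to
   its litter receivers (this is how LAI-assimilating models convert
   observed canopy loss into a respiration source);
4. decomposition: donor flux `k · f_T(T_soil) · f_W(moisture) · pool`,
   split between respired CO₂ (heterotrophic respiration) and receiver
   pools by a fixed transfer matrix whose rows sum to one (validated at
   load); clay content reduces slow/passive turnover. Soil temperature is
   an exponentially damped (7-day memory) air temperature; moisture is a
   single-bucket model with texture-derived capacity, Hargreaves-type ET
   demand, and overflow runoff. Turnover rates and respired fractions are
   Century-like defaults recorded in the parameter file — the source
   analysis names the pools but no rates, so these values define this
   package's world rather than replicate anyone's calibration.
5. nitrogen: available mineral N = pool + deposition + net mineralization,
   with net mineralization taken as 10 % of HR/CN_soil (the rest is
   microbial immobilization — without this the mineral pool is never
   limiting and deposition could not affect the sink); uptake is
   demand-driven (positive NPP / plant C:N of 40), temperature-scaled, and
   saturating in availability (half-saturation 2 g N m⁻²). Absorbed N
   follows carbon allocation into the leaf pool; leaf N concentration
   scales Vcmax linearly in [0.5, 1.5] around the reference
   0.025 g N (g C)⁻¹. There is no leaching term, so the daily balance
   inputs − uptake = Δmineral is exact bookkeeping.

NEP = GPP − AR − HR holds exactly by construction, and the acceptance
suite checks daily carbon closure to 10⁻⁹ relative on 10⁴ random states.

## Spin-up and the pre-period transient

Pools are initialized at dynamic equilibrium for the first historical year
("1901"): one climate year is drawn (seeded) from the first decade, mean
NPP is estimated from a forward probe under period-start CO₂/N deposition
and the 1982–1986 LAI climatology, and the 13-pool linear steady state
`(I − Tᵀ) f = u`, `x = f/k` is solved per pixel. Because the verification
gate (|annual NEP| < 0.5 % of annual GPP) is tighter than what the
mean-field solve plus a few settle years can deliver (seasonal covariances
and the maintenance–biomass feedback leave ≈1 % residuals), the state is
refined by a Newton solve on the annual map: one base year plus 13
pool-perturbed years give the per-pixel Jacobian J of the year-advance map
F, and `(I − J) Δx = F(x) − x` is solved directly. One Newton iteration
typically lands the residual near 10⁻³–10⁻⁴; the loop verifies after each
iteration and keeps the best state. The transient then integrates the
historical drivers to the analysis period with LAI pinned to the baseline
climatology, verifying that accumulated NEP equals the total pool change
(10⁻⁶ relative).

## The factorial attribution experiment

Baseline conditions: CO₂ and N deposition frozen at their period-start
(1981) values; LAI replaced by the 1982–1986 composite-date climatology
(seasonality preserved — a scalar annual mean would break the daily canopy
model); meteorology of each simulated year replaced by a whole calendar
year drawn uniformly **with replacement** (nine source years cannot cover
36 otherwise) from 1971–1979, one draw shared by all pixels to preserve
spatial weather coherence. The same resampling seed is shared by all six
scenarios so climate noise cancels in differences. The baseline's
accumulated NEP is the legacy effect; each driver's enhancement is the
single-factor run minus the baseline; percentages use the all-factors
accumulated sink as denominator (configurable to the enhancement-only
denominator, since the rounding of published percentages does not
determine the choice); the interaction residual is reported and never
redistributed. `make_baseline` is idempotent at fixed seed, and an
all-transient scenario returns the forcing object unchanged.

## Synthetic forcing: the stated world

The generators emulate the statistical structure of the real inputs, not
their spatial fields:

* **Meteorology**: latitude-dependent seasonal harmonics with AR(1)
  (ρ = 0.8) weather noise; default secular warming 0.15 °C/decade on
  tmax/tmin (≈1.7 °C over 1901–2016, a realistic land-surface trajectory);
  radiation from top-of-atmosphere flux times a noisy clearness index;
  gamma-distributed precipitation with 35 % wet days.
* **LAI**: base 1.6 m² m⁻² with seasonal amplitude 0.8, composite sampling
  every 16 days, Gaussian composite noise (σ = 0.1), and a greening trend
  of 0.028 m² m⁻² per decade — calibrated so the area-weighted global mean
  rises from 1.6 to 1.7 over 36 years, the observed greening magnitude.
* **CO₂**: piecewise-linear through (1901, 296), (1981, 340.13),
  (2016, 404.20) p.p.m. — the period endpoints are the observed values and
  the 1981 anchor matters for the fertilization effect.
* **N deposition**: global totals through (1901, 12), (1981, 42.3),
  (2016, 58.9) Tg N yr⁻¹ (the 1981–2016 ramp integrates to the 0.30 Pg N
  cumulative excess), disaggregated to pixels by a fixed seeded log-normal
  surface that conserves the global total each year.
* **Calendar**: 365 days everywhere; pixel areas are cos-latitude
  weighted; all global totals in Pg C via a single conversion function.

What a green test does **not** establish: the synthetic world has no real
geography, no satellite-retrieval artifacts, no land-use change, and its
absolute sink magnitudes are arbitrary (they scale with the synthetic
grid's area and the chosen productivity constants). The acceptance
experiment therefore asserts the *sign pattern* of the attribution — CO₂
and LAI positive, N deposition non-negative, climate warming negative,
legacy positive after a rising-driver pre-period — plus exact arithmetic,
oracle equivalences, and conservation, never the published magnitudes.

## Known limitations

* Single-bucket hydrology and damped-air soil temperature instead of a
  multi-layer scheme; no energy balance.
* The mineral-N budget has no leaching; the net-mineralization fraction is
  a stand-in for explicit per-pool N tracking.
* The legacy estimate inherits the (paper-mirroring) design choice of a
  single random spin-up climate year: the offset between that year and the
  baseline resampling window contributes to the baseline NEP. Differences
  between scenarios are immune (shared seeds).
* On small grids the N-deposition effect can be near zero (the sign test
  is ≥ 0 for that reason).
* `run_scenario` aggregates to annual per-pixel fluxes in-run; storing
  full daily flux grids for all six scenarios would need O(100 MB) per
  scenario at 16×16 and is deliberately not done.
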