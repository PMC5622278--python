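# Methods

This note records the model structure, the parameter choices that matter,
what the synthetic fixtures do and do not emulate, and the numerical
decisions taken where the design was genuinely open.

## Spatial structure and the daily loop

The landscape is a grid of cells (equal areas; 4-neighbour, edge-sharing
connectivity, since edges — not corners — carry designations such as
ditches, hedgerows and margins).  Each cell holds a three-layer soil
profile (230 mm layers by default), topsoil organic pools and at most one
crop.  One day advances every cell through a fixed order: management
events; bulk-density/retention refresh; atmospheric deposition; rain
partition and runoff with lateral routing; the drainage cascade; soil
evaporation; crop development, water stress/transpiration, growth, uptake,
translocation and senescence; grazing; decomposition and mineralisation;
phosphorus re-equilibration; nitrification; denitrification; leaching.
Surface processes precede profile transport so fertiliser applied on a
rain day is exposed to that day's runoff and leaching.

Cells are processed in descending elevation (ties broken by cell id), so
runoff cascades across many cells within one day.  Runoff is split among
strictly-downslope neighbours and ditch edges proportionally to slope;
dissolved NH₄⁺, NO₃⁻ and P travel at source concentration and partition at
each receiving cell like the water (the infiltrating share joins the
topsoil pools, the rest passes on).  A closed depression re-infiltrates its
runoff up to saturation and ponds the remainder.  Whether layer-3 drainage
also discharges to the ditch is a grid flag (on by default, matching
drained lowland grassland catchments).

Every record carries closure audits.  Daily per cell: water closes to
< 10⁻⁶ mm and C, N, P to < 10⁻⁹ (t or kg ha⁻¹); the acceptance suite runs
these over a decade.

## Soil water

Retention anchors (θ at saturation, −5, −10, −40 and −1500 kPa) come from
the continuous HYPRES pedotransfer regressions (topsoil/subsoil variants,
θ_r = 0.01, van Genuchten form), with organic matter = 1.724 × organic C
(Van Bemmelen).  Infiltration fills layers to field capacity from the top;
the excess from layer 3 is drainage.  Runoff is capacity excess over a
slope-reduced surface storage S = (1 − ḡ/g_max)·S_max with S_max = 10 mm
and g_max = 0.2 (a ceiling typical of UK farmland); the layer-1 intake
bound is the deficit to saturation (configurable to field capacity).
Air-dry water content is 0.33·θ_wp; it floors soil evaporation and defines
the top-20-mm mixing water for runoff chemistry.  Potential ET is a
classical Penman form (net radiation from the FAO geometry plus the
2.6(1 + 0.536 u)(e_s − e_a) wind function), split between soil evaporation
and transpiration by canopy cover 1 − e^{−k·LAI}.

Topsoil bulk density follows organic carbon through harmonic mixing of an
organic-matter bulk density (0.224 g cm⁻³) with a mineral-fraction bulk
density approximated by a smooth texture surface
BD_min = 1.35 + 0.0045·sand% − 0.0020·clay% (clamped to 1.1–1.8 g cm⁻³),
standing in for the published graphical nomogram.  The property the model
relies on — BD strictly decreasing, and topsoil thickness increasing, with
organic C at conserved soil mass — holds by construction; absolute BD
values for ordinary arable topsoils land in the 1.1–1.5 g cm⁻³ range.
Thickness rescales as δ·BD = const and the retention anchors are refreshed
daily.

## Organic matter and stoichiometry

Four active pools with annual rate constants k = {DPM 10, RPM 0.3,
BIO 0.66, HUM 0.02} yr⁻¹ and a clay-dependent CO₂:(BIO+HUM) ratio
x = 1.67(1.85 + 1.60 e^{−0.0786 clay}); the retained fraction splits
BIO:HUM = 46:54.  The temperature modifier is
47.91/(1 + e^{106.06/(T+18.27)}); the moisture modifier is 1 until the
topsoil deficit passes 44.4 % of (θ_fc − θ_wp)·δ and then declines linearly
to 0.2; soil cover multiplies by 0.6.  Inert organic matter defaults to the
Falloon estimate 0.049·TOC^1.139.

N and P stocks parallel the C pools.  BIO and HUM hold fixed ratios
(C:N 8.5; C:P 50 and 100); DPM and RPM ratios are whatever the mixture of
their inputs implies (crop residue splits 59:41 DPM:RPM; farmyard manure
49:49:2 DPM:RPM:HUM, with the HUM share taking its fixed stoichiometry and
the fresh pools carrying the balance so inputs conserve exactly).  Positive
net mineralisation enters the topsoil NH₄⁺ pool (or available P);
immobilisation draws NH₄⁺ before NO₃⁻ (available before non-available P).
If either mineral store cannot cover the demand, the whole day's
decomposition is cancelled.  Extending the halting rule to P (the
stated behaviour covers N) keeps daily stoichiometric closure exact with
non-negative pools; with equilibrium initial pools the P guard never fires
in any shipped scenario.

Equilibrium initialisation scales the plant-input magnitude by bisection so
that steady-state active C + IOM matches the measured TOC within 0.1 %.
Each bisection step is a forward run advanced year-by-year; because the C
dynamics are linear, the one-year daily map is precomputed once (as an
affine map from five basis runs) and then iterated, which keeps spin-up
under a second without changing the dynamics.  N and P pools follow from
the equilibrium C, the input stoichiometry (DPM/RPM) and the fixed ratios
(BIO/HUM).

## Mineral nitrogen

Deposition interpolates 35 kg N yr⁻¹ (1966) to 20 kg N yr⁻¹ (2012),
clamped outside and spread as annual/365 per day, all as nitrate.
Fertiliser enters NH₄⁺, NO₃⁻ or 50:50 by form.  Runoff removes
N_Surf·W_Run/(W_Run + W_Surf) from the top 20 mm, with
N_Surf = (20/δ₁)(N_NH4 + N_NO3) and W_Surf = (θ_sat − θ_airdry)·20.
Leaching moves nitrate at pool concentration with each layer's downward
water flux, capped at the pool.

Nitrification: N₂O = 10⁻⁴·N_NH4·S_pH·(1 − WFPS), then
NO₃⁻ = max((N_NH4 − N₂O − 0.05)(1 − e^{−0.15 f_T g_M}), 0).  The cited
literature behind f(T) and g(M) is not restated in the source material, so
both are implemented as configurable saturating responses: f_T is
Q10-style (Q10 = 2, 0.5 at 10 °C, capped at 1) and g_M is the
plant-available water fraction; S_pH reuses the tent-shaped pH response
(0→1 over pH 0→7, 1→0 over 7→14) that the P module defines, the only pH
response specified anywhere in the model family.

Denitrification (top two layers only):
f(WFPS) = e^{−0.6151·[ln(WFPS/(1−WFPS))]² − 1.192} — read with natural log
and a squared log-ratio term, the symmetric form that peaks near
WFPS 0.5–0.8 and coincides with the alternative readings at WFPS = 0.5 —
and N₂O = 0.000735·N_NO3·f(WFPS)·e^{−0.00045(T−23.65)²}.  The 0.00045
width coefficient is used as printed even though a "standard deviation
5.53" narrative would imply ≈ 0.0163; the printed constant is taken as the
fitted value.  N₂ = 0.0052·N_NO3·σ(0.14975 T − 4.0)·σ(12(WFPS − 0.62)),
read as a product of two logistic factors.  Gas fluxes are jointly capped
at the nitrate pool.  Crop uptake draws nitrate from rooted layers pro rata
root fraction, at most 6 kg N ha⁻¹ d⁻¹.

## Mineral phosphorus

The equilibrium available fraction is V = (α·P_Tot + β)/P_Tot with the
upper-branch coefficients (0.113, −49.3) above the branch junction
(≈ 476 mg kg⁻¹) and (0.0201, −5.097) below — the ratio form implied by the
underlying Olsen-P vs total-P regressions, since a raw linear V would
exceed 1.  V is clamped to [0.001, 0.95] to keep RRF = V/(1−V) finite and
positive at low P_Tot (the lower branch turns negative below
≈ 254 mg kg⁻¹).  Units: pools are kg P ha⁻¹; concentrations convert
through the layer soil mass 10·δ·BD t ha⁻¹ (δ in mm, BD in g cm⁻³).

Daily transfers P_Av→NA = λ·P_Av·f_pH and P_NA→Av = λ·P_NonAv·RRF·f_pH are
applied simultaneously from same-day state; total P is conserved exactly.
With λ = 0.01 d⁻¹ a pulse of available P decays at λ(1 + RRF)f_pH per day;
at Broadbalk-like P_Tot ≈ 1050 mg kg⁻¹ and pH 7 the half-life is ≈ 65
days — ln 2/λ alone would give 69.3 d, and the two-pool analytic rate is
the reading that reproduces the stated "approximately 65 days".  Fertiliser
P splits 80/20 available/non-available.  Runoff carries the mobile fraction
(10 % of P_Av) mixed over the top 20 mm; leaching moves solution P (1 % of
P_Av) with drainage water through the same cascade as nitrate.  Uptake is
capped at 2 kg P ha⁻¹ d⁻¹.

## Crop and grass growth

Growth is dB = Q·ε·W_rf·N_NI·P_NI with Q = 0.5·global radiation·
(1 − e^{−0.6·LAI}) and ε = 3.0 (wheat) / 2.8 (grass) g DM MJ⁻¹ PAR.  Grass
ε is further scaled by a radiation ramp (1 → 0.33 over 10 → 40 MJ m⁻² d⁻¹)
and a temperature ramp (0 → 1 over 6 → 9 °C).  Development is thermal time
(base 0 °C) scaled pre-anthesis by vernalisation (40 effective days between
0 and 12 °C) and a daylength ramp (8 → 16 h); wheat runs DVS 0→1 over
1000 °C d and 1→2 over 700 °C d, which places anthesis in mid-June and
maturity by early August for autumn-sown wheat under the synthetic
climatology.  Grass is capped at DVS < 1 (no flowering).  Partitioning
tables (root/leaf/stem shares shifting to storage after anthesis) are
config data in the LINTUL lineage, not code.

Water stress: per-layer W_S is 1 between θ_a and θ_d, declines to 0 toward
saturation and toward wilting (grass: no saturation stress and a 0.4 floor
at wilting).  Actual transpiration is
ATran(l) = P_Tran·W_S(l)²·F_RL(l)/Σ W_S F_RL — the squared numerator with a
linear denominator keeps ΣATran ≤ P_Tran — additionally limited by
extractable water; W_rf = ΣATran/P_Tran, defined as 1 when P_Tran = 0.
Roots deepen 12 mm d⁻¹ to the profile depth and distribute exponentially
with 98 % of length above the rooting front.

Nutrition indices follow (content − residual)/(maximum − residual) over
leaf + stem, clamped to [0,1]; wheat leaf N maximum is
0.046·e^{−1.7·DVS} + 0.014 (grass: 0.0425), stem maxima are half the leaf
values, residual N is 0.004 (wheat) / 0.01 (grass); wheat leaf P maximum
interpolates (0, 0.0066), (0.7, 0.0036), (1, 0.0009) and holds thereafter.
Demand is the organ-deficit sum (roots/stems/leaves), met from soil up to
the uptake caps, and stops at anthesis; storage N and P fill afterwards by
first-order translocation (0.03 d⁻¹) from vegetative organs down to their
residuals.  The translocation rate and the N-stress leaf-death multiplier
(0.01 d⁻¹ at full stress) were calibrated once so that a well-fertilised
wheat crop retains a green canopy through grain fill and reaches 5–7 t ha⁻¹
at 85 % DM; heat (> 30 °C) and shading (LAI > 6) add configurable death
rates.  Dead leaves enter a standing-dead pool of which half becomes litter
daily; root death is 0.02 d⁻¹ after DVS 1.5 (crops) or 0.01 d⁻¹ once grass
is established.  All dead material returns to DPM/RPM with its own
stoichiometry.  Harvest converts the storage organ at 85 % dry matter
(g m⁻² × 0.01/0.85 → t ha⁻¹); straw export is the arable default, roots and
stubble are always incorporated.

Grazing removes intake (defaults: beef 10, dairy 16, sheep 1.5 kg DM
head⁻¹ d⁻¹ — intake is not specified in the source material, only manure
rates, so these are ordinary husbandry values) down to the 50 g m⁻²
standing-biomass floor, and deposits manure C and N per head (beef
4.03/0.22, dairy 6.45/0.35, sheep 0.45/0.02 kg d⁻¹) routed as FYM-like
organic input.  Manure and FYM P contents are not specified; C:P defaults
of 80 (manure) and 78 (FYM ≈ 45 kg P per 35 t dressing) are used.

## Trade-off optimisation

Decision vectors (fertiliser day-of-year and dose by default) evolve by
differential evolution (rand/1/bin, F = 0.7, CR = 0.9, population 40,
60 generations by default; the forced crossover component applies only when
CR > 0 so the F = CR = 0 limit is the identity).  Out-of-bounds components
reflect into range.  Selection pools parents and offspring, ranks them by
iterative non-dominated sorting and fills the next population by rank with
a crowding-distance tie-break.  Convergence — the qualitative "similar
front each iteration" — is operationalised as the rank-0 hypervolume
changing by < 10⁻⁴ relative over five consecutive generations; hypervolume
is computed exactly by recursive slicing (adequate for ≤ 3 objectives and
small fronts).  Objectives are evaluated over a fixed-seed weather sample
so the surface is deterministic.

## Synthetic data

The weather generator produces sinusoidal temperature and radiation
climatologies (peak late July) with AR(1) anomalies, and rainfall from a
two-state Markov occurrence chain (p(wet|dry) = 0.3, p(wet|wet) = 0.6) with
exponential wet-day amounts scaled to 700 mm yr⁻¹ — means, seasonality and
wet/dry spell structure typical of south-east England.  It does not emulate
observed cross-correlations (e.g. cold wet spells), extremes beyond the
exponential tail, or real inter-annual modes; passing tests therefore
demonstrate internal consistency and plausible responses, not skill against
archived field data, which would require the real weather and soil series.

Fixture farms: a one-cell continuous-wheat plot with the classical N ladder
(0–288 kg N ha⁻¹, optional 35 t ha⁻¹ FYM ≈ 3.5 t C and 250 kg N), a
one-cell twice-cut grassland receiving 96 kg N in spring, a two-cell slope
and a 3×3 inclined catchment draining to a ditch.  Soils are silty clay
loam (25/55/20 clay/silt/sand, pH 7), initial water at field capacity,
Broadbalk-like P status (≈ 120 kg ha⁻¹ available over ≈ 3000 kg ha⁻¹
non-available in the topsoil), and organic pools spun to equilibrium for
the plot's target TOC (25 t C ha⁻¹ arable, 60 grass, 70 FYM).

## Numerical choices and limitations

- Explicit daily updates throughout; all pool withdrawals are capped at the
  pool so states stay non-negative.  Ten-year runs close water to < 10⁻⁶ mm
  and nutrients to < 10⁻⁹ daily.
- Elevation ties break by cell id; equal slopes split equally; cells must
  share one area so per-hectare intensities route consistently.
- Soil temperature is approximated by daily mean air temperature; there is
  no heat-flow model.
- No ammonia volatilisation, biological N fixation, snow, macropore flow,
  radiocarbon, pests/weeds or economics; grass swards are single-species.
- Scenario sizes in the shipped tests (5–10 years, ≤ 9 cells, small
  optimiser budgets) were chosen as the smallest that exercise every
  process through several full annual cycles.
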