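# landsim

A daily time-step, grid-based simulator of agricultural landscapes for
exploring trade-offs between production and the environment.  It couples:

- a **capacity ("tipping bucket") soil water model** over three layers, with
  van Genuchten retention curves from the HYPRES pedotransfer regressions,
  slope-adjusted surface runoff, Penman potential evapotranspiration, and a
  dynamic topsoil bulk density that responds to organic-matter change;
- **four-pool soil organic matter turnover** (DPM/RPM/BIO/HUM + inert IOM)
  with first-order decay `ΔC_i = C_i (1 − e^{−k_i f_T f_M f_cover Δt/365})`
  and parallel N and P stocks: BIO and HUM keep fixed C:N = 8.5 and
  C:P = 50/100, while net mineralisation per pool is
  `M_i = Δ_i/ρ_i − B_i/ρ_BIO − U_i/ρ_HUM`; immobilisation that mineral pools
  cannot cover cancels that day's decomposition;
- **mineral N dynamics**: atmospheric deposition, fertiliser forms,
  runoff mixing in the top 20 mm, convective nitrate leaching
  `F_NO3(l) = min(N_NO3, γ_NO3 F_W)`, nitrification with an N₂O by-product
  `N₂O = 10⁻⁴ N_NH4 S_pH (1 − θ/θ_s)`, and denitrification
  `N₂O = 7.35·10⁻⁴ N_NO3 f(WFPS) e^{−4.5·10⁻⁴(T−23.65)²}` with an N₂
  companion flux, plus crop uptake capped at 6 kg N ha⁻¹ d⁻¹;
- **two-pool mineral P** (available / non-available) with a piecewise-linear
  Olsen-P:total-P equilibrium fraction, daily re-equilibration at
  λ = 0.01 d⁻¹ (pulse half-life ≈ 65 days on a high-P silty clay loam),
  runoff and leaching of the mobile fractions, and uptake capped at
  2 kg P ha⁻¹ d⁻¹;
- a **light-use-efficiency crop/grass model**
  `dB/dt = Q ε W_rf N_NI P_NI` with thermal-time development, DVS-based
  partitioning, root-weighted water stress, N/P nutrition indices,
  senescence and litter return, cutting, grazing with manure return, and
  harvest at 85 % dry matter;
- **lateral routing** of runoff and dissolved N/P between grid cells by
  relative downslope gradients, with ditch edges exporting to a catchment
  discharge series; and
- a **multi-objective optimiser** (non-dominated sorting + differential
  evolution with crowding-distance selection) that maps Pareto fronts
  between yield, nitrate leaching and N₂O over fertiliser timing and dose.

Every scenario is generated programmatically: a synthetic weather generator
(sinusoidal climatology, Markov rainfall) and fixture farms emulating a
continuous-wheat N-ladder plot, a twice-cut fertilised grassland, and small
sloping catchments.

## Worked example

Five cropping years of winter wheat at 144 kg N ha⁻¹ yr⁻¹ on a
Broadbalk-like silty clay loam, with synthetic south-east England weather:

```python
import numpy as np
from landsim import build_fixture_farm, synth_weather, run

weather = synth_weather(years=6, latitude=51.8, seed=1, start_year=2001)
grid, events = build_fixture_farm("broadbalk_like_plot", n_dose=144, years=5)
records, harvests, _ = run(grid, weather, events)

yields = [h.yield_t_ha for h in harvests if h.kind == "harvest"]
print("harvest yields (t/ha @85% DM):", [round(y, 2) for y in yields])
print("mean yield: %.2f t/ha" % np.mean(yields))
print("mean annual N leached: %.1f kg N/ha" %
      (sum(r.n_leached for r in records) / 6.0))
print("mean annual N2O-N:     %.2f kg N/ha" %
      (sum(r.n2o for r in records) / 6.0))
```

prints

```
harvest yields (t/ha @85% DM): [6.4, 5.78, 7.5, 3.79, 6.01]
mean yield: 5.90 t/ha
mean annual N leached: 48.4 kg N/ha
mean annual N2O-N:     4.55 kg N/ha
```

The year-to-year spread reflects weather (the 3.79 t ha⁻¹ year is a dry
grain-fill); the mean sits where a well-fertilised UK winter-wheat plot
should.  Rerunning across the 0–288 kg N ladder shows yield rising and then
saturating while leaching and N₂O keep climbing — the trade-off the
optimiser (`landsim optimize`) explores systematically.

The same machinery is scriptable from the shell:

```bash
landsim synth-weather --years 5 --seed 1 --out weather.csv
landsim run --preset broadbalk_like_plot --n-dose 144 --years 5 \
    --weather weather.csv --out outputs/
landsim evaluate --obs obs.csv --sim sim.csv
```

`outputs/` then holds `fluxes.csv` (one row per cell per day: water, N, P,
C fluxes and the closure audits), `harvest.csv` and `catchment.csv`.

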