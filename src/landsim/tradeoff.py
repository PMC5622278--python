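"""Coupling of the simulator to the multi-objective optimiser.

The decision vector is (fertiliser day-of-year, amount); each evaluation
re-runs the single-cell wheat scenario over a fixed multi-year synthetic
weather sample (fixed seed, so the optimisation surface is deterministic)
and returns the objective vector (mean yield up, mean annual nitrate
leached down, mean annual N2O down).
"""

from __future__ import annotations

from datetime import date as Date, timedelta

import numpy as np

from . import fixtures
from .grid import run as run_grid
from .management import ManagementEvent
from .optimize import DecisionSpec, OptimiseResult, optimise
from .params import Params
from .weather import synth_weather

SENSES = ("max", "min", "min")


class FertiliserRunner:
    """Deterministic simulator runner for (fert_doy, fert_amount)."""

    def __init__(self, years: int = 3, start_year: int = 2001,
                 seed: int = 0, params: Params | None = None):
        self.years = years
        self.start_year = start_year
        self.params = params or Params()
        self.weather = synth_weather(years + 1, 51.8, seed, start_year)
        self._cache: dict = {}

    def __call__(self, decision: np.ndarray) -> tuple[float, float, float]:
        doy = int(round(decision[0]))
        amount = round(float(decision[1]), 1)
        key = (doy, amount)
        if key in self._cache:
            return self._cache[key]
        grid, events = fixtures.build_fixture_farm(
            "broadbalk_like_plot", n_dose=0.0, years=self.years,
            start_year=self.start_year, params=self.params)
        if amount > 0:
            for year in range(self.start_year + 1,
                              self.start_year + self.years + 1):
                d = Date(year, 1, 1) + timedelta(days=doy - 1)
                events.append(ManagementEvent(
                    d, "fertilise_N", amount=amount,
                    n_form="ammonium_nitrate"))
        events.sort(key=lambda e: e.date)
        records, harvests, _ = run_grid(grid, self.weather, events)
        yields = [h.yield_t_ha for h in harvests if h.kind == "harvest"]
        mean_yield = float(np.mean(yields)) if yields else 0.0
        n_days = len({r.date for r in records})
        years_run = n_days / 365.25
        leached = sum(r.n_leached for r in records) / years_run
        n2o = sum(r.n2o for r in records) / years_run
        out = (mean_yield, float(leached), float(n2o))
        self._cache[key] = out
        return out


def fertiliser_tradeoff(n_max: float = 300.0, years: int = 3,
                        generations: int = 20, pop_size: int = 24,
                        seed: int = 0, params: Params | None = None
                        ) -> tuple[OptimiseResult, DecisionSpec]:
    """Pareto front between yield, nitrate leached and N2O over a single
    spring fertiliser application (timing and dose)."""
    spec = DecisionSpec(names=("fert_doy", "fert_amount"),
                        lower=(60.0, 0.0), upper=(200.0, n_max))
    runner = FertiliserRunner(years=years, seed=seed, params=params)
    result = optimise(runner, spec, SENSES, generations=generations,
                      pop_size=pop_size, seed=seed)
    return result, spec
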