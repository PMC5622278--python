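"""Spatial orchestration: cells, the fixed daily process order, lateral
runoff routing, ditch capture and catchment aggregation.

Each cell carries a three-layer soil profile, topsoil organic pools and
(optionally) a crop.  One :func:`step_day` advances every cell through the
fixed order -- management events, bulk-density/retention refresh,
atmospheric deposition, rain partition with lateral routing (descending
elevation, so water cascades within the day), drainage, evaporation, crop
growth and uptake, grazing, decomposition/mineralisation, phosphorus
re-equilibration, nitrification, denitrification, leaching -- and emits a
flux record per cell with water, C, N and P closure errors for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import crop as cropmod
from . import nitrogen as nmod
from . import phosphorus as pmod
from . import organic as omod
from . import soil_water as swmod
from .management import ManagementEvent
from .organic import OrganicPools
from .params import Params
from .soil_water import SoilLayer
from .weather import WeatherDay, penman_pet

DIRECTIONS = ("N", "E", "S", "W")


@dataclass
class Cell:
    id: int
    area: float                    # m2
    elevation: float               # m
    gradient: float                # mean within-cell slope, dimensionless
    soil: list                     # 3 SoilLayer, top first
    pools: OrganicPools
    crop: cropmod.CropState | None = None
    neighbours: dict = field(default_factory=dict)   # direction -> cell id
    edges: dict = field(default_factory=dict)        # direction -> designation
    grazing: tuple | None = None   # (animal, stocking head ha-1)
    pond: float = 0.0              # mm ponded in a closed depression

    @property
    def layer1(self) -> SoilLayer:
        return self.soil[0]

    def organic_c_pct(self) -> float:
        """Topsoil organic C as mass % (TOC t ha-1 over layer soil mass)."""
        return 100.0 * self.pools.total_c / self.layer1.soil_mass

    def water_store(self) -> float:
        return sum(layer.water for layer in self.soil) + self.pond

    def mineral_n(self) -> float:
        return sum(layer.n_nh4 + layer.n_no3 for layer in self.soil)

    def mineral_p(self) -> float:
        return sum(layer.p_av + layer.p_nonav for layer in self.soil)


@dataclass
class Grid:
    cells: dict                    # id -> Cell
    latitude: float = 51.8
    params: Params = field(default_factory=Params)
    drains_to_ditch: bool = True   # layer-3 drainage joins ditch discharge

    def __post_init__(self):
        areas = {c.area for c in self.cells.values()}
        if len(areas) > 1:
            raise ValueError("all cells must share one area")
        for cell in self.cells.values():
            for direction, nb in cell.neighbours.items():
                if nb not in self.cells:
                    raise ValueError(f"cell {cell.id}: unknown neighbour {nb}")
        if not any("ditch" in c.edges.values() for c in self.cells.values()):
            import warnings
            warnings.warn("grid has no ditch edge; catchment output is zero",
                          stacklevel=2)

    def has_ditch(self) -> bool:
        return any("ditch" in c.edges.values() for c in self.cells.values())

    def crop_params(self, cell: Cell):
        return self.params.crop(cell.crop.kind) if cell.crop else None


@dataclass
class DailyRecord:
    """Per-cell per-day fluxes (mm for water, kg ha-1 for N and P,
    t ha-1 for carbon stocks)."""

    cell: int
    date: object
    rain: float = 0.0
    lateral_in: float = 0.0
    runoff: float = 0.0
    drainage: float = 0.0
    evaporation: float = 0.0
    transpiration: float = 0.0
    n_leached: float = 0.0
    n_runoff: float = 0.0
    n2o: float = 0.0
    n2: float = 0.0
    p_runoff: float = 0.0
    p_leached: float = 0.0
    net_min_n: float = 0.0
    net_min_p: float = 0.0
    co2: float = 0.0
    uptake_n: float = 0.0
    uptake_p: float = 0.0
    toc: float = 0.0
    biomass: float = 0.0
    lai: float = 0.0
    dvs: float = 0.0
    water_balance_err: float = 0.0
    n_balance_err: float = 0.0
    p_balance_err: float = 0.0
    c_balance_err: float = 0.0


@dataclass
class HarvestRecord:
    cell: int
    date: object
    kind: str                  # harvest | cut | graze
    yield_t_ha: float
    n_kg_ha: float
    p_kg_ha: float


@dataclass
class CatchmentDay:
    date: object
    discharge_m3: float = 0.0
    n_load_kg: float = 0.0
    p_load_kg: float = 0.0


def downslope_targets(grid: Grid, cell: Cell) -> list[tuple]:
    """(kind, neighbour id, slope) options for routing this cell's runoff.

    Ditch edges always accept flow (at the cell's own gradient, floored);
    field neighbours only when strictly lower.  Splits are proportional to
    slope magnitude.
    """
    size = math.sqrt(cell.area)
    targets = []
    for direction in DIRECTIONS:
        if cell.edges.get(direction) == "ditch":
            targets.append(("ditch", None, max(cell.gradient, 0.01)))
        elif direction in cell.neighbours:
            nb = grid.cells[cell.neighbours[direction]]
            if nb.elevation < cell.elevation:
                targets.append(
                    ("cell", nb.id, (cell.elevation - nb.elevation) / size))
    return targets


def _apply_events(grid: Grid, cell: Cell, events: list[ManagementEvent],
                  rec: DailyRecord, harvests: list, tallies: dict) -> None:
    p = grid.params
    for ev in events:
        if ev.kind == "sow":
            cell.crop = cropmod.sow(ev.crop or "wheat")
        elif ev.kind == "fallow":
            cell.crop = None
        elif ev.kind == "fertilise_N":
            if ev.n_form == "ammonium":
                cell.layer1.n_nh4 += ev.amount
            elif ev.n_form == "nitrate":
                cell.layer1.n_no3 += ev.amount
            else:
                cell.layer1.n_nh4 += 0.5 * ev.amount
                cell.layer1.n_no3 += 0.5 * ev.amount
            tallies["fert_n"] += ev.amount
        elif ev.kind == "fertilise_P":
            pmod.fertilise_p(cell.layer1, ev.amount, p.phosphorus)
            tallies["fert_p"] += ev.amount
        elif ev.kind == "apply_FYM":
            op = p.organic
            c_t_ha = ev.amount * op.fym_dm_frac * op.fym_c_frac  # t C ha-1
            n_kg = op.fym_n_per_35t * ev.amount / 35.0
            cn = 1000.0 * c_t_ha / n_kg
            omod.add_organic_input(cell.pools, c_t_ha, "fym", cn, op.fym_cp,
                                   op)
            tallies["c_in"] += c_t_ha
            tallies["org_n_in"] += n_kg
            tallies["org_p_in"] += 1000.0 * c_t_ha / op.fym_cp
        elif ev.kind == "cut":
            if cell.crop is not None and cell.crop.kind == "grass":
                cp = grid.crop_params(cell)
                rem = cropmod.cut_or_graze(cell.crop, None, cp)
                tallies["removed_n"] += rem.n * cropmod.G_M2_TO_KG_HA
                tallies["removed_p"] += rem.p * cropmod.G_M2_TO_KG_HA
                harvests.append(HarvestRecord(
                    cell.id, rec.date, "cut", rem.dry_matter * 0.01 / 0.85,
                    rem.n * cropmod.G_M2_TO_KG_HA,
                    rem.p * cropmod.G_M2_TO_KG_HA))
            else:
                raise ValueError(f"cut event on non-grass cell {cell.id}")
        elif ev.kind == "graze_start":
            cell.grazing = (ev.animal, ev.stocking)
        elif ev.kind == "graze_stop":
            cell.grazing = None
        elif ev.kind == "harvest":
            if cell.crop is not None:
                cp = grid.crop_params(cell)
                result = cropmod.harvest(cell.crop, cp)
                harvests.append(HarvestRecord(
                    cell.id, rec.date, "harvest", result.yield_t_ha,
                    result.grain_n, result.grain_p))
                tallies["removed_n"] += result.grain_n
                tallies["removed_p"] += result.grain_p
                if not cp.straw_incorporated:
                    # exported straw: removed from plant but not soil input
                    pass
                _return_residue(grid, cell, result.residue, tallies)
                cell.crop = None


def _return_residue(grid: Grid, cell: Cell, ret: cropmod.OrganicReturn,
                    tallies: dict) -> None:
    """Route dead plant material into DPM/RPM with its own stoichiometry."""
    if ret.c <= 0.0:
        return
    op = grid.params.organic
    cn = ret.c / ret.n if ret.n > 0 else 1e9
    cp_ratio = ret.c / ret.p if ret.p > 0 else 1e9
    omod.add_organic_input(cell.pools, ret.c / 1000.0, "residue", cn,
                           cp_ratio, op)
    tallies["c_in"] += ret.c / 1000.0
    tallies["org_n_in"] += ret.n
    tallies["org_p_in"] += ret.p
    tallies["plant_out_n"] += ret.n
    tallies["plant_out_p"] += ret.p


def step_day(grid: Grid, day: WeatherDay, events: list[ManagementEvent],
             catchment: CatchmentDay | None = None
             ) -> tuple[list[DailyRecord], list[HarvestRecord]]:
    """Advance the whole grid one day; returns (flux records, harvests)."""
    p = grid.params
    if catchment is None:
        catchment = CatchmentDay(day.date)
    order = sorted(grid.cells.values(),
                   key=lambda c: (-c.elevation, c.id))
    lateral: dict = {c.id: {"water": 0.0, "nh4": 0.0, "no3": 0.0, "p": 0.0}
                     for c in grid.cells.values()}
    records, harvests = [], []
    area_scale = next(iter(grid.cells.values())).area / 10000.0  # ha per cell

    for cell in order:
        rec = DailyRecord(cell.id, day.date, rain=day.rain)
        tallies = {k: 0.0 for k in (
            "fert_n", "fert_p", "c_in", "org_n_in", "org_p_in",
            "removed_n", "removed_p", "plant_out_n", "plant_out_p")}
        w0 = cell.water_store()
        n0 = cell.mineral_n()
        p0 = cell.mineral_p()
        c0 = cell.pools.total_c

        _apply_events(grid, cell, events, rec, harvests, tallies)

        # bulk density / retention refresh (topsoil follows organic C)
        swmod.update_bulk_density(cell.layer1, cell.organic_c_pct(), p.water)

        # atmospheric deposition (as nitrate)
        deposition = nmod.atmospheric_deposition(day.date)
        cell.layer1.n_no3 += deposition

        # rain + lateral inflow partition, runoff generation and routing
        lat = lateral[cell.id]
        rec.lateral_in = lat["water"]
        surface = day.rain + lat["water"]
        storage = swmod.slope_storage(p.water.s_max, cell.gradient,
                                      p.water.g_max)
        infil, runoff = swmod.partition_rain(
            surface, storage, cell.layer1, p.water.infiltration_limit)
        infil_frac = infil / surface if surface > 0 else 0.0
        # incoming solutes split like the incoming water
        cell.layer1.n_nh4 += lat["nh4"] * infil_frac
        cell.layer1.n_no3 += lat["no3"] * infil_frac
        cell.layer1.p_av += lat["p"] * infil_frac
        pass_n_nh4 = lat["nh4"] * (1.0 - infil_frac)
        pass_n_no3 = lat["no3"] * (1.0 - infil_frac)
        pass_p = lat["p"] * (1.0 - infil_frac)
        out_nh4 = pass_n_nh4
        out_no3 = pass_n_no3
        out_p = pass_p
        if runoff > 0.0:
            w_surf = nmod.surface_water(cell.layer1, p.water.air_dry_frac)
            nh4_before = cell.layer1.n_nh4
            no3_before = cell.layer1.n_no3
            own_n = nmod.runoff_n(cell.layer1, runoff, w_surf)
            if nh4_before + no3_before > 0:
                out_nh4 += own_n * nh4_before / (nh4_before + no3_before)
                out_no3 += own_n * no3_before / (nh4_before + no3_before)
            out_p += pmod.runoff_p(cell.layer1, runoff, w_surf, p.phosphorus)
        rec.n_runoff = out_nh4 + out_no3 - pass_n_nh4 - pass_n_no3
        rec.p_runoff = out_p - pass_p
        targets = downslope_targets(grid, cell)
        if runoff > 0.0 or out_nh4 + out_no3 + out_p > 0.0:
            if not targets:
                # closed depression: water re-infiltrates / ponds locally
                room = max(0.0, cell.layer1.sat_mm - cell.layer1.water)
                back = min(runoff, room)
                cell.layer1.water += back
                cell.pond += runoff - back
                cell.layer1.n_nh4 += out_nh4
                cell.layer1.n_no3 += out_no3
                cell.layer1.p_av += out_p
                rec.n_runoff = 0.0
                rec.p_runoff = 0.0
                runoff = 0.0
                out_nh4 = out_no3 = out_p = 0.0
            else:
                total_slope = sum(t[2] for t in targets)
                for kind, nb_id, slope in targets:
                    share = slope / total_slope
                    if kind == "ditch":
                        catchment.discharge_m3 += (runoff * share
                                                   * cell.area / 1000.0)
                        catchment.n_load_kg += ((out_nh4 + out_no3) * share
                                                * area_scale)
                        catchment.p_load_kg += out_p * share * area_scale
                    else:
                        tgt = lateral[nb_id]
                        tgt["water"] += runoff * share
                        tgt["nh4"] += out_nh4 * share
                        tgt["no3"] += out_no3 * share
                        tgt["p"] += out_p * share
        rec.runoff = runoff

        # drainage cascade
        f_w, drainage = swmod.drain_cascade(cell.soil, infil)
        rec.drainage = drainage
        if grid.drains_to_ditch and grid.has_ditch():
            catchment.discharge_m3 += drainage * cell.area / 1000.0

        # evaporation from the uncovered soil surface
        cp = grid.crop_params(cell)
        cover = cropmod.cover_fraction(cell.crop, cp)
        pet = penman_pet(day, grid.latitude, p.water.albedo,
                         p.water.psychrometric, p.water.latent_heat)
        rec.evaporation = swmod.soil_evaporation(
            day, cover, cell.layer1, grid.latitude, p.water, pet=pet)

        # crop development, water stress, growth, uptake, senescence
        uptake_n = uptake_p = 0.0
        if cell.crop is not None:
            state = cell.crop
            cropmod.develop(state, day, grid.latitude, cp)
            if state.emerged:
                roots = cropmod.root_distribution(
                    max(state.root_depth, 1.0), cell.soil, cp.f_r)
                cover = cropmod.cover_fraction(state, cp)
                p_tran = cover * pet
                w_rf, atran = cropmod.water_stress(cell.soil, p_tran, roots,
                                                   cp)
                for layer, a in zip(cell.soil, atran):
                    layer.water -= a
                rec.transpiration = sum(atran)
                state.w_rf = w_rf
                n_ni, p_ni = cropmod.nutrition_indices(state, cp)
                state.n_ni, state.p_ni = n_ni, p_ni
                cropmod.daily_growth(state, day, w_rf, n_ni, p_ni, cp)
                dem_n, dem_p = cropmod.nutrient_demand(state, cp)
                uptake_n = nmod.supply_n_uptake(cell.soil, roots, dem_n,
                                                p.nitrogen)
                uptake_p = pmod.supply_p_uptake(cell.soil, roots, dem_p,
                                                p.phosphorus)
                cropmod.apply_uptake(state, uptake_n, uptake_p, cp)
                cropmod.translocate_to_storage(state, cp)
                ret = cropmod.senesce_and_return(state, day, n_ni, cp)
                _return_residue(grid, cell, ret, tallies)
                rec.lai = state.lai
                rec.dvs = state.dvs
                rec.biomass = state.total_mass
        rec.uptake_n, rec.uptake_p = uptake_n, uptake_p

        # grazing: intake removal and manure return
        if cell.grazing is not None and cell.crop is not None \
                and cell.crop.kind == "grass":
            animal, stocking = cell.grazing
            gp = p.grazing
            intake = gp.intake[animal] * stocking / cropmod.G_M2_TO_KG_HA
            rem = cropmod.cut_or_graze(cell.crop, intake, cp)
            tallies["removed_n"] += rem.n * cropmod.G_M2_TO_KG_HA
            tallies["removed_p"] += rem.p * cropmod.G_M2_TO_KG_HA
            if rem.dry_matter > 0:
                harvests.append(HarvestRecord(
                    cell.id, day.date, "graze", rem.dry_matter * 0.01 / 0.85,
                    rem.n * cropmod.G_M2_TO_KG_HA,
                    rem.p * cropmod.G_M2_TO_KG_HA))
            man_c, man_n = cropmod.grazing_returns(animal, stocking, gp)
            if man_c > 0:
                op = p.organic
                omod.add_organic_input(cell.pools, man_c / 1000.0, "fym",
                                       man_c / man_n, op.manure_cp, op)
                tallies["c_in"] += man_c / 1000.0
                tallies["org_n_in"] += man_n
                tallies["org_p_in"] += man_c / op.manure_cp

        # decomposition and mineralisation (topsoil)
        op = p.organic
        layer1 = cell.layer1
        max_deficit = max(0.0, layer1.fc_mm - layer1.wp_mm)
        deficit = max(0.0, layer1.fc_mm - layer1.water)
        covered = cell.crop is not None and cell.crop.emerged
        mods = omod.rate_modifiers(day.tavg, deficit, max_deficit, covered,
                                   op)
        step = omod.decompose(cell.pools, mods, layer1.clay, op)
        avail_n = layer1.n_nh4 + layer1.n_no3
        avail_p = layer1.p_av + layer1.p_nonav
        net_n, net_p, performed = omod.mineralise(step, cell.pools, avail_n,
                                                  avail_p, op)
        if performed:
            rec.co2 = step.total_co2
            if net_n >= 0:
                layer1.n_nh4 += net_n
            else:
                need = -net_n
                from_nh4 = min(need, layer1.n_nh4)
                layer1.n_nh4 -= from_nh4
                layer1.n_no3 -= need - from_nh4
            if net_p >= 0:
                layer1.p_av += net_p
            else:
                pmod.immobilise_p(layer1, -net_p)
        rec.net_min_n, rec.net_min_p = net_n, net_p

        # phosphorus re-equilibration (every layer)
        for layer in cell.soil:
            pmod.reequilibrate(layer, p.phosphorus)

        # nitrification (all layers), denitrification (top two only)
        f_t = nmod.nitrification_f_t(day.tavg, p.nitrogen)
        for i, layer in enumerate(cell.soil):
            g_m = nmod.nitrification_g_m(layer)
            _, n2o_nit = nmod.nitrify(layer, f_t, g_m, p.nitrogen)
            rec.n2o += n2o_nit
            n2o_den, n2 = nmod.denitrify(layer, day.tavg, p.nitrogen,
                                         active=(i < 2))
            rec.n2o += n2o_den
            rec.n2 += n2
        # leaching with today's drainage fluxes
        _, rec.n_leached = nmod.leach_no3(cell.soil, f_w)
        _, rec.p_leached = pmod.leach_p(cell.soil, f_w, p.phosphorus)
        if grid.drains_to_ditch and grid.has_ditch():
            catchment.n_load_kg += rec.n_leached * area_scale
            catchment.p_load_kg += rec.p_leached * area_scale

        rec.toc = cell.pools.total_c

        # closure audits
        rec.water_balance_err = (day.rain + rec.lateral_in
                                 - (cell.water_store() - w0)
                                 - rec.runoff - rec.drainage
                                 - rec.evaporation - rec.transpiration)
        rec.n_balance_err = (tallies["fert_n"] + deposition + rec.net_min_n
                             + lat["nh4"] + lat["no3"]
                             - (cell.mineral_n() - n0)
                             - rec.n_leached - (out_nh4 + out_no3)
                             - rec.n2o - rec.n2 - rec.uptake_n)
        rec.p_balance_err = (tallies["fert_p"] + rec.net_min_p + lat["p"]
                             - (cell.mineral_p() - p0)
                             - rec.p_leached - out_p - rec.uptake_p)
        rec.c_balance_err = tallies["c_in"] - rec.co2 \
            - (cell.pools.total_c - c0)
        records.append(rec)
    return records, harvests


def run(grid: Grid, weather: list[WeatherDay],
        events: list[ManagementEvent]
        ) -> tuple[list[DailyRecord], list[HarvestRecord],
                   list[CatchmentDay]]:
    """Run the grid over a weather series with a management schedule."""
    by_date: dict = {}
    for ev in events:
        by_date.setdefault(ev.date, []).append(ev)
    records, harvests, catchment = [], [], []
    for day in weather:
        cd = CatchmentDay(day.date)
        recs, harv = step_day(grid, day, by_date.get(day.date, []), cd)
        records.extend(recs)
        harvests.extend(harv)
        catchment.append(cd)
    return records, harvests, catchment


def aggregate_catchment(catchment: list[CatchmentDay]) -> "object":
    """Catchment series as a DataFrame (discharge m3 d-1, loads kg d-1)."""
    import pandas as pd

    return pd.DataFrame([{
        "date": c.date, "discharge_m3": c.discharge_m3,
        "n_load_kg": c.n_load_kg, "p_load_kg": c.p_load_kg}
        for c in catchment])
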