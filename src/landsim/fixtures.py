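"""Ready-to-run synthetic farm configurations.

Presets emulate the structure of the long-term Rothamsted experiments the
model is aimed at (a continuous-wheat plot with an N ladder and an FYM
treatment; a twice-cut fertilised permanent-grass plot) and two small
sloping grids for testing lateral routing and catchment export.  All soils,
pool states and schedules are generated programmatically; nothing is read
from external archives.
"""

from __future__ import annotations

import math
from datetime import date as Date

import numpy as np

from . import organic as omod
from .crop import sow
from .grid import Cell, Grid
from .management import ManagementEvent
from .organic import OrganicPools
from .params import Params
from .soil_water import SoilLayer, hypres_retention, nomogram_bulk_density

PRESETS = ("broadbalk_like_plot", "park_grass_like_plot", "two_cell_slope",
           "catchment_3x3")

# Broadbalk-like N ladder (kg N ha-1) and the FYM dressing (t fresh ha-1)
N_LADDER = (0, 48, 96, 144, 192, 240, 288)
FYM_RATE = 35.0

_SOIL = dict(clay=25.0, silt=55.0, sand=20.0, ph=7.0)


def _spinup_pools(target_toc: float, clay: float, params: Params,
                  input_cn: float = 40.0, input_cp: float = 300.0
                  ) -> OrganicPools:
    """Equilibrium organic pools for a target TOC under typical forcing."""
    doy = np.arange(365)
    temps = 10.0 + 6.5 * np.cos(2.0 * math.pi * (doy - 196) / 365.0)
    f_t = np.array([omod.rate_modifier_temperature(t) for t in temps])
    modifiers = f_t * 0.9 * 0.7          # moisture ~0.9, cover mix ~0.7
    pattern = np.full(365, 1.0 / 365.0)
    pools, _ = omod.spinup_to_equilibrium(
        target_toc, clay, modifiers, pattern, input_cn, input_cp,
        params.organic)
    return pools


def _profile(toc_t_ha: float, params: Params) -> list[SoilLayer]:
    """Three 230-mm layers of a silty clay loam, water at field capacity."""
    s = _SOIL
    om_pct = 100.0 * toc_t_ha / (10.0 * 230.0 * 1.30) * \
        params.water.om_conversion
    bd_top = nomogram_bulk_density(s["sand"], s["clay"],
                                   om_pct / params.water.om_conversion)
    layers = []
    for i, (bd, topsoil) in enumerate(((bd_top, True), (1.40, False),
                                       (1.45, False))):
        anchors = hypres_retention(s["clay"], s["silt"],
                                   om_pct if topsoil else 0.5, bd, topsoil)
        layer = SoilLayer(thickness=230.0, clay=s["clay"], silt=s["silt"],
                          sand=s["sand"], ph=s["ph"], bulk_density=bd,
                          anchors=anchors)
        layer.water = layer.fc_mm
        layers.append(layer)
    # mineral pools: modest nitrate profile, Broadbalk-like P status
    layers[0].n_nh4, layers[0].n_no3 = 2.0, 20.0
    layers[1].n_nh4, layers[1].n_no3 = 0.5, 5.0
    layers[2].n_nh4, layers[2].n_no3 = 0.2, 2.0
    layers[0].p_av, layers[0].p_nonav = 120.0, 3000.0
    layers[1].p_av, layers[1].p_nonav = 30.0, 1500.0
    layers[2].p_av, layers[2].p_nonav = 10.0, 1000.0
    return layers


def _cell(cell_id: int, elevation: float, gradient: float, toc: float,
          params: Params, area: float = 10000.0) -> Cell:
    return Cell(id=cell_id, area=area, elevation=elevation,
                gradient=gradient, soil=_profile(toc, params),
                pools=_spinup_pools(toc, _SOIL["clay"], params))


def _wheat_year_events(year: int, n_dose: float, fym: bool,
                       p_dose: float = 35.0) -> list[ManagementEvent]:
    ev = [ManagementEvent(Date(year, 10, 15), "sow", crop="wheat")]
    if p_dose > 0:
        ev.append(ManagementEvent(Date(year, 10, 1), "fertilise_P",
                                  amount=p_dose))
    if fym:
        ev.append(ManagementEvent(Date(year, 10, 10), "apply_FYM",
                                  amount=FYM_RATE))
    if n_dose > 0:
        ev.append(ManagementEvent(Date(year + 1, 4, 15), "fertilise_N",
                                  amount=n_dose, n_form="ammonium_nitrate"))
    ev.append(ManagementEvent(Date(year + 1, 8, 15), "harvest"))
    return ev


def build_fixture_farm(preset: str, n_dose: float = 144.0,
                       years: int = 5, start_year: int = 2001,
                       params: Params | None = None, fym: bool = False
                       ) -> tuple[Grid, list[ManagementEvent]]:
    """Build (grid, management schedule) for a named preset.

    ``n_dose`` applies to the wheat preset (one spring dressing, the
    Broadbalk-style ladder values 0..288 being typical choices); ``fym``
    adds the 35 t ha-1 farmyard-manure dressing each autumn.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    params = params or Params()
    events: list[ManagementEvent] = []

    if preset == "broadbalk_like_plot":
        toc = 70.0 if fym else 25.0
        cell = _cell(0, 100.0, 0.0, toc, params)
        cell.edges = {"S": "ditch"}
        grid = Grid({0: cell}, params=params)
        for year in range(start_year, start_year + years):
            events.extend(_wheat_year_events(year, n_dose, fym))

    elif preset == "park_grass_like_plot":
        cell = _cell(0, 100.0, 0.0, 60.0, params)
        cell.edges = {"S": "ditch"}
        grid = Grid({0: cell}, params=params)
        events.append(ManagementEvent(Date(start_year, 3, 1), "sow",
                                      crop="grass"))
        for year in range(start_year, start_year + years):
            events.append(ManagementEvent(Date(year, 4, 1), "fertilise_N",
                                          amount=96.0, n_form="nitrate"))
            events.append(ManagementEvent(Date(year, 10, 1), "fertilise_P",
                                          amount=35.0))
            events.append(ManagementEvent(Date(year, 6, 15), "cut"))
            events.append(ManagementEvent(Date(year, 11, 1), "cut"))

    elif preset == "two_cell_slope":
        upper = _cell(0, 101.0, 0.05, 55.0, params)
        lower = _cell(1, 100.0, 0.05, 55.0, params)
        upper.neighbours = {"S": 1}
        lower.neighbours = {"N": 0}
        lower.edges = {"S": "ditch"}
        grid = Grid({0: upper, 1: lower}, params=params)
        events.append(ManagementEvent(Date(start_year, 3, 1), "sow",
                                      crop="grass"))

    else:  # catchment_3x3
        cells = {}
        for row in range(3):
            for col in range(3):
                cid = 3 * row + col
                cells[cid] = _cell(cid, 102.0 - row, 0.01, 55.0, params)
        for cid, cell in cells.items():
            row, col = divmod(cid, 3)
            if row > 0:
                cell.neighbours["N"] = cid - 3
            if row < 2:
                cell.neighbours["S"] = cid + 3
            if col > 0:
                cell.neighbours["W"] = cid - 1
            if col < 2:
                cell.neighbours["E"] = cid + 1
            if row == 2:
                cell.edges["S"] = "ditch"
        grid = Grid(cells, params=params)
        events.append(ManagementEvent(Date(start_year, 3, 1), "sow",
                                      crop="grass"))
        for year in range(start_year, start_year + years):
            events.append(ManagementEvent(Date(year, 4, 1), "fertilise_N",
                                          amount=50.0,
                                          n_form="ammonium_nitrate"))
            events.append(ManagementEvent(Date(year, 5, 15), "graze_start",
                                          animal="beef", stocking=2.0))
            events.append(ManagementEvent(Date(year, 9, 15), "graze_stop"))
    return grid, sorted(events, key=lambda e: e.date)
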