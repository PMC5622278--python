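"""Light-use-efficiency crop and grass growth.

Biomass accumulates as dB = Q * eps * W_rf * N_NI * P_NI where Q is the
intercepted PAR (Beer's law on LAI), eps the light-use efficiency and the
three indices are multiplicative stress factors in [0, 1].  Development
follows thermal time modified by vernalisation and photoperiod; biomass is
partitioned to root, leaf, stem and storage organ by development-stage
tables.  Grass is indeterminate (DVS held below 1), its LUE additionally
scaled by radiation and temperature ramps, and it can be cut or grazed down
to a standing-biomass floor.

Internal crop state is in g DM m-2; exchanges with the soil modules convert
to kg ha-1 (1 g m-2 = 10 kg ha-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import CropParams, GrazingParams
from .soil_water import SoilLayer
from .weather import WeatherDay, solar_geometry

G_M2_TO_KG_HA = 10.0
ORGANS = ("root", "leaf", "stem", "storage")


@dataclass
class CropState:
    """State of the growing crop in one cell."""

    kind: str
    dvs: float = 0.0
    emerged: bool = False
    tt_sowing: float = 0.0        # thermal time since sowing (pre-emergence)
    vern: float = 0.0             # vernalisation days accumulated
    days_since_sowing: int = 0
    mass: dict = field(default_factory=lambda: dict.fromkeys(ORGANS, 0.0))
    n: dict = field(default_factory=lambda: dict.fromkeys(ORGANS, 0.0))
    p: dict = field(default_factory=lambda: dict.fromkeys(ORGANS, 0.0))
    dead_leaf: float = 0.0        # standing dead leaf (g m-2)
    dead_leaf_n: float = 0.0
    dead_leaf_p: float = 0.0
    root_depth: float = 0.0       # mm
    n_ni: float = 1.0
    p_ni: float = 1.0
    w_rf: float = 1.0

    @property
    def lai(self) -> float:
        return self._lai

    _lai: float = 0.0

    @property
    def above_ground(self) -> float:
        return (self.mass["leaf"] + self.mass["stem"] + self.mass["storage"]
                + self.dead_leaf)

    @property
    def total_mass(self) -> float:
        return sum(self.mass.values()) + self.dead_leaf

    @property
    def total_n(self) -> float:
        return sum(self.n.values()) + self.dead_leaf_n

    @property
    def total_p(self) -> float:
        return sum(self.p.values()) + self.dead_leaf_p


def sow(kind: str) -> CropState:
    return CropState(kind=kind)


def update_lai(state: CropState, cp: CropParams) -> None:
    state._lai = cp.sla * state.mass["leaf"]


def cover_fraction(state: CropState | None, cp: CropParams | None) -> float:
    """Canopy cover = intercepted fraction of incoming radiation."""
    if state is None or cp is None or not state.emerged:
        return 0.0
    return 1.0 - math.exp(-cp.extinction * state.lai)


# --- development ------------------------------------------------------------

def daylength_hours(day: WeatherDay, latitude: float) -> float:
    return solar_geometry(day.date.timetuple().tm_yday, latitude)[0]


def develop(state: CropState, day: WeatherDay, latitude: float,
            cp: CropParams) -> float:
    """Advance DVS by effective thermal time; returns the increment.

    Pre-anthesis thermal time is scaled by vernalisation progress and a
    photoperiod ramp; grass never reaches DVS 1 (no flowering).
    """
    tavg = day.tavg
    state.days_since_sowing += 1
    tt = max(0.0, tavg - cp.base_temp)
    if cp.vern_days > 0 and cp.vern_tmin <= tavg <= cp.vern_tmax:
        state.vern = min(cp.vern_days, state.vern + 1.0)
    if not state.emerged:
        state.tt_sowing += tt
        if state.tt_sowing >= cp.tsum_emerge:
            state.emerged = True
            for organ in ("root", "leaf", "stem"):
                state.mass[organ] = cp.init_mass / 3.0
            state.root_depth = 50.0
            update_lai(state, cp)
        return 0.0
    if state.dvs < 1.0:
        factor = 1.0
        if cp.vern_days > 0:
            factor *= state.vern / cp.vern_days
        if cp.photo_sat > cp.photo_base:
            dl = daylength_hours(day, latitude)
            factor *= min(1.0, max(0.0, (dl - cp.photo_base)
                                   / (cp.photo_sat - cp.photo_base)))
        inc = tt * factor / cp.tsum1
        if state.kind == "grass":
            new = min(0.999, state.dvs + inc)
            inc = new - state.dvs
        else:
            inc = min(inc, 2.0 - state.dvs)
    else:
        inc = min(tt / cp.tsum2, 2.0 - state.dvs)
    state.dvs += inc
    state.root_depth = min(cp.max_root_depth,
                           state.root_depth + cp.root_growth)
    return inc


# --- water ------------------------------------------------------------------

def water_stress_factor(layer: SoilLayer, cp: CropParams) -> float:
    """Per-layer water stress W_S from the retention anchors.

    1 on the plateau between theta_a (-5 kPa) and theta_d (-40 kPa);
    declines linearly towards saturation above theta_a and towards wilting
    below theta_d.  Grass suffers no saturation stress and has a floor of
    0.4 at wilting point.
    """
    a = layer.anchors
    theta = layer.theta
    if theta > a.theta_a:
        if cp.kind == "grass":
            return 1.0
        return max(0.0, (a.theta_sat - theta) / (a.theta_sat - a.theta_a))
    if theta > a.theta_d:
        return 1.0
    if theta > a.theta_wp:
        frac = (theta - a.theta_wp) / (a.theta_d - a.theta_wp)
        if cp.kind == "grass":
            return cp.grass_ws_floor + (1.0 - cp.grass_ws_floor) * frac
        return frac
    return cp.grass_ws_floor if cp.kind == "grass" else 0.0


def water_stress(profile: list[SoilLayer], p_tran: float,
                 root_fractions: list[float], cp: CropParams
                 ) -> tuple[float, list[float]]:
    """Transpiration reduction factor and per-layer actual transpiration.

    ATran(l) = P_Tran * W_S(l)^2 * F_RL(l) / sum_l W_S(l) F_RL(l); supply is
    additionally limited by extractable water above wilting in each layer.
    W_rf = sum ATran / P_Tran (1 when there is no demand).
    """
    if p_tran < 0:
        raise ValueError("potential transpiration must be >= 0")
    if p_tran == 0.0:
        return 1.0, [0.0] * len(profile)
    ws = [water_stress_factor(layer, cp) for layer in profile]
    denom = sum(w * f for w, f in zip(ws, root_fractions))
    if denom <= 0.0:
        return 0.0, [0.0] * len(profile)
    atran = []
    for layer, w, f in zip(profile, ws, root_fractions):
        a = p_tran * w * w * f / denom
        extractable = max(0.0, layer.water - layer.wp_mm)
        atran.append(min(a, extractable))
    return sum(atran) / p_tran, atran


def root_distribution(root_depth: float, profile: list[SoilLayer],
                      f_r: float = 0.98) -> list[float]:
    """Root fraction per layer from an exponential root-length profile.

    a = -ln(1 - F_r)/d_root; layer mass proportional to
    exp(-a z_top) - exp(-a z_bottom), truncated at d_root, normalised to 1.
    """
    if root_depth <= 0:
        raise ValueError("root depth must be positive")
    a = -math.log(1.0 - f_r) / root_depth
    masses = []
    z = 0.0
    for layer in profile:
        z_top, z_bot = z, z + layer.thickness
        z = z_bot
        lo = min(z_top, root_depth)
        hi = min(z_bot, root_depth)
        masses.append(math.exp(-a * lo) - math.exp(-a * hi) if hi > lo
                      else 0.0)
    total = sum(masses)
    return [m / total for m in masses]


# --- growth and nutrition ---------------------------------------------------

def grass_lue_factors(day: WeatherDay, cp: CropParams) -> float:
    """Radiation and temperature scaling of grass LUE."""
    rad = day.radiation
    if rad <= cp.r_lue_lo:
        r = 1.0
    elif rad >= cp.r_lue_hi:
        r = cp.r_lue_min
    else:
        r = 1.0 + (cp.r_lue_min - 1.0) * (rad - cp.r_lue_lo) \
            / (cp.r_lue_hi - cp.r_lue_lo)
    t = min(1.0, max(0.0, (day.tavg - cp.t_lue_lo)
                     / (cp.t_lue_hi - cp.t_lue_lo)))
    return r * t


def _interp(knots, x: float) -> float:
    if x <= knots[0][0]:
        return knots[0][1]
    for (x0, y0), (x1, y1) in zip(knots, knots[1:]):
        if x <= x1:
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    return knots[-1][1]


def partition_fractions(dvs: float, cp: CropParams) -> dict:
    knots = cp.partition
    fr = {organ: _interp([(k[0], k[i + 1]) for k in knots], dvs)
          for i, organ in enumerate(ORGANS)}
    total = sum(fr.values())
    return {k: v / total for k, v in fr.items()} if total > 0 else fr


def n_max_prop_leaf(dvs: float, cp: CropParams) -> float:
    if cp.kind == "grass":
        return cp.n_max_leaf_const
    return cp.n_max_leaf_a * math.exp(-1.7 * dvs) + cp.n_max_leaf_b


def p_max_prop_leaf(dvs: float, cp: CropParams) -> float:
    if cp.kind == "grass":
        return cp.p_max_leaf_const
    return _interp(list(cp.p_max_leaf_knots), dvs)


def nutrition_indices(state: CropState, cp: CropParams
                      ) -> tuple[float, float]:
    """N and P nutrition indices from leaf+stem contents, clamped [0, 1].

    index = (content - residual) / (maximum - residual) over the combined
    leaf and stem mass; 1 before emergence (no stress without a canopy).
    """
    w_leaf, w_stem = state.mass["leaf"], state.mass["stem"]
    total = w_leaf + w_stem
    if total <= 0.0:
        return 1.0, 1.0
    nmax_leaf = n_max_prop_leaf(state.dvs, cp)
    nmax_stem = cp.stem_factor * nmax_leaf
    n_actual = (state.n["leaf"] + state.n["stem"]) / total
    n_max = (w_leaf * nmax_leaf + w_stem * nmax_stem) / total
    n_ni = (n_actual - cp.n_res) / (n_max - cp.n_res)
    pmax_leaf = p_max_prop_leaf(state.dvs, cp)
    pmax_stem = cp.stem_factor * pmax_leaf
    p_actual = state.p["leaf"] + state.p["stem"]
    p_res = w_leaf * cp.p_res_leaf + w_stem * cp.p_res_stem
    p_max = w_leaf * pmax_leaf + w_stem * pmax_stem
    p_ni = (p_actual - p_res) / (p_max - p_res) if p_max > p_res else 1.0
    clamp = lambda v: min(1.0, max(0.0, v))
    return clamp(n_ni), clamp(p_ni)


def daily_growth(state: CropState, day: WeatherDay, w_rf: float,
                 n_ni: float, p_ni: float, cp: CropParams) -> float:
    """Produce and partition the day's biomass; returns dB (g DM m-2)."""
    if not state.emerged:
        return 0.0
    q = cp.par_frac * day.radiation * cover_fraction(state, cp)
    eps = cp.lue
    if cp.kind == "grass":
        eps *= grass_lue_factors(day, cp)
    db = q * eps * w_rf * n_ni * p_ni
    fracs = partition_fractions(state.dvs, cp)
    for organ in ORGANS:
        state.mass[organ] += db * fracs[organ]
    update_lai(state, cp)
    return db


# --- nutrient demand, uptake, translocation --------------------------------

def organ_max_props(state: CropState, cp: CropParams) -> tuple[dict, dict]:
    nmax_leaf = n_max_prop_leaf(state.dvs, cp)
    pmax_leaf = p_max_prop_leaf(state.dvs, cp)
    n_max = {"leaf": nmax_leaf, "stem": cp.stem_factor * nmax_leaf,
             "root": cp.n_max_root, "storage": cp.n_max_storage}
    p_max = {"leaf": pmax_leaf, "stem": cp.stem_factor * pmax_leaf,
             "root": cp.p_max_root, "storage": cp.p_max_storage}
    return n_max, p_max


def nutrient_demand(state: CropState, cp: CropParams) -> tuple[float, float]:
    """Crop (N, P) demand in kg ha-1 d-1: sum over root, stem, leaf of
    (maximum - actual) content.  Zero after anthesis (uptake stops)."""
    if not state.emerged or state.dvs >= 1.0:
        return 0.0, 0.0
    n_max, p_max = organ_max_props(state, cp)
    dn = dp = 0.0
    for organ in ("root", "leaf", "stem"):
        w = state.mass[organ]
        dn += max(0.0, w * n_max[organ] - state.n[organ])
        dp += max(0.0, w * p_max[organ] - state.p[organ])
    return dn * G_M2_TO_KG_HA, dp * G_M2_TO_KG_HA


def apply_uptake(state: CropState, n_kg_ha: float, p_kg_ha: float,
                 cp: CropParams) -> None:
    """Distribute delivered soil N and P over organs pro rata their demand."""
    n_up, p_up = n_kg_ha / G_M2_TO_KG_HA, p_kg_ha / G_M2_TO_KG_HA
    n_max, p_max = organ_max_props(state, cp)
    for nutrient, up, stock, maxes in (("n", n_up, state.n, n_max),
                                       ("p", p_up, state.p, p_max)):
        if up <= 0:
            continue
        deficits = {o: max(0.0, state.mass[o] * maxes[o] - stock[o])
                    for o in ("root", "leaf", "stem")}
        total = sum(deficits.values())
        if total <= 0:
            stock["leaf"] += up   # luxury uptake parks in the leaf
            continue
        for organ, deficit in deficits.items():
            stock[organ] += up * min(1.0, deficit / total)
        extra = up - sum(up * min(1.0, d / total) for d in deficits.values())
        stock["leaf"] += extra


def translocate_to_storage(state: CropState, cp: CropParams) -> None:
    """Post-anthesis: move N and P from vegetative organs into the storage
    organ at a first-order daily rate, down to the residual contents."""
    if state.dvs < 1.0 or state.mass["storage"] <= 0.0:
        return
    res_n = {"leaf": cp.n_res, "stem": cp.n_res, "root": cp.n_res_root}
    res_p = {"leaf": cp.p_res_leaf, "stem": cp.p_res_stem,
             "root": cp.p_res_root}
    for nutrient, stock, res, cap_prop in (
            ("n", state.n, res_n, cp.n_max_storage),
            ("p", state.p, res_p, cp.p_max_storage)):
        headroom = max(0.0, state.mass["storage"] * cap_prop
                       - stock["storage"])
        if headroom <= 0:
            continue
        moved = 0.0
        for organ in ("leaf", "stem", "root"):
            transferable = max(0.0, stock[organ]
                               - state.mass[organ] * res[organ])
            take = min(transferable * cp.transloc_rate, headroom - moved)
            stock[organ] -= take
            moved += take
            if moved >= headroom:
                break
        stock["storage"] += moved


# --- senescence, litter, removal -------------------------------------------

@dataclass
class OrganicReturn:
    """C, N, P (kg ha-1) handed from the crop to the soil organic pools."""

    c: float = 0.0
    n: float = 0.0
    p: float = 0.0

    def add(self, mass_g_m2: float, n_g_m2: float, p_g_m2: float,
            c_frac: float = 0.45) -> None:
        self.c += mass_g_m2 * c_frac * G_M2_TO_KG_HA
        self.n += n_g_m2 * G_M2_TO_KG_HA
        self.p += p_g_m2 * G_M2_TO_KG_HA


def leaf_death_rate(state: CropState, day: WeatherDay, n_ni: float,
                    cp: CropParams) -> float:
    """Relative leaf death rate from heat stress, N stress and shading."""
    rate = 0.0
    if day.tmax > cp.leaf_death_heat_t:
        rate = max(rate, cp.leaf_death_heat_rate)
    rate = max(rate, cp.leaf_death_n_rate * (1.0 - n_ni))
    if state.lai > cp.leaf_death_shade_lai:
        rate = max(rate, cp.leaf_death_shade_rate
                   * (state.lai - cp.leaf_death_shade_lai)
                   / cp.leaf_death_shade_lai)
    return min(rate, 1.0)


def senesce_and_return(state: CropState, day: WeatherDay, n_ni: float,
                       cp: CropParams) -> OrganicReturn:
    """Kill leaves and roots; move dead material to litter.

    Dying leaves join the standing dead pool; half of the standing dead
    becomes litter daily.  Root death starts late season for crops
    (DVS > 1.5) and after establishment for grass.  All dead C, N and P is
    returned to the soil (litter + dead roots).
    """
    ret = OrganicReturn()
    if not state.emerged:
        return ret
    # leaf death into the standing-dead pool
    rate = leaf_death_rate(state, day, n_ni, cp)
    if rate > 0 and state.mass["leaf"] > 0:
        dm = state.mass["leaf"] * rate
        dn = state.n["leaf"] * rate
        dp = state.p["leaf"] * rate
        state.mass["leaf"] -= dm
        state.n["leaf"] -= dn
        state.p["leaf"] -= dp
        state.dead_leaf += dm
        state.dead_leaf_n += dn
        state.dead_leaf_p += dp
    # standing dead -> litter
    if state.dead_leaf > 0:
        frac = cp.litter_frac
        ret.add(state.dead_leaf * frac, state.dead_leaf_n * frac,
                state.dead_leaf_p * frac)
        state.dead_leaf *= (1.0 - frac)
        state.dead_leaf_n *= (1.0 - frac)
        state.dead_leaf_p *= (1.0 - frac)
    # root death
    if state.kind == "grass":
        established = (state.dvs >= cp.grass_establish_dvs
                       or state.days_since_sowing >= cp.grass_establish_days)
        r = cp.grass_root_death_rate if established else 0.0
    else:
        r = cp.root_death_rate if state.dvs > cp.root_death_dvs else 0.0
    if r > 0 and state.mass["root"] > 0:
        dm = state.mass["root"] * r
        dn = state.n["root"] * r
        dp = state.p["root"] * r
        state.mass["root"] -= dm
        state.n["root"] -= dn
        state.p["root"] -= dp
        ret.add(dm, dn, dp)
    update_lai(state, cp)
    return ret


@dataclass
class Removal:
    """Biomass removed from the system by cutting, grazing or harvest."""

    dry_matter: float = 0.0   # g m-2
    n: float = 0.0            # g m-2
    p: float = 0.0


def cut_or_graze(state: CropState, amount: float | None, cp: CropParams
                 ) -> Removal:
    """Remove aboveground grass biomass, respecting the 50 g m-2 floor.

    ``amount`` is the requested removal (g m-2); None cuts everything above
    the floor.  Removal comes pro rata from leaf, stem and standing dead.
    """
    if state.kind != "grass":
        raise ValueError("cut/graze events apply to grass only")
    removable = max(0.0, state.above_ground - cp.grass_floor)
    take = removable if amount is None else min(amount, removable)
    rem = Removal()
    if take <= 0.0 or state.above_ground <= 0.0:
        return rem
    frac = take / state.above_ground
    for organ in ("leaf", "stem", "storage"):
        rem.dry_matter += state.mass[organ] * frac
        rem.n += state.n[organ] * frac
        rem.p += state.p[organ] * frac
        state.mass[organ] *= (1.0 - frac)
        state.n[organ] *= (1.0 - frac)
        state.p[organ] *= (1.0 - frac)
    rem.dry_matter += state.dead_leaf * frac
    rem.n += state.dead_leaf_n * frac
    rem.p += state.dead_leaf_p * frac
    state.dead_leaf *= (1.0 - frac)
    state.dead_leaf_n *= (1.0 - frac)
    state.dead_leaf_p *= (1.0 - frac)
    update_lai(state, cp)
    return rem


@dataclass
class HarvestResult:
    yield_t_ha: float         # t ha-1 at 85% dry matter
    grain_n: float            # kg ha-1
    grain_p: float            # kg ha-1
    residue: OrganicReturn    # returned to soil


def harvest(state: CropState, cp: CropParams) -> HarvestResult:
    """Remove the storage organ as grain; route residues to the soil.

    Yield converts g DM m-2 to t ha-1 at 85% dry matter (x 0.01 / 0.85).
    Straw (leaf + stem + standing dead) is exported unless
    ``straw_incorporated``; roots and stubble are always returned.
    """
    grain = state.mass["storage"]
    result = HarvestResult(
        yield_t_ha=grain * 0.01 / 0.85,
        grain_n=state.n["storage"] * G_M2_TO_KG_HA,
        grain_p=state.p["storage"] * G_M2_TO_KG_HA,
        residue=OrganicReturn(),
    )
    result.residue.add(state.mass["root"], state.n["root"], state.p["root"])
    straw_m = state.mass["leaf"] + state.mass["stem"] + state.dead_leaf
    straw_n = state.n["leaf"] + state.n["stem"] + state.dead_leaf_n
    straw_p = state.p["leaf"] + state.p["stem"] + state.dead_leaf_p
    if cp.straw_incorporated:
        result.residue.add(straw_m, straw_n, straw_p)
    for organ in ORGANS:
        state.mass[organ] = state.n[organ] = state.p[organ] = 0.0
    state.dead_leaf = state.dead_leaf_n = state.dead_leaf_p = 0.0
    state.emerged = False
    update_lai(state, cp)
    return result


def grazing_returns(animal: str, stocking: float, gp: GrazingParams
                    ) -> tuple[float, float]:
    """Manure (C, N) deposited per ha per day for a stocking rate."""
    return (gp.manure_c[animal] * stocking, gp.manure_n[animal] * stocking)
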