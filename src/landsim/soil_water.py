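"""Three-layer capacity ("tipping bucket") soil water model.

Retention anchors come from the continuous HYPRES pedotransfer regressions
(van Genuchten form, topsoil/subsoil variants) evaluated at -5, -10, -40 and
-1500 kPa.  Infiltration fills layers to field capacity from the top down;
excess from layer 3 is drainage.  Runoff is generated by capacity excess over
a slope-reduced surface storage.  Topsoil bulk density (and hence thickness
and the retention curve) responds to organic carbon through a nomogram-style
harmonic mixing rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .params import WaterParams
from .weather import WeatherDay, penman_pet

# tension (kPa) -> head (cm water)
KPA_TO_CM = 10.19716
TENSIONS_KPA = {"a": 5.0, "fc": 10.0, "d": 40.0, "wp": 1500.0}


@dataclass
class RetentionAnchors:
    theta_sat: float
    theta_a: float    # -5 kPa
    theta_fc: float   # -10 kPa
    theta_d: float    # -40 kPa
    theta_wp: float   # -1500 kPa


def hypres_vg_params(clay: float, silt: float, om: float, bd: float,
                     topsoil: bool) -> tuple[float, float, float, float]:
    """HYPRES continuous regressions -> (theta_s, theta_r, alpha cm-1, n).

    Inputs outside the pedotransfer calibration range are clamped with a
    warning (texture percent in (0, 100), OM > 0, BD in (0.5, 2.0)).
    """
    lo_c, lo_s, lo_om = 0.5, 0.5, 0.1
    if not (lo_c <= clay <= 95 and lo_s <= silt <= 95 and om >= lo_om
            and 0.5 < bd < 2.0):
        warnings.warn("pedotransfer inputs outside calibration range; clamped",
                      stacklevel=2)
    c = min(max(clay, lo_c), 95.0)
    s = min(max(silt, lo_s), 95.0)
    om = max(om, lo_om)
    d = min(max(bd, 0.6), 1.9)
    ts = 1.0 if topsoil else 0.0

    theta_s = (0.7919 + 0.001691 * c - 0.29619 * d - 0.000001491 * s * s
               + 0.0000821 * om * om + 0.02427 / c + 0.01113 / s
               + 0.01472 * math.log(s) - 0.0000733 * om * c - 0.000619 * d * c
               - 0.001183 * d * om - 0.0001664 * ts * s)
    ln_alpha = (-14.96 + 0.03135 * c + 0.0351 * s + 0.646 * om + 15.29 * d
                - 0.192 * ts - 4.671 * d * d - 0.000781 * c * c
                - 0.00687 * om * om + 0.0449 / om + 0.0663 * math.log(s)
                + 0.1482 * math.log(om) - 0.04546 * d * s - 0.4852 * d * om
                + 0.00673 * ts * c)
    ln_n1 = (-25.23 - 0.02195 * c + 0.0074 * s - 0.1940 * om + 45.5 * d
             - 7.24 * d * d + 0.0003658 * c * c + 0.002885 * om * om
             - 12.81 / d - 0.1524 / s - 0.01958 / om - 0.2876 * math.log(s)
             - 0.0709 * math.log(om) - 44.6 * math.log(d) - 0.02264 * d * c
             + 0.0896 * d * om + 0.00718 * ts * c)
    return theta_s, 0.01, math.exp(ln_alpha), 1.0 + math.exp(ln_n1)


def van_genuchten(theta_s: float, theta_r: float, alpha: float, n: float,
                  head_cm: float) -> float:
    m = 1.0 - 1.0 / n
    return theta_r + (theta_s - theta_r) / (1.0 + (alpha * head_cm) ** n) ** m


def hypres_retention(clay: float, silt: float, om: float, bd: float,
                     topsoil: bool) -> RetentionAnchors:
    """Retention anchors (volumetric fractions) at the model tensions."""
    theta_s, theta_r, alpha, n = hypres_vg_params(clay, silt, om, bd, topsoil)
    th = {k: van_genuchten(theta_s, theta_r, alpha, n, kpa * KPA_TO_CM)
          for k, kpa in TENSIONS_KPA.items()}
    return RetentionAnchors(theta_s, th["a"], th["fc"], th["d"], th["wp"])


@dataclass
class SoilLayer:
    """One soil layer: texture, retention anchors, water and nutrient pools."""

    thickness: float          # mm
    clay: float               # mass %
    silt: float
    sand: float
    ph: float
    bulk_density: float       # g cm-3
    anchors: RetentionAnchors
    water: float = 0.0        # mm stored
    n_nh4: float = 0.0        # kg N ha-1
    n_no3: float = 0.0
    p_av: float = 0.0         # kg P ha-1
    p_nonav: float = 0.0

    def __post_init__(self):
        if abs(self.clay + self.silt + self.sand - 100.0) > 0.5:
            raise ValueError("clay + silt + sand must be 100 +/- 0.5")

    @property
    def theta(self) -> float:
        return self.water / self.thickness

    @property
    def sat_mm(self) -> float:
        return self.anchors.theta_sat * self.thickness

    @property
    def fc_mm(self) -> float:
        return self.anchors.theta_fc * self.thickness

    @property
    def wp_mm(self) -> float:
        return self.anchors.theta_wp * self.thickness

    def air_dry_mm(self, air_dry_frac: float) -> float:
        return air_dry_frac * self.anchors.theta_wp * self.thickness

    @property
    def soil_mass(self) -> float:
        """Layer soil mass, t ha-1 (thickness mm x BD g cm-3 x 10)."""
        return 10.0 * self.thickness * self.bulk_density

    @property
    def wfps(self) -> float:
        return self.water / self.sat_mm


def slope_storage(s_max: float, gradient: float, g_max: float) -> float:
    """Surface storage reduced by mean cell gradient: S=(1-g/gmax)*Smax."""
    if g_max <= 0:
        raise ValueError("g_max must be positive")
    if gradient < 0:
        raise ValueError("gradient must be >= 0")
    if gradient > g_max:
        warnings.warn("gradient exceeds g_max; storage clamped to 0",
                      stacklevel=2)
        return 0.0
    return (1.0 - gradient / g_max) * s_max


def partition_rain(rain: float, storage: float, layer1: SoilLayer,
                   limit: str = "saturation") -> tuple[float, float]:
    """Split surface water into (infiltration, runoff).

    Runoff is the capacity excess over slope-reduced surface storage plus the
    layer-1 intake capacity for the day (deficit to saturation by default).
    """
    if rain < 0:
        raise ValueError("rain must be >= 0")
    cap = layer1.sat_mm if limit == "saturation" else layer1.fc_mm
    deficit = max(0.0, cap - layer1.water)
    runoff = max(0.0, rain - storage - deficit)
    return rain - runoff, runoff


def drain_cascade(profile: list[SoilLayer], infiltration: float
                  ) -> tuple[list[float], float]:
    """Fill layers to field capacity top-down; return per-layer downward
    fluxes F_W(l) (l -> l+1, last entry = drainage) and the drainage.

    Water mass is conserved: infiltration = sum of storage change + drainage.
    """
    if infiltration < 0:
        raise ValueError("infiltration must be >= 0")
    flux = []
    incoming = infiltration
    for layer in profile:
        room = max(0.0, layer.fc_mm - layer.water)
        kept = min(incoming, room)
        layer.water += kept
        incoming -= kept
        flux.append(incoming)
    return flux, incoming


def soil_evaporation(day: WeatherDay, cover: float, layer1: SoilLayer,
                     latitude: float, wp: WaterParams,
                     pet: float | None = None) -> float:
    """Evaporate the bare-soil share of Penman potential ET from layer 1.

    Supply-limited by extractable water above air dry.  Returns mm removed.
    """
    if not 0.0 <= cover <= 1.0:
        raise ValueError("cover fraction must be in [0, 1]")
    if pet is None:
        pet = penman_pet(day, latitude, wp.albedo, wp.psychrometric,
                         wp.latent_heat)
    demand = (1.0 - cover) * pet
    supply = max(0.0, layer1.water - layer1.air_dry_mm(wp.air_dry_frac))
    evap = min(demand, supply)
    layer1.water -= evap
    return evap


def _mineral_bd(sand: float, clay: float) -> float:
    # smooth texture surface approximating the mineral-fraction bulk density
    # nomogram: sandy soils pack denser, clays looser
    return min(1.8, max(1.1, 1.35 + 0.0045 * sand - 0.0020 * clay))


def nomogram_bulk_density(sand: float, clay: float, organic_c: float,
                          bd_organic: float = 0.224,
                          om_conversion: float = 1.724) -> float:
    """Whole-soil bulk density (g cm-3) from texture and organic carbon.

    Harmonic (mass-weighted volume) mixing of the organic-matter and
    mineral-fraction bulk densities; strictly decreasing in organic C.
    """
    om = min(95.0, max(0.0, organic_c * om_conversion))
    bd_min = _mineral_bd(sand, clay)
    return 100.0 / (om / bd_organic + (100.0 - om) / bd_min)


def update_bulk_density(layer: SoilLayer, organic_c_pct: float,
                        wp: WaterParams) -> None:
    """Refresh topsoil bulk density, thickness and retention anchors.

    Thickness rescales so the layer's mineral soil mass is conserved:
    delta_new * BD_new = delta_old * BD_old.
    """
    bd_new = nomogram_bulk_density(layer.sand, layer.clay, organic_c_pct,
                                   wp.bd_organic, wp.om_conversion)
    layer.thickness = layer.thickness * layer.bulk_density / bd_new
    layer.bulk_density = bd_new
    om = organic_c_pct * wp.om_conversion
    layer.anchors = hypres_retention(layer.clay, layer.silt, om, bd_new,
                                     topsoil=True)
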