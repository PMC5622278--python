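"""Mineral nitrogen dynamics: deposition, surface runoff loss, leaching,
nitrification (with an N2O by-product), denitrification (N2O and N2) and
crop uptake supply.

All pools and fluxes are kg N ha-1 (per day where rates).  Gas fluxes are
capped so pools never go negative; layer 3 is assumed biologically inactive
for denitrification.
"""

from __future__ import annotations

import math
from .params import NitrogenParams
from .soil_water import SoilLayer


def ph_factor(ph: float) -> float:
    """Tent-shaped pH response: 0 at pH 0, 1 at pH 7, 0 at pH 14."""
    if ph <= 0.0 or ph >= 14.0:
        return 0.0
    return ph / 7.0 if ph <= 7.0 else (14.0 - ph) / 7.0


def atmospheric_deposition(date, np_: NitrogenParams | None = None) -> float:
    """Daily NO3- deposition (kg N ha-1 d-1), linear between the 1966 and
    2012 annual endpoints (35 -> 20 kg N yr-1), clamped outside.

    The annual rate is spread evenly as rate/365 (leap days receive the
    same daily rate).
    """
    np_ = np_ or NitrogenParams()
    year = date.year
    frac = (year - np_.dep_year0) / (np_.dep_year1 - np_.dep_year0)
    frac = min(1.0, max(0.0, frac))
    annual = np_.dep_rate0 + frac * (np_.dep_rate1 - np_.dep_rate0)
    return annual / 365.0


def surface_water(layer1: SoilLayer, air_dry_frac: float) -> float:
    """W_Surf: water (mm) held in the top 20 mm at runoff mixing, given by
    the saturation minus air-dry water content over that depth."""
    a = layer1.anchors
    return (a.theta_sat - air_dry_frac * a.theta_wp) * 20.0


def runoff_n(layer1: SoilLayer, w_run: float, w_surf: float) -> float:
    """Mineral N (kg ha-1) carried by runoff from the top 20 mm; removes it
    from the layer pools pro rata NH4:NO3."""
    if w_run < 0 or w_surf < 0:
        raise ValueError("runoff and surface water must be >= 0")
    if w_run + w_surf == 0.0:
        return 0.0
    n_surf = (20.0 / layer1.thickness) * (layer1.n_nh4 + layer1.n_no3)
    n_run = n_surf * w_run / (w_run + w_surf)
    total = layer1.n_nh4 + layer1.n_no3
    if total > 0:
        layer1.n_nh4 -= n_run * layer1.n_nh4 / total
        layer1.n_no3 -= n_run * layer1.n_no3 / total
    return n_run


def leach_no3(profile: list[SoilLayer], water_flux: list[float]
              ) -> tuple[list[float], float]:
    """Convective NO3- movement down the profile with the drainage fluxes.

    water_flux[l] is the water (mm) flowing out of layer l downward.  The
    flux of N out of layer l is min(pool, concentration x water), evaluated
    top-down so transfers cascade within the day.  Returns (per-layer N
    fluxes, N leached below the bottom layer).
    """
    n_flux = []
    for layer, f_w in zip(profile, water_flux):
        if f_w < 0:
            raise ValueError("water flux must be >= 0")
        if f_w == 0.0 or layer.water <= 0.0 or layer.n_no3 <= 0.0:
            n_flux.append(0.0)
            continue
        gamma = layer.n_no3 / layer.water
        out = max(0.0, min(layer.n_no3, gamma * f_w))
        n_flux.append(out)
    for i, out in enumerate(n_flux):
        profile[i].n_no3 -= out
        if i + 1 < len(profile):
            profile[i + 1].n_no3 += out
    return n_flux, n_flux[-1] if n_flux else 0.0


def nitrification_f_t(t_soil: float, np_: NitrogenParams) -> float:
    """Saturating Q10-style temperature response, 0.5 at 10 degC, capped 1."""
    if t_soil <= -5.0:
        return 0.0
    return min(1.0, 0.5 * np_.nitrif_q10 **
               ((t_soil - np_.nitrif_t_half) / 10.0))


def nitrification_g_m(layer: SoilLayer) -> float:
    """Moisture response: plant-available water fraction, clamped [0, 1]."""
    a = layer.anchors
    span = (a.theta_fc - a.theta_wp) * layer.thickness
    if span <= 0:
        return 0.0
    return min(1.0, max(0.0, (layer.water - a.theta_wp * layer.thickness)
                        / span))


def nitrify(layer: SoilLayer, f_t: float, g_m: float, np_: NitrogenParams
            ) -> tuple[float, float]:
    """Oxidise NH4+ to NO3- with a small N2O by-product.

    N2O = k_N2O * NH4 * S_pH * (1 - WFPS); the nitrate produced follows a
    saturating first-order step on the NH4 above the floor N_min.
    Returns (NO3- produced, N2O emitted), both removed from NH4+.
    """
    if not (0.0 <= f_t <= 1.0 and 0.0 <= g_m <= 1.0):
        raise ValueError("f_t and g_m must be in [0, 1]")
    s_ph = ph_factor(layer.ph)
    wfps = min(1.0, max(0.0, layer.wfps))
    n2o = np_.k_n2o * layer.n_nh4 * s_ph * (1.0 - wfps)
    n2o = min(n2o, layer.n_nh4)
    no3 = max((layer.n_nh4 - n2o - np_.n_min)
              * (1.0 - math.exp(-np_.k_nitrif * f_t * g_m)), 0.0)
    no3 = min(no3, layer.n_nh4 - n2o)
    layer.n_nh4 -= n2o + no3
    layer.n_no3 += no3
    return no3, n2o


def denit_wfps_factor(wfps: float, np_: NitrogenParams) -> float:
    """Water-filled-pore-space response of denitrification N2O."""
    w = min(0.99, max(0.01, wfps))
    z = math.log(w / (1.0 - w))
    return math.exp(-np_.wfps_coef * z * z - np_.wfps_const)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def denitrify(layer: SoilLayer, t_soil: float, np_: NitrogenParams,
              active: bool = True) -> tuple[float, float]:
    """Denitrification N2O and N2 (kg N ha-1 d-1) from one layer.

    N2O = a * NO3 * f(WFPS) * exp(-w (T - T_opt)^2); N2 = c * NO3 *
    sigma(0.14975 T - 4) * sigma(12 (WFPS - 0.62)).  Inactive layers
    (layer 3) emit nothing.  Both fluxes are drawn from the NO3- pool,
    jointly capped at the pool size.
    """
    if not active or layer.n_no3 <= 0.0:
        return 0.0, 0.0
    wfps = layer.wfps
    n2o = (np_.denit_a * layer.n_no3 * denit_wfps_factor(wfps, np_)
           * math.exp(-np_.t_width * (t_soil - np_.t_opt) ** 2))
    n2 = (np_.n2_coef * layer.n_no3
          * _logistic(np_.n2_t_slope * t_soil - np_.n2_t_const)
          * _logistic(np_.n2_wfps_slope * (wfps - np_.n2_wfps_mid)))
    total = n2o + n2
    if total > layer.n_no3:
        scale = layer.n_no3 / total
        n2o *= scale
        n2 *= scale
    layer.n_no3 -= n2o + n2
    return n2o, n2


def supply_n_uptake(profile: list[SoilLayer], root_fractions: list[float],
                    demand: float, np_: NitrogenParams) -> float:
    """Deliver crop N demand from rooted-layer NO3-, capped at 6 kg ha-1 d-1.

    Drawn pro rata root fraction, then topped up from any rooted layer with
    remaining nitrate if a layer runs short.
    """
    if demand < 0:
        raise ValueError("demand must be >= 0")
    available = sum(layer.n_no3 for layer, f in zip(profile, root_fractions)
                    if f > 0)
    delivered = min(demand, available, np_.uptake_cap)
    if delivered <= 0.0:
        return 0.0
    remaining = delivered
    # first pass pro rata roots, second pass whatever is left
    for pass_ in range(2):
        for layer, f in zip(profile, root_fractions):
            if f <= 0 or remaining <= 0:
                continue
            want = delivered * f if pass_ == 0 else remaining
            take = min(want, layer.n_no3, remaining)
            layer.n_no3 -= take
            remaining -= take
    return delivered - max(0.0, remaining)
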