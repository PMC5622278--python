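"""Two-pool mineral phosphorus: available / non-available P with daily
re-equilibration, runoff and leaching of the mobile fractions, fertiliser
split and crop uptake supply.

The equilibrium partition comes from piecewise-linear Olsen-P vs total-P
regressions: V(P_Tot) is the equilibrium available fraction, RRF = V/(1-V)
the release:fixation ratio.  A pulse of available P relaxes back towards the
equilibrium at rate lambda*(1+RRF)*f_pH per day (half-life ~65 days for a
Broadbalk-like topsoil at pH 7).
"""

from __future__ import annotations

from .params import PhosphorusParams
from .nitrogen import ph_factor
from .soil_water import SoilLayer


def total_p_concentration(layer: SoilLayer) -> float:
    """Mineral P concentration (mg kg-1) from the kg ha-1 pools."""
    return 100.0 * (layer.p_av + layer.p_nonav) / (
        layer.thickness * layer.bulk_density)


def equilibrium_fraction(p_tot: float, pp: PhosphorusParams) -> float:
    """Equilibrium available fraction V from total mineral P (mg kg-1)."""
    if p_tot <= 0:
        raise ValueError("P_Tot must be positive")
    junction = (pp.beta_a - pp.beta_b) / (pp.alpha_b - pp.alpha_a)
    if p_tot > junction:
        v = (pp.alpha_b * p_tot + pp.beta_b) / p_tot
    else:
        v = (pp.alpha_a * p_tot + pp.beta_a) / p_tot
    return min(pp.v_max, max(pp.v_min, v))


def release_fixation_ratio(v: float) -> float:
    return v / (1.0 - v)


def reequilibrate(layer: SoilLayer, pp: PhosphorusParams) -> tuple[float, float]:
    """One daily step of the two-pool exchange; total P conserved exactly.

    Both transfers are evaluated from the same-day state and applied
    simultaneously:  Av->NA = lambda*P_Av*f_pH,  NA->Av =
    lambda*P_NonAv*RRF*f_pH.  Returns the two transfers (kg P ha-1).
    """
    p_tot = total_p_concentration(layer)
    if p_tot <= 0:
        return 0.0, 0.0
    v = equilibrium_fraction(p_tot, pp)
    rrf = release_fixation_ratio(v)
    f_ph = ph_factor(layer.ph)
    av_to_na = pp.lam * layer.p_av * f_ph
    na_to_av = pp.lam * layer.p_nonav * rrf * f_ph
    layer.p_av += na_to_av - av_to_na
    layer.p_nonav += av_to_na - na_to_av
    return av_to_na, na_to_av


def fertilise_p(layer: SoilLayer, dose: float, pp: PhosphorusParams) -> None:
    """Apply mineral P fertiliser: 80% to available, 20% to non-available."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    layer.p_av += pp.fert_avail_frac * dose
    layer.p_nonav += (1.0 - pp.fert_avail_frac) * dose


def runoff_p(layer1: SoilLayer, w_run: float, w_surf: float,
             pp: PhosphorusParams) -> float:
    """Mobile P (10% of P_Av) lost in runoff from the top 20 mm."""
    if w_run < 0 or w_surf < 0:
        raise ValueError("runoff and surface water must be >= 0")
    if w_run + w_surf == 0.0:
        return 0.0
    p_m = pp.mobile_frac * layer1.p_av
    p_surf = (20.0 / layer1.thickness) * p_m
    p_run = p_surf * w_run / (w_run + w_surf)
    layer1.p_av -= p_run
    return p_run


def leach_p(profile: list[SoilLayer], water_flux: list[float],
            pp: PhosphorusParams) -> tuple[list[float], float]:
    """Solution P (1% of P_Av) moves with drainage water analogously to
    nitrate.  Returns (per-layer fluxes, P leached from the bottom layer)."""
    p_flux = []
    for layer, f_w in zip(profile, water_flux):
        if f_w <= 0.0 or layer.water <= 0.0 or layer.p_av <= 0.0:
            p_flux.append(0.0)
            continue
        solution = pp.solution_frac * layer.p_av
        gamma = solution / layer.water
        p_flux.append(max(0.0, min(solution, gamma * f_w)))
    for i, out in enumerate(p_flux):
        profile[i].p_av -= out
        if i + 1 < len(profile):
            profile[i + 1].p_av += out
    return p_flux, p_flux[-1] if p_flux else 0.0


def supply_p_uptake(profile: list[SoilLayer], root_fractions: list[float],
                    demand: float, pp: PhosphorusParams) -> float:
    """Deliver crop P demand from rooted-layer available P, capped at
    2 kg P ha-1 d-1, drawn pro rata root fraction."""
    if demand < 0:
        raise ValueError("demand must be >= 0")
    available = sum(layer.p_av for layer, f in zip(profile, root_fractions)
                    if f > 0)
    delivered = min(demand, available, pp.uptake_cap)
    if delivered <= 0.0:
        return 0.0
    remaining = delivered
    for pass_ in range(2):
        for layer, f in zip(profile, root_fractions):
            if f <= 0 or remaining <= 0:
                continue
            want = delivered * f if pass_ == 0 else remaining
            take = min(want, layer.p_av, remaining)
            layer.p_av -= take
            remaining -= take
    return delivered - max(0.0, remaining)


def immobilise_p(layer: SoilLayer, amount: float) -> float:
    """Draw immobilised P from available first, then non-available.

    Returns the amount actually supplied (callers cancel decomposition if
    this falls short).
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    from_av = min(amount, layer.p_av)
    layer.p_av -= from_av
    rest = amount - from_av
    from_na = min(rest, layer.p_nonav)
    layer.p_nonav -= from_na
    return from_av + from_na
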