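"""Soil organic matter: four-pool first-order carbon turnover with coupled
nitrogen and phosphorus stocks.

Carbon sits in DPM, RPM, BIO and HUM pools (plus inert IOM).  Each active
pool decays first-order, modified by temperature, moisture and plant cover;
decomposed C splits between CO2 and (BIO, HUM) by a clay-dependent ratio.
N and P ride along: BIO and HUM hold fixed C:N (8.5) and C:P (50 / 100)
ratios, DPM and RPM ratios reflect the mixture of their inputs.  Net
mineralisation adds NH4+ (or available P); net immobilisation draws from the
mineral pools, and if mineral N (or P) cannot cover the demand the whole
day's decomposition is cancelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import OrganicParams

POOLS = ("dpm", "rpm", "bio", "hum")


@dataclass
class OrganicPools:
    """C / N / P stocks (t ha-1) for the four active pools plus inert C."""

    c: dict = field(default_factory=lambda: dict.fromkeys(POOLS, 0.0))
    n: dict = field(default_factory=lambda: dict.fromkeys(POOLS, 0.0))
    p: dict = field(default_factory=lambda: dict.fromkeys(POOLS, 0.0))
    iom: float = 0.0

    @property
    def total_c(self) -> float:
        return sum(self.c.values()) + self.iom

    @property
    def active_c(self) -> float:
        return sum(self.c.values())

    @property
    def total_n(self) -> float:
        return sum(self.n.values())

    @property
    def total_p(self) -> float:
        return sum(self.p.values())

    def cn(self, pool: str) -> float:
        return self.c[pool] / self.n[pool] if self.n[pool] > 0 else math.inf

    def cp(self, pool: str) -> float:
        return self.c[pool] / self.p[pool] if self.p[pool] > 0 else math.inf

    def copy(self) -> "OrganicPools":
        return OrganicPools(dict(self.c), dict(self.n), dict(self.p), self.iom)


def falloon_iom(toc: float) -> float:
    """Inert organic matter estimate from total organic C (t ha-1)."""
    return 0.049 * toc ** 1.139


@dataclass
class DecompositionStep:
    """One day's decomposition fluxes (t C ha-1 d-1 per pool)."""

    delta: dict          # C leaving each pool
    to_bio: dict         # share routed to BIO
    to_hum: dict         # share routed to HUM
    co2: dict            # share respired
    f_t: float
    f_m: float
    f_cover: float

    @property
    def total_co2(self) -> float:
        return sum(self.co2.values())


def rate_modifier_temperature(t_air: float) -> float:
    """Temperature rate modifier; zero at or below -18.27 degC."""
    if t_air <= -18.27:
        return 0.0
    return 47.91 / (1.0 + math.exp(106.06 / (t_air + 18.27)))


def rate_modifier_moisture(deficit: float, max_deficit: float,
                           op: OrganicParams) -> float:
    """Moisture modifier: 1 while the topsoil deficit is small, declining
    linearly to ``fm_min`` at the maximum deficit."""
    if max_deficit <= 0:
        return 1.0
    knee = op.fm_knee * max_deficit
    if deficit <= knee:
        return 1.0
    frac = (max_deficit - min(deficit, max_deficit)) / (max_deficit - knee)
    return op.fm_min + (1.0 - op.fm_min) * frac


def rate_modifiers(t_air: float, deficit: float, max_deficit: float,
                   covered: bool, op: OrganicParams
                   ) -> tuple[float, float, float]:
    f_t = rate_modifier_temperature(t_air)
    f_m = rate_modifier_moisture(deficit, max_deficit, op)
    f_c = op.fcov_covered if covered else op.fcov_bare
    return f_t, f_m, f_c


def clay_co2_ratio(clay: float) -> float:
    """CO2 : (BIO+HUM) partition ratio x as a function of clay content."""
    return 1.67 * (1.85 + 1.60 * math.exp(-0.0786 * clay))


def decompose(pools: OrganicPools, modifiers: tuple[float, float, float],
              clay: float, op: OrganicParams, dt: float = 1.0
              ) -> DecompositionStep:
    """First-order decay of each active pool over dt days (no state change)."""
    f_t, f_m, f_c = modifiers
    rate = f_t * f_m * f_c * dt / 365.0
    ks = {"dpm": op.k_dpm, "rpm": op.k_rpm, "bio": op.k_bio, "hum": op.k_hum}
    x = clay_co2_ratio(clay)
    co2_frac = x / (x + 1.0)
    delta, to_bio, to_hum, co2 = {}, {}, {}, {}
    for pool in POOLS:
        d = pools.c[pool] * (1.0 - math.exp(-ks[pool] * rate))
        delta[pool] = d
        co2[pool] = d * co2_frac
        formed = d - co2[pool]
        to_bio[pool] = formed * op.bio_fraction
        to_hum[pool] = formed * (1.0 - op.bio_fraction)
    return DecompositionStep(delta, to_bio, to_hum, co2, f_t, f_m, f_c)


def mineralisation_flux(step: DecompositionStep, pools: OrganicPools,
                        op: OrganicParams) -> tuple[float, float]:
    """Net (N, P) mineralisation in t ha-1 d-1 implied by a step.

    Per pool: M_i = Delta_i/rho_i - B_i/rho_bio - U_i/rho_hum, with rho the
    C:N (or C:P) ratio.  Positive = mineralisation, negative = immobilisation.
    """
    m_n = m_p = 0.0
    for pool in POOLS:
        if step.delta[pool] == 0.0:
            continue
        rho_n = pools.cn(pool)
        rho_p = pools.cp(pool)
        m_n += (step.delta[pool] / rho_n - step.to_bio[pool] / op.cn_bio
                - step.to_hum[pool] / op.cn_hum)
        m_p += (step.delta[pool] / rho_p - step.to_bio[pool] / op.cp_bio
                - step.to_hum[pool] / op.cp_hum)
    return m_n, m_p


def mineralise(step: DecompositionStep, pools: OrganicPools,
               mineral_n_available: float, mineral_p_available: float,
               op: OrganicParams) -> tuple[float, float, bool]:
    """Apply a decomposition step to the pools.

    Returns (net N flux, net P flux, performed) in kg ha-1 d-1.  If the
    implied immobilisation exceeds the available mineral N (or P), the day's
    decomposition is cancelled and the pools are left untouched.
    """
    m_n, m_p = mineralisation_flux(step, pools, op)
    # t ha-1 -> kg ha-1
    m_n_kg, m_p_kg = m_n * 1000.0, m_p * 1000.0
    if (m_n_kg < 0 and -m_n_kg > mineral_n_available + 1e-12) or \
       (m_p_kg < 0 and -m_p_kg > mineral_p_available + 1e-12):
        return 0.0, 0.0, False
    for pool in POOLS:
        d = step.delta[pool]
        if d > 0 and pools.c[pool] > 0:
            frac = d / pools.c[pool]
            pools.n[pool] -= pools.n[pool] * frac
            pools.p[pool] -= pools.p[pool] * frac
            pools.c[pool] -= d
    bio_in = sum(step.to_bio.values())
    hum_in = sum(step.to_hum.values())
    pools.c["bio"] += bio_in
    pools.c["hum"] += hum_in
    pools.n["bio"] += bio_in / op.cn_bio
    pools.n["hum"] += hum_in / op.cn_hum
    pools.p["bio"] += bio_in / op.cp_bio
    pools.p["hum"] += hum_in / op.cp_hum
    return m_n_kg, m_p_kg, True


def add_organic_input(pools: OrganicPools, c_amount: float, source: str,
                      cn: float, cp: float, op: OrganicParams) -> None:
    """Add fresh organic C (t ha-1) with its stoichiometry.

    Crop residue splits DPM:RPM (59:41 by default); farmyard manure splits
    DPM:RPM:HUM (49:49:2).  Receiving-pool ratios become the stock-weighted
    mixture of old and new material (N and P stocks simply add).
    """
    if c_amount == 0.0:
        return
    if c_amount < 0:
        raise ValueError("organic input must be >= 0")
    if cn <= 0 or cp <= 0:
        raise ValueError("input C:N and C:P must be positive")
    if source == "residue":
        split = {"dpm": op.residue_dpm, "rpm": 1.0 - op.residue_dpm}
    elif source == "fym":
        split = {"dpm": op.fym_dpm, "rpm": op.fym_rpm, "hum": op.fym_hum}
    else:
        raise ValueError(f"unknown organic input source {source!r}")
    total_n = c_amount / cn
    total_p = c_amount / cp
    # HUM keeps its fixed stoichiometry; the balance of the input's N and P
    # is carried by the DPM/RPM stocks so total input N and P are conserved
    c_hum = c_amount * split.get("hum", 0.0)
    hum_n = c_hum / op.cn_hum
    hum_p = c_hum / op.cp_hum
    if hum_n > total_n or hum_p > total_p:
        raise ValueError("input stoichiometry incompatible with HUM routing")
    c_fresh = c_amount - c_hum
    for pool in ("dpm", "rpm"):
        frac = split.get(pool, 0.0)
        c_in = c_amount * frac
        pools.c[pool] += c_in
        share = c_in / c_fresh if c_fresh > 0 else 0.0
        pools.n[pool] += (total_n - hum_n) * share
        pools.p[pool] += (total_p - hum_p) * share
    if c_hum > 0:
        pools.c["hum"] += c_hum
        pools.n["hum"] += hum_n
        pools.p["hum"] += hum_p


def organic_input_n(c_amount: float, cn: float) -> float:
    return c_amount / cn


# --- equilibrium initialisation --------------------------------------------

def _annual_affine_map(modifier_series: np.ndarray, clay: float,
                       input_pattern: np.ndarray, dpm_frac: float,
                       op: OrganicParams) -> tuple[np.ndarray, np.ndarray]:
    """One-year map C -> A C + b for the linear 4-pool C dynamics.

    ``modifier_series`` is the daily product f_T*f_M*f_cover over one year;
    ``input_pattern`` the daily plant C input (t ha-1) at unit magnitude.
    """
    ks = np.array([op.k_dpm, op.k_rpm, op.k_bio, op.k_hum])
    x = clay_co2_ratio(clay)
    keep = 1.0 / (x + 1.0)
    route = np.zeros((4, 4))
    for i in range(4):
        route[2, i] = keep * op.bio_fraction
        route[3, i] = keep * (1.0 - op.bio_fraction)

    def run_year(c0: np.ndarray) -> np.ndarray:
        c = c0.copy()
        for t in range(modifier_series.size):
            frac = 1.0 - np.exp(-ks * modifier_series[t] / 365.0)
            d = c * frac
            c -= d
            c += route @ d
            c[0] += input_pattern[t] * dpm_frac
            c[1] += input_pattern[t] * (1.0 - dpm_frac)
        return c

    b = run_year(np.zeros(4))
    a = np.empty((4, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = 1.0
        a[:, j] = run_year(e) - b
    return a, b


def spinup_to_equilibrium(target_toc: float, clay: float,
                          modifier_series: np.ndarray,
                          input_pattern: np.ndarray,
                          input_cn: float, input_cp: float,
                          op: OrganicParams, iom: float | None = None,
                          tol: float = 1e-3, max_years: int = 5000
                          ) -> tuple[OrganicPools, float]:
    """Initialise pools so steady-state TOC matches a measured target.

    The plant-input magnitude is found by bisection; each candidate is run
    forward (year-by-year through the precomputed one-year map of the daily
    dynamics) until the pools stop changing.  Returns (pools, input scale)
    where scale multiplies ``input_pattern``.  N and P stocks follow from the
    equilibrium C and the pool ratios (DPM/RPM take the input stoichiometry).
    """
    if iom is None:
        iom = falloon_iom(target_toc)
    if target_toc <= iom:
        raise ValueError("target TOC must exceed inert organic matter")
    dpm_frac = op.residue_dpm
    a, b = _annual_affine_map(modifier_series, clay, input_pattern,
                              dpm_frac, op)

    def steady_active(scale: float) -> np.ndarray:
        c = np.zeros(4)
        for _ in range(max_years):
            c_next = a @ c + scale * b
            if np.abs(c_next - c).max() < 1e-10 * max(1.0, c_next.max()):
                return c_next
            c = c_next
        return c

    target_active = target_toc - iom
    lo, hi = 0.0, 1.0
    while steady_active(hi).sum() < target_active:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("equilibrium target unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        total = steady_active(mid).sum()
        if abs(total - target_active) <= tol * target_active:
            break
        if total < target_active:
            lo = mid
        else:
            hi = mid
    c_eq = steady_active(mid)
    pools = OrganicPools(iom=iom)
    for i, pool in enumerate(POOLS):
        pools.c[pool] = float(c_eq[i])
    pools.n["dpm"] = pools.c["dpm"] / input_cn
    pools.n["rpm"] = pools.c["rpm"] / input_cn
    pools.n["bio"] = pools.c["bio"] / op.cn_bio
    pools.n["hum"] = pools.c["hum"] / op.cn_hum
    pools.p["dpm"] = pools.c["dpm"] / input_cp
    pools.p["rpm"] = pools.c["rpm"] / input_cp
    pools.p["bio"] = pools.c["bio"] / op.cp_bio
    pools.p["hum"] = pools.c["hum"] / op.cp_hum
    return pools, mid
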