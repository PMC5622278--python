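"""Model constants and configuration.

All tunable constants of the simulator live on small dataclasses collected in
:class:`Params`.  A run can override any field from a YAML config file with
nested sections mirroring the dataclass names, e.g.::

    nitrogen:
      k_nitrif: 0.12
    water:
      g_max: 0.25

Unknown sections or keys are rejected on load so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class WaterParams:
    """Soil-water constants (capacity model, Penman ET, surface storage)."""

    g_max: float = 0.2              # upper gradient limit in the slope-storage rule
    s_max: float = 10.0             # mm, maximum surface storage of a flat cell
    air_dry_frac: float = 0.33      # air-dry water content as fraction of theta_wp
    albedo: float = 0.23
    psychrometric: float = 0.0665   # kPa / degC
    latent_heat: float = 2.45       # MJ / kg water
    om_conversion: float = 1.724    # TOC -> organic matter (Van Bemmelen)
    bd_organic: float = 0.224       # g cm-3, bulk density of organic matter
    infiltration_limit: str = "saturation"  # layer-1 capacity bound for runoff


@dataclass
class OrganicParams:
    """RothC-style turnover constants with coupled N and P stoichiometry."""

    k_dpm: float = 10.0             # yr-1
    k_rpm: float = 0.3
    k_bio: float = 0.66
    k_hum: float = 0.02
    bio_fraction: float = 0.46      # BIO share of the non-CO2 decomposition flux
    cn_bio: float = 8.5
    cn_hum: float = 8.5
    cp_bio: float = 50.0
    cp_hum: float = 100.0
    fcov_covered: float = 0.6       # plant-retainment modifier when vegetated
    fcov_bare: float = 1.0
    fm_min: float = 0.2
    fm_knee: float = 0.444          # deficit fraction below which f_M = 1
    residue_dpm: float = 0.59       # DPM share of crop residue C
    fym_dpm: float = 0.49
    fym_rpm: float = 0.49
    fym_hum: float = 0.02
    fym_dm_frac: float = 0.25       # fresh weight -> dry matter
    fym_c_frac: float = 0.40        # C fraction of dry matter
    fym_n_per_35t: float = 250.0    # kg N per 35 t fresh dressing
    fym_cp: float = 78.0            # C:P of farmyard manure
    manure_cp: float = 80.0         # C:P of grazing returns


@dataclass
class NitrogenParams:
    """Mineral-N constants: nitrification, denitrification, transport."""

    k_n2o: float = 0.0001           # nitrification N2O yield coefficient
    n_min: float = 0.05             # kg N ha-1, NH4 floor for nitrification
    k_nitrif: float = 0.15
    denit_a: float = 0.000735       # fitted denitrification N2O coefficient
    t_opt: float = 23.65            # degC, denitrification temperature optimum
    t_width: float = 0.00045        # Gaussian width coefficient
    wfps_coef: float = 0.6151
    wfps_const: float = 1.192
    n2_coef: float = 0.0052
    n2_t_slope: float = 0.14975
    n2_t_const: float = 4.0
    n2_wfps_slope: float = 12.0
    n2_wfps_mid: float = 0.62
    uptake_cap: float = 6.0         # kg N ha-1 d-1
    dep_year0: int = 1966
    dep_rate0: float = 35.0         # kg N yr-1
    dep_year1: int = 2012
    dep_rate1: float = 20.0
    nitrif_q10: float = 2.0         # temperature response of nitrification
    nitrif_t_half: float = 10.0     # degC at which f_T = 0.5


@dataclass
class PhosphorusParams:
    """Two-pool mineral-P constants (Olsen-P vs total-P regressions)."""

    alpha_b: float = 0.113
    beta_b: float = -49.3
    alpha_a: float = 0.0201
    beta_a: float = -5.1
    lam: float = 0.01               # d-1 re-equilibration rate
    v_min: float = 0.001
    v_max: float = 0.95
    fert_avail_frac: float = 0.80
    mobile_frac: float = 0.10       # of P_Av, mobile in runoff
    solution_frac: float = 0.01     # of P_Av, leachable solution P
    uptake_cap: float = 2.0         # kg P ha-1 d-1


@dataclass
class CropParams:
    """Parameters of one crop (wheat or grass) for the LUE growth model."""

    kind: str = "wheat"
    lue: float = 3.0                # g DM per MJ intercepted PAR
    extinction: float = 0.6
    sla: float = 0.022              # m2 leaf per g leaf DM
    par_frac: float = 0.5           # PAR fraction of global radiation
    base_temp: float = 0.0
    tsum_emerge: float = 120.0      # degC d sowing -> emergence
    tsum1: float = 1000.0           # emergence -> anthesis (DVS 1)
    tsum2: float = 700.0            # anthesis -> maturity (DVS 2)
    vern_days: float = 40.0         # vernalisation requirement (days)
    vern_tmin: float = 0.0
    vern_tmax: float = 12.0
    photo_base: float = 8.0         # h, daylength ramp start
    photo_sat: float = 16.0         # h, ramp end
    max_root_depth: float = 690.0   # mm
    root_growth: float = 12.0       # mm d-1
    f_r: float = 0.98               # root fraction above d_root
    init_mass: float = 2.0          # g m-2 seedling dry mass at emergence
    n_res: float = 0.004
    n_max_leaf_a: float = 0.046     # leaf N max = a*exp(-1.7 DVS)+b (wheat)
    n_max_leaf_b: float = 0.014
    n_max_leaf_const: float = 0.0425  # grass constant alternative
    stem_factor: float = 0.5
    n_max_root: float = 0.01
    n_res_root: float = 0.002
    n_max_storage: float = 0.025
    p_res_leaf: float = 0.0003
    p_res_stem: float = 0.00018
    p_res_root: float = 0.0002
    p_max_root: float = 0.002
    p_max_storage: float = 0.0035
    # wheat leaf P maximum: piecewise linear in DVS
    p_max_leaf_knots: tuple = ((0.0, 0.0066), (0.7, 0.0036), (1.0, 0.0009))
    p_max_leaf_const: float = 0.0035  # grass
    grass_floor: float = 50.0       # g m-2 minimum standing biomass
    grass_ws_floor: float = 0.4     # water stress floor theta_d..theta_w
    r_lue_lo: float = 10.0          # MJ m-2 d-1, grass radiation ramp
    r_lue_hi: float = 40.0
    r_lue_min: float = 0.33
    t_lue_lo: float = 6.0           # degC, grass temperature ramp
    t_lue_hi: float = 9.0
    root_death_rate: float = 0.02   # d-1 (crop, DVS > 1.5)
    root_death_dvs: float = 1.5
    grass_root_death_rate: float = 0.01
    grass_establish_dvs: float = 0.01
    grass_establish_days: int = 90
    litter_frac: float = 0.5        # of dead leaves, daily
    leaf_death_heat_t: float = 30.0  # degC threshold for heat kill
    leaf_death_heat_rate: float = 0.03
    leaf_death_n_rate: float = 0.01  # scaled by (1 - N_NI)
    leaf_death_shade_lai: float = 6.0
    leaf_death_shade_rate: float = 0.03
    transloc_rate: float = 0.03     # d-1, post-anthesis N/P move to storage
    straw_incorporated: bool = False
    residue_cn_min: float = 20.0
    # DVS-keyed partition tables: (dvs, root, leaf, stem, storage)
    partition: tuple = (
        (0.00, 0.50, 0.33, 0.17, 0.00),
        (0.10, 0.50, 0.33, 0.17, 0.00),
        (0.25, 0.40, 0.42, 0.18, 0.00),
        (0.50, 0.13, 0.44, 0.43, 0.00),
        (0.70, 0.07, 0.28, 0.65, 0.00),
        (0.95, 0.03, 0.00, 0.97, 0.00),
        (1.00, 0.00, 0.00, 0.00, 1.00),
        (2.00, 0.00, 0.00, 0.00, 1.00),
    )


def grass_params() -> CropParams:
    """Default grass parameterisation (perennial, indeterminate, DVS < 1)."""
    return CropParams(
        kind="grass",
        lue=2.8,
        sla=0.025,
        tsum_emerge=100.0,
        tsum1=1500.0,
        vern_days=0.0,
        photo_base=0.0,
        photo_sat=0.1,
        max_root_depth=500.0,
        n_res=0.01,
        p_res_leaf=0.001,
        p_res_stem=0.001,
        partition=(
            (0.00, 0.40, 0.45, 0.15, 0.0),
            (0.50, 0.35, 0.50, 0.15, 0.0),
            (0.99, 0.30, 0.52, 0.18, 0.0),
        ),
    )


@dataclass
class GrazingParams:
    """Per-head daily intake and manure return rates (fresh-deposit basis)."""

    intake: dict = field(default_factory=lambda: {
        "beef": 10.0, "dairy": 16.0, "sheep": 1.5})      # kg DM head-1 d-1
    manure_c: dict = field(default_factory=lambda: {
        "beef": 4.03, "dairy": 6.45, "sheep": 0.45})     # kg C head-1 d-1
    manure_n: dict = field(default_factory=lambda: {
        "beef": 0.22, "dairy": 0.35, "sheep": 0.02})     # kg N head-1 d-1


@dataclass
class Params:
    water: WaterParams = field(default_factory=WaterParams)
    organic: OrganicParams = field(default_factory=OrganicParams)
    nitrogen: NitrogenParams = field(default_factory=NitrogenParams)
    phosphorus: PhosphorusParams = field(default_factory=PhosphorusParams)
    wheat: CropParams = field(default_factory=CropParams)
    grass: CropParams = field(default_factory=grass_params)
    grazing: GrazingParams = field(default_factory=GrazingParams)

    def crop(self, kind: str) -> CropParams:
        if kind == "wheat":
            return self.wheat
        if kind == "grass":
            return self.grass
        raise KeyError(f"unknown crop kind: {kind!r}")


class ConfigError(ValueError):
    """Raised for unknown or ill-typed config entries."""


def _apply(obj: Any, section: str, data: dict) -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")
        current = getattr(obj, key)
        if isinstance(current, (int, float)) and not isinstance(current, bool):
            value = type(current)(value)
        setattr(obj, key, value)


def load_params(path: str | None = None, overrides: dict | None = None) -> Params:
    """Build a :class:`Params`, optionally overridden from a YAML file/dict."""
    params = Params()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    sections = {f.name for f in dataclasses.fields(params)}
    for section, content in data.items():
        if section not in sections:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        _apply(getattr(params, section), section, content)
    return params
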