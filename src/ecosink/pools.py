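"""Century-style carbon--nitrogen pool dynamics at a daily time step.

The carbon stock is split into 4 biomass pools (leaf, stem, coarse root,
fine root) and 9 soil/litter pools (surface structural litter, surface
metabolic litter, soil structural litter, soil metabolic litter, coarse
woody litter, surface microbe, soil microbe, slow, passive). Each day:

* canopy GPP (from :mod:`ecosink.canopy`) minus autotrophic respiration
  (maintenance: biomass- and temperature-dependent with Q10; growth: a
  fixed 25% fraction of GPP) gives NPP;
* NPP is allocated to biomass pools by fixed coefficients (negative NPP
  draws pools down proportionally, floored at zero);
* litterfall transfers biomass to litter pools by base turnover, plus an
  additional transfer when LAI drops faster than its seasonal climatology
  (the disturbance pathway);
* soil pools decompose at ``k * modifier`` with the temperature/moisture
  modifier, each flux split between respired CO2 (heterotrophic
  respiration) and receiver pools by the transfer matrix;
* a single-bucket water balance and a mineral-nitrogen balance close the
  coupling: soil moisture scales stomatal conductance and decomposition,
  leaf nitrogen scales Vcmax.

NEP = GPP - AR - HR holds exactly, and the daily change in total stored
carbon equals NPP - HR to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecosink import canopy
from ecosink.grid import PixelStatic
from ecosink.params import (
    BIOMASS_POOLS,
    N_POOLS,
    POOL_INDEX,
    ParamSet,
    PoolParams,
)

N_BIOMASS = len(BIOMASS_POOLS)
_SLOW = POOL_INDEX["slow"]
_PASSIVE = POOL_INDEX["passive"]
_LEAF = POOL_INDEX["leaf"]


@dataclass
class FluxRecord:
    """Daily carbon fluxes per pixel, g C m-2 d-1."""

    gpp: np.ndarray
    npp: np.ndarray
    ar_maintenance: np.ndarray
    ar_growth: np.ndarray
    hr: np.ndarray
    nep: np.ndarray


@dataclass
class EcosystemState:
    """Per-pixel prognostic state: 13 carbon pools (g C m-2), mineral and
    leaf nitrogen (g N m-2), plant-available soil water (mm) with its
    capacity, and damped soil temperature (degC)."""

    pools: np.ndarray  # (13, n_pix)
    mineral_n: np.ndarray  # (n_pix,)
    leaf_n: np.ndarray  # (n_pix,) g N m-2 in the leaf pool
    soil_water: np.ndarray  # (n_pix,) mm
    water_capacity: np.ndarray  # (n_pix,) mm
    tsoil: np.ndarray  # (n_pix,) degC

    def copy(self) -> "EcosystemState":
        return EcosystemState(*(getattr(self, f).copy() for f in (
            "pools", "mineral_n", "leaf_n", "soil_water", "water_capacity",
            "tsoil")))

    def total_carbon(self) -> np.ndarray:
        return self.pools.sum(axis=0)

    @property
    def leaf_n_conc(self) -> np.ndarray:
        """Leaf nitrogen concentration, g N per g C."""
        leaf_c = self.pools[_LEAF]
        return np.where(leaf_c > 1e-6, self.leaf_n / np.maximum(leaf_c, 1e-6),
                        0.0)


def water_capacity_mm(static: PixelStatic, params: PoolParams) -> np.ndarray:
    """Plant-available water capacity from soil texture: rooting depth times
    a texture-weighted available-water fraction (field capacity minus
    wilting point)."""
    awc = (params.awc_sand * static.sand + params.awc_silt * static.silt
           + params.awc_clay * static.clay)
    return params.root_depth_mm * awc


def init_state(static: PixelStatic, params: ParamSet,
               water_fill: float = 0.5) -> EcosystemState:
    """Fresh state with empty pools, reference leaf N, half-full bucket."""
    n = static.n_pix
    cap = water_capacity_mm(static, params.pools)
    return EcosystemState(
        pools=np.zeros((N_POOLS, n)),
        mineral_n=np.full(n, 1.0),
        leaf_n=np.zeros(n),
        soil_water=water_fill * cap,
        water_capacity=cap,
        tsoil=np.full(n, 15.0),
    )


def autotrophic_respiration(pools, tair, gpp, params: PoolParams):
    """Maintenance respiration ``sum_i r_i B_i Q10^((T - Tref)/10)`` over the
    biomass pools plus growth respiration as a fixed fraction of GPP
    (optionally of GPP minus maintenance)."""
    q10f = params.q10 ** ((np.asarray(tair, dtype=float) - params.t_ref) / 10.0)
    ar_m = (params.maintenance_daily[:, None] * pools[:N_BIOMASS]).sum(axis=0) * q10f
    if params.growth_respiration_basis == "gpp":
        ar_g = params.growth_respiration_fraction * gpp
    else:
        ar_g = params.growth_respiration_fraction * np.maximum(gpp - ar_m, 0.0)
    return ar_m, ar_g


def allocate_npp(npp, pools_biomass, params: PoolParams):
    """Biomass increments from NPP: positive NPP splits by the allocation
    coefficients; negative NPP draws pools down proportionally to their
    sizes, floored at zero. Increments sum to NPP exactly whenever the
    biomass can supply the deficit (callers clamp respiration so it can)."""
    npp = np.asarray(npp, dtype=float)
    pos = np.maximum(npp, 0.0)
    inc = params.allocation[:, None] * pos[None, :]
    deficit = np.maximum(-npp, 0.0)
    total = pools_biomass.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, pools_biomass / np.maximum(total, 1e-300), 0.0)
    draw = frac * np.minimum(deficit, total)[None, :]
    return inc - draw


def env_scalars(tsoil, moisture_scalar, params: PoolParams):
    """Decomposition modifier f_T * f_W: Q10 response normalized to 1 at the
    reference temperature, times the (already 0..1) moisture scalar."""
    f_t = params.q10 ** ((np.asarray(tsoil, dtype=float) - params.t_ref) / 10.0)
    return f_t * np.clip(moisture_scalar, 0.0, 1.0)


def texture_turnover_factor(static: PixelStatic, params: PoolParams):
    """Clay-dependent multiplier on the stabilized (slow/passive) pool
    turnover: finer soils protect carbon."""
    return 1.0 - params.texture_turnover_clay_slope * static.clay


def _effective_daily_rates(modifier, texture_factor, params: PoolParams,
                           include_biomass: bool):
    """k * modifier per pool (13, n_pix); biomass rows either the plain base
    turnover (for steady-state solves) or zero (for decompose_step)."""
    modifier = np.atleast_1d(np.asarray(modifier, dtype=float))
    k = np.tile(params.turnover_daily[:, None], (1, modifier.size)).astype(float)
    k[N_BIOMASS:] *= modifier[None, :]
    k[_SLOW] *= texture_factor
    k[_PASSIVE] *= texture_factor
    if not include_biomass:
        k[:N_BIOMASS] = 0.0
    return k


def decompose_step(pools, modifier, params: PoolParams, texture_factor=1.0,
                   dt: float = 1.0, return_flux: bool = False):
    """One decomposition step over the soil pools.

    Flux from each donor is ``k * modifier * pool * dt``, split into respired
    CO2 (summed into HR) and receiver-pool transfers per the transfer
    matrix. Sub-steps automatically if any ``k * modifier * dt`` exceeds 1.
    Returns ``(hr, new_pools)`` (plus the per-donor flux if ``return_flux``);
    mass balance (pool change + HR = 0) holds to rounding.
    """
    k = _effective_daily_rates(modifier, texture_factor, params,
                               include_biomass=False)
    kmax = float(k.max(initial=0.0)) * dt
    n_sub = max(1, int(np.ceil(kmax / 0.5)))
    sub_dt = dt / n_sub
    pools = np.array(pools, dtype=float)
    hr = np.zeros(pools.shape[1])
    flux_total = np.zeros_like(pools) if return_flux else None
    for _ in range(n_sub):
        flux = k * pools * sub_dt
        hr += params.respired @ flux
        pools += params.transfer.T @ flux - flux
        if return_flux:
            flux_total += flux
    if return_flux:
        return hr, pools, flux_total
    return hr, pools


def litterfall_and_disturbance(pools, lai_today, lai_yesterday,
                               params: PoolParams, clim_drop=0.0,
                               dt: float = 1.0):
    """Biomass-to-litter transfers for one day.

    Baseline litterfall moves ``k_i * B_i`` from each biomass pool to its
    litter receivers. Additionally, if the relative LAI drop since yesterday
    exceeds the expected seasonal (climatological) drop by more than the
    configured threshold, the excess fraction f of *each* biomass pool is
    transferred to its litter receivers as disturbance (f clamped to 1).
    Total carbon is conserved exactly.

    Returns ``(new_pools, leaf_litter_fraction, biomass_flux)``: the leaf
    fraction depletes leaf N in the daily step; ``biomass_flux`` is the
    (4, n_pix) carbon moved out of each biomass pool.
    """
    pools = np.array(pools, dtype=float)
    lai_t = np.asarray(lai_today, dtype=float)
    lai_y = np.asarray(lai_yesterday, dtype=float)
    if np.any(lai_t < 0) or np.any(lai_y < 0):
        raise ValueError("LAI must be non-negative")
    drop = np.where(lai_y > 1e-6, (lai_y - lai_t) / np.maximum(lai_y, 1e-6), 0.0)
    extra = np.clip(drop - np.asarray(clim_drop, dtype=float), 0.0, 1.0)
    extra = np.where(extra > params.disturbance_drop_threshold, extra, 0.0)

    base_frac = np.minimum(params.turnover_daily[:N_BIOMASS, None] * dt, 1.0)
    frac = np.clip(base_frac + extra[None, :], 0.0, 1.0)
    flux = frac * pools[:N_BIOMASS]
    transfer_b = params.transfer[:N_BIOMASS]  # (4, 13) receiver fractions
    pools[:N_BIOMASS] -= flux
    pools += transfer_b.T @ flux
    leaf_frac = frac[_LEAF]
    return pools, leaf_frac, flux


def soil_water_step(water, capacity, precip, et_demand):
    """Single-bucket water balance: ET limited by availability, overflow
    runs off, scalar = water / capacity.

    Returns ``(water_new, scalar, et, runoff)``; the budget
    ``precip - et - runoff = water_new - water`` closes exactly.
    """
    water = np.asarray(water, dtype=float)
    capacity = np.asarray(capacity, dtype=float)
    avail = water + np.maximum(precip, 0.0)
    et = np.minimum(np.maximum(et_demand, 0.0), avail)
    w2 = avail - et
    runoff = np.maximum(w2 - capacity, 0.0)
    w_new = w2 - runoff
    scalar = np.where(capacity > 0, w_new / np.maximum(capacity, 1e-12), 0.0)
    return w_new, np.clip(scalar, 0.0, 1.0), et, runoff


def et_demand_mm(tmean, srad, lai, params: PoolParams):
    """Evapotranspiration demand: Hargreaves-type potential ET scaled by
    canopy cover (saturating in LAI)."""
    pet = np.maximum(0.0135 * (np.asarray(tmean, dtype=float) + 17.8)
                     * 0.408 * np.asarray(srad, dtype=float), 0.0)
    cover = 0.2 + 0.8 * np.minimum(np.asarray(lai, dtype=float)
                                   / params.et_lai_half, 1.0)
    return pet * cover


def n_leaf_allocation_fraction(params: PoolParams) -> float:
    """Fraction of absorbed N entering the leaf pool: C allocation weighted
    by pool C:N ratios."""
    w = params.allocation / params.cn_ratio
    return float(w[_LEAF] / w.sum())


def n_cycle_step(mineral_n, leaf_n, ndep_daily, mineralized_n, npp, tair,
                 leaf_litter_frac, params: PoolParams):
    """Daily mineral-nitrogen balance and leaf-N update.

    Available N = mineral pool + deposition + mineralization. Vegetation
    uptake is demand-driven (positive NPP / effective plant C:N), scaled by
    a temperature factor and a saturating availability term, and never
    exceeds what is available. Absorbed N follows the C allocation into the
    leaf pool; leaf litterfall removes leaf N proportionally to leaf C.

    Returns ``(mineral_n_new, leaf_n_new, uptake)``; the balance
    ``inputs - uptake = delta mineral`` is exact.
    """
    avail = (np.asarray(mineral_n, dtype=float)
             + np.maximum(ndep_daily, 0.0) + np.maximum(mineralized_n, 0.0))
    demand = np.maximum(npp, 0.0) / params.plant_cn_demand
    f_t = np.clip(np.asarray(tair, dtype=float) / 25.0, 0.0, 1.0)
    uptake = np.minimum(
        demand * f_t * avail / (avail + params.uptake_half_saturation), avail
    )
    mineral_new = avail - uptake
    leaf_gain = uptake * n_leaf_allocation_fraction(params)
    leaf_new = (np.asarray(leaf_n, dtype=float)
                * (1.0 - np.asarray(leaf_litter_frac, dtype=float)) + leaf_gain)
    return mineral_new, np.maximum(leaf_new, 0.0), uptake


def vcmax_adjust(leaf_n_conc, params: PoolParams):
    """Vcmax25 multiplier, linear in leaf N concentration around the
    reference (multiplier 1), clamped to [0.5, 1.5]."""
    conc = np.asarray(leaf_n_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("leaf N concentration must be non-negative")
    rel = (conc - params.reference_leaf_n) / params.reference_leaf_n
    return np.clip(1.0 + params.vcmax_n_slope * rel, 0.5, 1.5)


def pft_vcmax_scale(static: PixelStatic, params: ParamSet) -> np.ndarray:
    """Per-pixel Vcmax scaling relative to the default leaf parameter set,
    so one stacked canopy solve covers all land-cover classes."""
    base = params.leaf_default.vcmax25
    scale = np.ones(static.n_pix)
    for pft, leaf in params.leaf_by_pft.items():
        scale[static.pft == pft] = leaf.vcmax25 / base
    return scale


def step_day(state: EcosystemState, day: dict, static: PixelStatic,
             params: ParamSet, pft_scale: np.ndarray | None = None,
             budget: dict | None = None):
    """Advance all pixels by one day.

    ``day`` must carry: tmax, tmin, srad, rh, precip (per-pixel arrays),
    lai_today, lai_yesterday, clim_drop (expected relative seasonal LAI
    drop), co2 (scalar p.p.m.), ndep_daily (g N m-2 d-1), doy.

    Mutates ``state`` in place and returns the day's :class:`FluxRecord`.
    NEP = GPP - AR - HR holds exactly; the change of total stored carbon
    equals NPP - HR to rounding error. Maintenance respiration is capped so
    a negative-NPP drawdown can always be met by the biomass pools.

    ``budget``, if given, must hold ``"in"`` and ``"out"`` arrays of shape
    (13, n_pix); the day's per-pool carbon inputs and outputs are added to
    them (used by the spin-up's equilibrium correction).
    """
    p = params.pools
    tmean = 0.5 * (day["tmax"] + day["tmin"])
    lai = day["lai_today"]

    state.tsoil += (tmean - state.tsoil) / p.soil_t_memory_days
    moisture = np.clip(
        np.where(state.water_capacity > 0,
                 state.soil_water / np.maximum(state.water_capacity, 1e-12), 0.0),
        0.0, 1.0)

    if pft_scale is None:
        pft_scale = pft_vcmax_scale(static, params)
    n_mult = vcmax_adjust(np.where(state.pools[_LEAF] > 1e-3,
                                   state.leaf_n_conc, p.reference_leaf_n), p)
    flux_c, _ = canopy.canopy_gpp_day(
        lai, static.omega, static.latitude, day["doy"], tmean, day["srad"],
        day["rh"], day["co2"], moisture, params.leaf_default,
        vcmax_n_multiplier=n_mult * pft_scale)
    gpp = flux_c.gpp_canopy

    ar_m, ar_g = autotrophic_respiration(state.pools, tmean, gpp, p)
    # cap maintenance so the biomass pools can fund a negative-NPP day
    headroom = gpp - ar_g + state.pools[:N_BIOMASS].sum(axis=0)
    ar_m = np.minimum(ar_m, np.maximum(headroom, 0.0))
    npp = gpp - ar_m - ar_g

    alloc_inc = allocate_npp(npp, state.pools[:N_BIOMASS], p)
    state.pools[:N_BIOMASS] += alloc_inc

    state.pools, leaf_frac, flux_b = litterfall_and_disturbance(
        state.pools, lai, day["lai_yesterday"], p,
        clim_drop=day.get("clim_drop", 0.0))

    modifier = env_scalars(state.tsoil, moisture, p)
    tex = texture_turnover_factor(static, p)
    hr, state.pools, flux_s = decompose_step(state.pools, modifier, p,
                                             texture_factor=tex,
                                             return_flux=True)
    if budget is not None:
        budget["in"][:N_BIOMASS] += np.maximum(alloc_inc, 0.0)
        budget["out"][:N_BIOMASS] += np.maximum(-alloc_inc, 0.0) + flux_b
        budget["in"] += p.transfer[:N_BIOMASS].T @ flux_b
        budget["in"] += p.transfer.T @ flux_s
        budget["out"] += flux_s

    mineralized = p.net_mineralization_fraction * hr / p.cn_soil
    state.mineral_n, state.leaf_n, _ = n_cycle_step(
        state.mineral_n, state.leaf_n, day["ndep_daily"], mineralized, npp,
        tmean, leaf_frac, p)

    demand = et_demand_mm(tmean, day["srad"], lai, p)
    state.soil_water, _, _, _ = soil_water_step(
        state.soil_water, state.water_capacity, day["precip"], demand)

    nep = gpp - (ar_m + ar_g) - hr
    return FluxRecord(gpp=gpp, npp=npp, ar_maintenance=ar_m, ar_growth=ar_g,
                      hr=hr, nep=nep)
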