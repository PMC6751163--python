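"""Factorial attribution of the accumulated land carbon sink.

The experiment design follows the single-factor pattern: a baseline run
(all drivers frozen/resampled at pre-period conditions, so its accumulated
NEP is the pure legacy effect of pre-period driver changes), one run per
driver with only that driver transient, and an all-transient run. The
enhancement attributed to driver d is

    dS_d = accNEP(single-factor d) - accNEP(baseline)

and its contribution percentage uses the all-factors accumulated sink as
denominator. Single-factor effects need not sum to the total; the gap is
reported as the interaction residual, never redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ecosink.forcing import DRIVERS, ForcingSet, ScenarioSpec, make_baseline
from ecosink.params import ParamSet
from ecosink.pools import EcosystemState
from ecosink.simulate import daily_lai_climatology, run_period, seasonal_drop
from ecosink.units import grams_to_petagrams

SCENARIOS = ("baseline",) + DRIVERS + ("all",)
#: fixed tie-break priority for the dominant-driver map
TIE_ORDER = ("co2", "lai", "climate", "ndep")


def scenario_modes(name: str) -> dict[str, str]:
    """Driver modes for a named scenario: 'baseline', one driver name
    (that driver transient, the rest baseline), or 'all' (all transient)."""
    if name == "baseline":
        return {d: "baseline" for d in DRIVERS}
    if name == "all":
        return {d: "transient" for d in DRIVERS}
    if name not in DRIVERS:
        raise ValueError(f"unknown scenario {name!r}")
    return {d: ("transient" if d == name else "baseline") for d in DRIVERS}


def run_scenario(
    initial_state: EcosystemState,
    forcing: ForcingSet,
    scenario: ScenarioSpec,
    params: ParamSet,
) -> dict[str, np.ndarray]:
    """Run one scenario: apply the baseline rules per the scenario's driver
    modes, then integrate the period from a copy of the initial state.

    Returns annual per-pixel flux sums (g C m-2 yr-1) keyed by
    gpp/npp/ar/hr/nep, each (n_years, n_pix). Deterministic given the
    scenario seed.
    """
    period = scenario.period or (int(forcing.years[0]), int(forcing.years[-1]))
    forced = make_baseline(forcing, scenario)
    clim = daily_lai_climatology(forced, scenario.baseline_lai_window)
    state = initial_state.copy()
    return run_period(state, forced, period, params,
                      clim_drop=seasonal_drop(clim))


def accumulated_nep_pg(annual_nep: np.ndarray, areas: np.ndarray) -> float:
    """Area-weighted accumulated NEP in Pg C from annual per-pixel sums."""
    return float(grams_to_petagrams((annual_nep * areas[None, :]).sum()))


def legacy_effect(baseline_annual_nep: np.ndarray, areas: np.ndarray) -> float:
    """Legacy effect: area-weighted global accumulated NEP of the baseline
    scenario (all drivers at pre-period conditions), Pg C."""
    return accumulated_nep_pg(baseline_annual_nep, areas)


@dataclass
class AttributionResult:
    """Decomposition of the accumulated sink.

    ``accumulated`` maps scenario name to accumulated NEP (Pg C);
    ``effects`` maps driver to its enhancement dS_d (Pg C); percentages use
    the all-factors accumulated sink as denominator. ``interaction`` is
    accNEP(all) - accNEP(baseline) - sum dS_d. ``effect_grids`` carries the
    per-pixel accumulated dS_d (g C m-2) behind the dominant-driver map.
    """

    accumulated: dict[str, float]
    legacy: float
    effects: dict[str, float]
    percentages: dict[str, float]
    interaction: float
    effect_grids: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    annual_global_nep: pd.DataFrame | None = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """Tabular summary: one row per driver plus legacy/interaction."""
        rows = [{"term": "legacy", "sink_pg_c": self.legacy,
                 "percent_of_total": (100.0 * self.legacy
                                      / self.accumulated["all"]
                                      if self.accumulated["all"] else np.nan)}]
        for d in DRIVERS:
            rows.append({"term": d, "sink_pg_c": self.effects[d],
                         "percent_of_total": self.percentages[d]})
        rows.append({"term": "interaction", "sink_pg_c": self.interaction,
                     "percent_of_total": np.nan})
        rows.append({"term": "total (all factors)",
                     "sink_pg_c": self.accumulated["all"],
                     "percent_of_total": 100.0})
        return pd.DataFrame(rows)


def single_factor_effects(
    acc_grids: Mapping[str, np.ndarray],
    areas: np.ndarray,
    denominator: str = "all",
) -> AttributionResult:
    """Decompose accumulated NEP grids into per-driver enhancements.

    ``acc_grids`` maps each scenario in ``baseline, lai, co2, ndep, climate,
    all`` to the per-pixel accumulated NEP over the period (g C m-2). The
    driver effect is the single-factor minus baseline accumulated sink; the
    interaction residual is whatever the single factors do not explain.
    ``denominator`` selects the percentage base: ``"all"`` (the all-factors
    accumulated sink, default) or ``"enhancement"`` (all minus baseline).
    """
    missing = set(SCENARIOS) - set(acc_grids)
    if missing:
        raise ValueError(f"missing scenarios: {sorted(missing)}")
    areas = np.asarray(areas, dtype=float)
    acc = {name: float(grams_to_petagrams((np.asarray(g, dtype=float) * areas).sum()))
           for name, g in acc_grids.items()}
    effects = {d: acc[d] - acc["baseline"] for d in DRIVERS}
    if denominator == "all":
        denom = acc["all"]
    elif denominator == "enhancement":
        denom = acc["all"] - acc["baseline"]
    else:
        raise ValueError("denominator must be 'all' or 'enhancement'")
    percentages = {d: (100.0 * effects[d] / denom if denom else np.nan)
                   for d in DRIVERS}
    interaction = acc["all"] - acc["baseline"] - sum(effects.values())
    grids = {d: np.asarray(acc_grids[d], dtype=float)
             - np.asarray(acc_grids["baseline"], dtype=float) for d in DRIVERS}
    return AttributionResult(
        accumulated=acc, legacy=acc["baseline"], effects=effects,
        percentages=percentages, interaction=interaction, effect_grids=grids)


def n_use_efficiency(n_effect_pg_c: float, cumulative_n_pg: float) -> float:
    """Carbon sink enhancement per unit deposited nitrogen, g C / g N."""
    if cumulative_n_pg <= 0:
        raise ValueError("cumulative N input must be positive")
    return n_effect_pg_c / cumulative_n_pg


def dominant_driver_map(effect_grids: Mapping[str, np.ndarray],
                        areas: np.ndarray,
                        veg_mask: np.ndarray | None = None):
    """Per-pixel dominant driver (largest |dS_d|) with its sign, plus
    cos-latitude-area-weighted category fractions.

    Returns ``(labels, fractions)``: ``labels`` an int array indexing
    ``TIE_ORDER`` with sign carried separately in ``fractions`` keys of the
    form ``(driver, '+'|'-')``; fractions sum to 1 over vegetated pixels.
    Exact ties resolve by the fixed priority co2 > lai > climate > ndep.
    """
    drivers = [d for d in TIE_ORDER if d in effect_grids]
    if set(drivers) != set(effect_grids):
        raise ValueError("effect grids must align with known drivers")
    stack = np.stack([np.asarray(effect_grids[d], dtype=float)
                      for d in drivers])  # priority order
    if np.any(~np.isfinite(stack)):
        raise ValueError("effect grids contain non-finite values")
    winner = np.argmax(np.abs(stack), axis=0)  # argmax -> first max: tie order
    sign = np.take_along_axis(stack, winner[None], axis=0)[0] >= 0
    areas = np.asarray(areas, dtype=float)
    mask = np.ones(stack.shape[1], dtype=bool) if veg_mask is None \
        else np.asarray(veg_mask, dtype=bool)
    total = (areas * mask).sum()
    fractions = {}
    for i, d in enumerate(drivers):
        for s, flag in (("+", True), ("-", False)):
            sel = mask & (winner == i) & (sign == flag)
            fractions[(d, s)] = float((areas * sel).sum() / total)
    return winner, fractions


def regional_totals(acc_grids: Mapping[str, np.ndarray],
                    region_mask: np.ndarray, areas: np.ndarray,
                    veg_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Accumulated Pg C per region per scenario/driver grid.

    ``region_mask`` assigns an integer region id to every pixel; a vegetated
    pixel without a region (id < 0) is an error. Region rows sum exactly to
    the global total (same pixels, same weights).
    """
    region_mask = np.asarray(region_mask)
    mask = np.ones(region_mask.size, dtype=bool) if veg_mask is None \
        else np.asarray(veg_mask, dtype=bool)
    if np.any(mask & (region_mask < 0)):
        raise ValueError("vegetated pixel without region assignment")
    areas = np.asarray(areas, dtype=float)
    regions = np.unique(region_mask[mask])
    rows = []
    for r in regions:
        sel = mask & (region_mask == r)
        row = {"region": int(r)}
        for name, g in acc_grids.items():
            row[name] = float(grams_to_petagrams(
                (np.asarray(g, dtype=float) * areas * sel).sum()))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("region")
    df.loc["global"] = df.sum(axis=0)
    return df


@dataclass
class ExperimentDesign:
    """The full factorial experiment: baseline, four single-factor runs, and
    the all-transient run, sharing one initial state, period, and climate
    resampling seed (so climate noise cancels in differences).
    """

    forcing: ForcingSet
    initial_state: EcosystemState
    params: ParamSet
    period: tuple[int, int]
    baseline_lai_window: tuple[int, int] = (1982, 1986)
    climate_resample_window: tuple[int, int] = (1971, 1979)
    seed: int = 0
    denominator: str = "all"

    def spec_for(self, name: str) -> ScenarioSpec:
        return ScenarioSpec(
            modes=scenario_modes(name),
            baseline_lai_window=self.baseline_lai_window,
            climate_resample_window=self.climate_resample_window,
            period=self.period, seed=self.seed)

    def run(self, collect_fluxes: bool = False):
        """Run all six scenarios and decompose. Returns an
        :class:`AttributionResult` (and the raw per-scenario annual flux
        dicts if ``collect_fluxes``)."""
        areas = self.forcing.grid.pixel_area
        acc_grids, annual_global, fluxes = {}, {}, {}
        for name in SCENARIOS:
            out = run_scenario(self.initial_state, self.forcing,
                               self.spec_for(name), self.params)
            acc_grids[name] = out["nep"].sum(axis=0)
            annual_global[name] = grams_to_petagrams(
                (out["nep"] * areas[None, :]).sum(axis=1))
            if collect_fluxes:
                fluxes[name] = out
        result = single_factor_effects(acc_grids, areas,
                                       denominator=self.denominator)
        y0, y1 = self.period
        result.annual_global_nep = pd.DataFrame(
            annual_global, index=np.arange(y0, y1 + 1))
        if collect_fluxes:
            return result, fluxes
        return result
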