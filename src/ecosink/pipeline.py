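"""End-to-end pipeline: synthetic forcing -> spin-up -> historical
transient -> factorial attribution -> trend statistics.

Thin orchestration over the library modules, shared by the command-line
interface and by scripts; a pure function of (config, seeds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ecosink import spinup as spinup_mod
from ecosink.attribution import AttributionResult, ExperimentDesign
from ecosink.config import RunConfig
from ecosink.forcing import ForcingSet, gen_forcing
from ecosink.grid import gen_grid
from ecosink.params import ParamSet, load_default_params, load_params
from ecosink.pools import EcosystemState

logger = logging.getLogger(__name__)


def build_forcing(cfg: RunConfig) -> ForcingSet:
    """Generate the synthetic forcing world described by the config."""
    grid, static = gen_grid(cfg.n_lat, cfg.n_lon, cfg.lat_range, seed=cfg.seed)
    return gen_forcing(
        grid, static, (cfg.start_year, cfg.end_year),
        met_trend=cfg.met_trend, lai_trend=cfg.lai_trend,
        composite_length=cfg.composite_length,
        co2_endpoints=cfg.co2_endpoints,
        ndep_endpoints_tg=cfg.ndep_endpoints_tg,
        co2_anchors=cfg.co2_anchors, ndep_anchors_tg=cfg.ndep_anchors_tg,
        seed=cfg.seed)


def load_cfg_params(cfg: RunConfig) -> ParamSet:
    if cfg.params_path:
        return load_params(cfg.params_path)
    return load_default_params()


@dataclass
class PipelineRun:
    """Everything the downstream stages need from a completed pipeline."""

    forcing: ForcingSet
    params: ParamSet
    initial_state: EcosystemState
    spinup_report: spinup_mod.SpinupReport
    equilibrium_state: EcosystemState | None = None
    attribution: AttributionResult | None = None


def run_spinup_and_transient(cfg: RunConfig, forcing: ForcingSet,
                             params: ParamSet) -> PipelineRun:
    """Equilibrium spin-up at the first forcing year followed by the
    historical transient up to the analysis period."""
    state, report = spinup_mod.spinup_1901(
        forcing, params, start_year=cfg.start_year,
        climate_window=cfg.spinup_climate_window,
        lai_window=cfg.baseline_lai_window, seed=cfg.seed,
        probe_years=cfg.probe_years, settle_years=cfg.settle_years,
        tolerance=cfg.spinup_tolerance)
    equilibrium_state = state.copy()
    if cfg.period_start > cfg.start_year:
        spinup_mod.transient_run(
            state, forcing, (cfg.start_year, cfg.period_start - 1), params,
            lai_window=cfg.baseline_lai_window)
        report.transient_years = (cfg.start_year, cfg.period_start - 1)
    return PipelineRun(forcing=forcing, params=params, initial_state=state,
                       spinup_report=report,
                       equilibrium_state=equilibrium_state)


def run_attribution(cfg: RunConfig, run: PipelineRun) -> AttributionResult:
    """Run the six-scenario factorial experiment from the transient-end
    state and decompose the accumulated sink."""
    design = ExperimentDesign(
        forcing=run.forcing, initial_state=run.initial_state,
        params=run.params, period=(cfg.period_start, cfg.period_end),
        baseline_lai_window=cfg.baseline_lai_window,
        climate_resample_window=cfg.climate_resample_window,
        seed=cfg.scenario_seed, denominator=cfg.denominator)
    result = design.run()
    run.attribution = result
    return result


def run_full(cfg: RunConfig) -> PipelineRun:
    """Forcing generation through attribution in one call."""
    forcing = build_forcing(cfg)
    params = load_cfg_params(cfg)
    run = run_spinup_and_transient(cfg, forcing, params)
    run_attribution(cfg, run)
    return run
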