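"""Run configuration: YAML-backed, schema-validated, explicit seeds.

Unknown keys are rejected by name; defaults are filled for everything
optional. ``write_config(load_config(p)) == load_config(write_config(...))``
round-trips exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Pipeline configuration.

    Paths may be None for stages that generate their inputs in memory.
    All randomness is controlled by the explicit seeds.
    """

    # grid / forcing generation
    n_lat: int = 8
    n_lon: int = 8
    lat_range: tuple[float, float] = (-60.0, 75.0)
    start_year: int = 1901
    end_year: int = 2016
    lai_trend: float = 0.028  # m2/m2 per decade
    composite_length: int = 16
    co2_endpoints: tuple[float, float] = (296.0, 404.20)
    ndep_endpoints_tg: tuple[float, float] = (12.0, 58.9)
    # piecewise-linear driver curves: [year, value] anchor pairs; these pin
    # the observed 1981 levels (endpoints are used only when anchors are None)
    co2_anchors: list = field(default_factory=lambda: [
        [1901, 296.0], [1981, 340.13], [2016, 404.20]])
    ndep_anchors_tg: list = field(default_factory=lambda: [
        [1901, 12.0], [1981, 42.3], [2016, 58.9]])
    met_trend: dict = field(default_factory=lambda: {"tmax": 0.15, "tmin": 0.15})
    # experiment
    period_start: int = 1981
    period_end: int = 2016
    baseline_lai_window: tuple[int, int] = (1982, 1986)
    climate_resample_window: tuple[int, int] = (1971, 1979)
    spinup_climate_window: tuple[int, int] = (1901, 1910)
    settle_years: int = 3
    probe_years: int = 10
    spinup_tolerance: float = 0.005
    denominator: str = "all"
    # seeds
    seed: int = 0
    scenario_seed: int = 0
    # paths
    forcing_path: str | None = None
    state_path: str | None = None
    params_path: str | None = None
    output_dir: str = "."

    _TUPLE_FIELDS = ("lat_range", "co2_endpoints", "ndep_endpoints_tg",
                     "baseline_lai_window", "climate_resample_window",
                     "spinup_climate_window")

    def validate(self) -> "RunConfig":
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if not (self.start_year <= self.period_start <= self.period_end
                <= self.end_year):
            raise ValueError("period must lie within the forcing years")
        if self.denominator not in ("all", "enhancement"):
            raise ValueError("denominator must be 'all' or 'enhancement'")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises on unknown keys (named), missing files, and invalid values;
    omitted keys take their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for name in RunConfig._TUPLE_FIELDS:
        val = getattr(cfg, name)
        if val is not None:
            setattr(cfg, name, tuple(val))
    return cfg.validate()


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a configuration back to YAML (round-trip exact)."""
    raw = asdict(cfg)
    for name in RunConfig._TUPLE_FIELDS:
        if raw[name] is not None:
            raw[name] = list(raw[name])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
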