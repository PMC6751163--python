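"""Parameter containers and the versioned default parameter file.

``LeafParams`` carries the Farquhar/Ball--Berry constants per land-cover
class; ``PoolParams`` carries the 13-pool turnover rates, the donor->receiver
transfer-fraction matrix (with respired shares), allocation coefficients,
C:N ratios, and the respiration/hydrology constants. Both are loaded from a
flat YAML file; :func:`load_default_params` reads the packaged defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

BIOMASS_POOLS = ["leaf", "stem", "coarse_root", "fine_root"]
SOIL_POOLS = [
    "surface_structural",
    "surface_metabolic",
    "soil_structural",
    "soil_metabolic",
    "coarse_woody",
    "surface_microbe",
    "soil_microbe",
    "slow",
    "passive",
]
POOL_NAMES = BIOMASS_POOLS + SOIL_POOLS
N_POOLS = len(POOL_NAMES)
POOL_INDEX = {name: i for i, name in enumerate(POOL_NAMES)}


@dataclass
class LeafParams:
    """Leaf biochemical and stomatal constants (one PFT).

    ``vcmax25``/``jmax25`` in umol m-2 s-1; Michaelis constants at 25 C with
    Arrhenius activation energies in J mol-1; Ball--Berry slope g1
    (dimensionless) and intercept g0 (mol m-2 s-1).
    """

    vcmax25: float = 60.0
    jmax_ratio: float = 1.9
    rd_frac: float = 0.015
    kc25: float = 404.9
    ko25: float = 278.4
    gamma_star25: float = 42.75
    ea_vcmax: float = 65330.0
    ea_jmax: float = 43540.0
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    ea_gamma_star: float = 37830.0
    ea_rd: float = 46390.0
    quantum_yield: float = 0.3
    curvature: float = 0.9
    ball_berry_slope: float = 8.0
    ball_berry_intercept: float = 0.01
    kn_extinction: float = 0.3

    @property
    def jmax25(self) -> float:
        return self.jmax_ratio * self.vcmax25

    def __post_init__(self) -> None:
        for name in (
            "vcmax25",
            "kc25",
            "ko25",
            "gamma_star25",
            "ball_berry_slope",
            "ball_berry_intercept",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"LeafParams.{name} must be positive")
        if self.jmax25 <= 1.2 * self.vcmax25:
            raise ValueError("jmax25 must exceed 1.2 * vcmax25")


@dataclass
class PoolParams:
    """Century-style pool constants, compiled to arrays in pool order.

    ``turnover_daily`` is the base rate k (d-1) per pool; ``transfer``
    is the donor->receiver fraction-of-flux matrix T with ``respired`` the
    CO2 share per donor; each donor's row of T plus its respired share sums
    to 1 (validated at load).
    """

    turnover_daily: np.ndarray  # (13,)
    transfer: np.ndarray  # (13, 13) T[d, r]
    respired: np.ndarray  # (13,)
    allocation: np.ndarray  # (4,) NPP allocation over biomass pools
    cn_ratio: np.ndarray  # (4,) biomass C:N
    cn_soil: float
    maintenance_daily: np.ndarray  # (4,) d-1 at t_ref
    q10: float
    t_ref: float
    growth_respiration_fraction: float
    growth_respiration_basis: str
    texture_turnover_clay_slope: float
    disturbance_drop_threshold: float
    # nitrogen coupling
    reference_leaf_n: float
    leaf_n_floor: float
    leaf_n_cap: float
    vcmax_n_slope: float
    uptake_half_saturation: float
    plant_cn_demand: float
    net_mineralization_fraction: float
    # hydrology
    root_depth_mm: float
    awc_sand: float
    awc_silt: float
    awc_clay: float
    et_lai_half: float
    soil_t_memory_days: float

    def __post_init__(self) -> None:
        rowsum = self.transfer.sum(axis=1) + self.respired
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            bad = [POOL_NAMES[i] for i in np.flatnonzero(~np.isclose(rowsum, 1.0))]
            raise ValueError(f"transfer rows must sum to 1; offending pools: {bad}")
        if not np.isclose(self.allocation.sum(), 1.0):
            raise ValueError("NPP allocation coefficients must sum to 1")
        if not 0.0 <= self.growth_respiration_fraction <= 1.0:
            raise ValueError("growth respiration fraction must lie in [0, 1]")
        if self.growth_respiration_basis not in ("gpp", "gpp_minus_maintenance"):
            raise ValueError("growth_respiration_basis must be 'gpp' or "
                             "'gpp_minus_maintenance'")


@dataclass
class ParamSet:
    """Bundle of leaf parameters per PFT class and shared pool parameters."""

    leaf_default: LeafParams
    leaf_by_pft: dict[int, LeafParams] = field(default_factory=dict)
    pools: PoolParams = None

    def leaf(self, pft: int) -> LeafParams:
        return self.leaf_by_pft.get(int(pft), self.leaf_default)


def _compile_pools(raw: dict, nitrogen: dict, hydrology: dict) -> PoolParams:
    k = np.array([raw["turnover"][name] for name in POOL_NAMES]) / 365.0
    transfer = np.zeros((N_POOLS, N_POOLS))
    respired = np.zeros(N_POOLS)
    for donor, row in raw["transfers"].items():
        d = POOL_INDEX[donor]
        respired[d] = float(row.get("respired", 0.0))
        for receiver, frac in row.get("to", {}).items():
            transfer[d, POOL_INDEX[receiver]] = float(frac)
    alloc = np.array([raw["allocation"][name] for name in BIOMASS_POOLS])
    cn = np.array([raw["cn_ratio"][name] for name in BIOMASS_POOLS])
    maint = np.array([raw["maintenance"][name] for name in BIOMASS_POOLS])
    return PoolParams(
        turnover_daily=k,
        transfer=transfer,
        respired=respired,
        allocation=alloc,
        cn_ratio=cn,
        cn_soil=float(raw["cn_soil"]),
        maintenance_daily=maint,
        q10=float(raw["q10"]),
        t_ref=float(raw["t_ref"]),
        growth_respiration_fraction=float(raw["growth_respiration_fraction"]),
        growth_respiration_basis=str(raw["growth_respiration_basis"]),
        texture_turnover_clay_slope=float(raw["texture_turnover_clay_slope"]),
        disturbance_drop_threshold=float(raw["disturbance_drop_threshold"]),
        reference_leaf_n=float(nitrogen["reference_leaf_n"]),
        leaf_n_floor=float(nitrogen["leaf_n_floor"]),
        leaf_n_cap=float(nitrogen["leaf_n_cap"]),
        vcmax_n_slope=float(nitrogen["vcmax_n_slope"]),
        uptake_half_saturation=float(nitrogen["uptake_half_saturation"]),
        plant_cn_demand=float(nitrogen["plant_cn_demand"]),
        net_mineralization_fraction=float(
            nitrogen["net_mineralization_fraction"]),
        root_depth_mm=float(hydrology["root_depth_mm"]),
        awc_sand=float(hydrology["awc_sand"]),
        awc_silt=float(hydrology["awc_silt"]),
        awc_clay=float(hydrology["awc_clay"]),
        et_lai_half=float(hydrology["et_lai_half"]),
        soil_t_memory_days=float(hydrology["soil_t_memory_days"]),
    )


def load_params(path_or_stream) -> ParamSet:
    """Load a parameter YAML file into a :class:`ParamSet`."""
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    leaf_raw = raw["leaf"]["default"]
    leaf_default = LeafParams(**leaf_raw)
    leaf_by_pft = {}
    for pft, overrides in (raw["leaf"].get("pft_overrides") or {}).items():
        merged = dict(leaf_raw)
        merged.update(overrides or {})
        leaf_by_pft[int(pft)] = LeafParams(**merged)
    pools = _compile_pools(raw["pools"], raw["nitrogen"], raw["hydrology"])
    return ParamSet(leaf_default=leaf_default, leaf_by_pft=leaf_by_pft, pools=pools)


def load_default_params() -> ParamSet:
    """Load the packaged default parameter set."""
    ref = resources.files("ecosink") / "params" / "default.yaml"
    with ref.open() as fh:
        return load_params(fh)
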