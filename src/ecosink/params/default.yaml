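# Default parameter set: C3 leaf biochemistry with Ball-Berry stomatal
# coupling, and Century-style pool turnover/transfer constants.
#
# Leaf constants follow the standard C3 Farquhar formulation (Michaelis
# constants and CO2 compensation point at 25 C with Arrhenius activation
# energies, J mol-1). Pool turnover rates are per year and converted to
# per day at load.

leaf:
  default:
    vcmax25: 60.0          # umol m-2 s-1
    jmax_ratio: 1.9        # jmax25 = ratio * vcmax25
    rd_frac: 0.015         # dark respiration as fraction of vcmax25
    kc25: 404.9            # umol mol-1
    ko25: 278.4            # mmol mol-1
    gamma_star25: 42.75    # umol mol-1
    ea_vcmax: 65330.0
    ea_jmax: 43540.0
    ea_kc: 79430.0
    ea_ko: 36380.0
    ea_gamma_star: 37830.0
    ea_rd: 46390.0
    quantum_yield: 0.3     # mol e- per mol photon
    curvature: 0.9         # J light response curvature
    ball_berry_slope: 8.0
    ball_berry_intercept: 0.01   # mol m-2 s-1
    kn_extinction: 0.3     # canopy nitrogen extinction coefficient
  # per-PFT overrides (class indices from the synthetic land-cover field)
  pft_overrides:
    0: {}                          # broadleaf forest (defaults)
    1: {vcmax25: 45.0}             # needleleaf forest
    2: {vcmax25: 75.0}             # grass/crop (C4 share folded into an
                                   # elevated effective vcmax; flagged limitation)

pools:
  # base turnover, yr-1
  turnover:
    leaf: 1.0
    stem: 0.025
    coarse_root: 0.04
    fine_root: 0.6
    surface_structural: 3.9
    surface_metabolic: 14.8
    soil_structural: 4.9
    soil_metabolic: 18.5
    coarse_woody: 0.3
    surface_microbe: 6.0
    soil_microbe: 7.3
    slow: 0.2
    passive: 0.0045
  # donor -> {respired fraction, receiver fractions}; each row sums to 1.
  # Biomass litterfall respires nothing; soil transfers follow Century-style
  # respired shares.
  transfers:
    leaf:           {respired: 0.0,  to: {surface_structural: 0.55, surface_metabolic: 0.45}}
    stem:           {respired: 0.0,  to: {coarse_woody: 1.0}}
    coarse_root:    {respired: 0.0,  to: {coarse_woody: 1.0}}
    fine_root:      {respired: 0.0,  to: {soil_structural: 0.65, soil_metabolic: 0.35}}
    surface_structural: {respired: 0.45, to: {surface_microbe: 0.35, slow: 0.20}}
    surface_metabolic:  {respired: 0.55, to: {surface_microbe: 0.45}}
    soil_structural:    {respired: 0.45, to: {soil_microbe: 0.35, slow: 0.20}}
    soil_metabolic:     {respired: 0.55, to: {soil_microbe: 0.45}}
    coarse_woody:       {respired: 0.45, to: {surface_microbe: 0.30, slow: 0.25}}
    surface_microbe:    {respired: 0.60, to: {slow: 0.40}}
    soil_microbe:       {respired: 0.55, to: {slow: 0.42, passive: 0.03}}
    slow:               {respired: 0.55, to: {soil_microbe: 0.42, passive: 0.03}}
    passive:            {respired: 0.55, to: {soil_microbe: 0.45}}
  # NPP allocation to biomass pools (sums to 1)
  allocation: {leaf: 0.30, stem: 0.30, coarse_root: 0.15, fine_root: 0.25}
  # C:N ratio per biomass pool
  cn_ratio: {leaf: 25.0, stem: 80.0, coarse_root: 60.0, fine_root: 40.0}
  cn_soil: 12.0          # mean C:N of decomposing organic matter
  # maintenance respiration coefficients, d-1 at the reference temperature
  maintenance: {leaf: 0.0020, stem: 0.00010, coarse_root: 0.00010, fine_root: 0.0020}
  q10: 2.0               # AR and HR temperature response
  t_ref: 20.0            # degC reference for Q10 scaling
  growth_respiration_fraction: 0.25
  growth_respiration_basis: gpp   # 'gpp' (literal) or 'gpp_minus_maintenance'
  texture_turnover_clay_slope: 0.5  # slow/passive k multiplied by (1 - slope*clay)
  disturbance_drop_threshold: 0.05  # relative LAI drop beyond climatology

nitrogen:
  reference_leaf_n: 0.025   # g N per g C, vcmax multiplier = 1 here
  leaf_n_floor: 0.005
  leaf_n_cap: 0.05
  vcmax_n_slope: 1.0        # multiplier = 1 + slope*(conc-ref)/ref, clipped
  uptake_half_saturation: 2.0   # g N m-2
  plant_cn_demand: 40.0     # effective whole-plant C:N for N demand
  net_mineralization_fraction: 0.1  # share of gross mineralization escaping
                                    # microbial immobilization

hydrology:
  root_depth_mm: 1000.0
  # available water capacity fraction = a_sand*sand + a_silt*silt + a_clay*clay
  awc_sand: 0.06
  awc_silt: 0.13
  awc_clay: 0.11
  et_lai_half: 4.0          # demand ramps with min(1, lai/et_lai_half)
  soil_t_memory_days: 7.0   # e-folding of soil temperature toward air mean
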