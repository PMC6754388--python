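# Packaged defaults: the studied mat's measured constants and scenario inputs.
# Grid spacing/time step are coarsened 4x/20x from the 0.071 mm / 1 s
# microprofile resolution so converge-mode runs finish in seconds; the FTCS
# stability number stays below 0.5.

kinetics:
  vmax_prod: 2.1            # nmol/L/s, maximal O2 production
  km_prod: 1000.0           # uE/m2/s, light half-saturation
  vmax_resp: 1.75           # nmol/L/s, maximal respiration
  km_resp: 250.0            # nmol/L, O2 half-saturation
  par_surface: 1500.0       # uE/m2/s at the mat surface
  par_attenuation_fraction: 0.01   # 1% loss per depth step
  attenuation_step_mm: 0.071

transport:
  porosity: 0.97
  diffusivity_cm2s: 1.0e-5  # tortuosity-corrected D'

grid:
  depth_mm: 20.0
  spacing_mm: 0.284

boundary:
  top_um: 230.0             # air-equilibrated O2, tropical fresh water
  bottom: no_flux

run:
  mode: converge
  tolerance: 1.0e-4         # nM/s residual
  dt_s: 20.0
  seed: 0

profile:
  path: null                # use the synthetic forward profile when null
  noise_sd_um: 0.0

wtc:
  surface_wt: 12.0          # wt% C at the surface
  deep_wt: 1.0              # wt% C at depth
  decay_depth_mm: 5.0
  noise_sd: 0.0

balance:
  mat_thickness_cm: 6.0
  age_yr: 9.0
  om_override: 20.0         # measured areal OM accretion, mmol C/m2/d
  ch4_dark: 4.1             # dark-incubation CH4, mmol/m2/d
  inhibition_factor: 0.5    # oxic-day methanogenesis inhibition
  respiration: 15.0         # night respiration magnitude, mmol/m2/d

global:
  gross_rate: 38.0          # gross O2 production, mmol/m2/d
  net_c_rate: 20.0          # net C accretion, mmol C/m2/d
  land_area_km2: 2.5e+7      # late Archean land surface
  coverages: [0.05, 0.55]
  earth_surface_km2: 5.10e+8
  ocean_fraction: 0.95
  c_to_n: 15.0
  nitrate_coverage: 0.10

cells:
  density_min: 1.0e+8        # cells/cm3
  density_max: 1.0e+9
  c_per_cell_min: 1.0       # fg C per cell
  c_per_cell_max: 150.0
  toc_wt_min: 1.0
  toc_wt_max: 12.0

# Literature reference fluxes [Tmol/yr] for coverage break-even comparison;
# supply your own cited values, e.g. {sulphate_modern: 3.3}
references: {}
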