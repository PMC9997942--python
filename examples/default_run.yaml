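# Reference cuvette vitrification run: 7.05M DMSO in a polystyrene cuvette,
# 2D axisymmetric, 20 degC/min from 10 degC to -125 degC.
# All lengths in metres, temperatures in degC, viscosities in Pa.s.

geometry:
  inner_radius: 5.0e-3
  wall_thickness: 1.25e-3
  height: 45.0e-3
  fill_height: 27.5e-3

protocol:
  T_initial: 10.0
  cooling_rate: 20.0      # degC/min
  T_final: -125.0
  hold_duration: 0.0      # s

materials:
  # single-exponential viscosity anchors (config-exposed: measured values
  # for 7.05M DMSO are only sparsely available)
  mu_ref: 1.0e-2          # Pa.s at T_ref
  T_ref: 10.0
  mu_glass: 1.0e12        # Pa.s at T_glass
  T_glass: -132.0         # glass transition of 7.05M DMSO
  mu_cap: 1.0e8           # numerical cap
  density_slope_factor: 1.0   # set 1.15 for the steeper-density HCPA study
  h_free: 10.0            # W/m^2-degC
  h_forced: 350.0
  # property polynomials may be overridden, constant term first:
  # cpa:
  #   density: [1090.0, -0.6922, 0.000257]

numerics:
  dt_max: 20.0            # s
  target_elements: 4000
  max_surface_step: 3.0e-4   # m per step (surface CFL cap)
  arrest_threshold: null  # Pa.s; set to exclude arrested regions from flow

maxwell:
  E: 1.0e9                # Pa (placeholder: not a measured value)
  nu: 0.33
  arrest_viscosity: 1.0e8 # Pa.s, fluid -> solid switch for the TM model
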