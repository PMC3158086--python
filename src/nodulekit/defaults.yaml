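# nodulekit default configuration, version 1.
#
# These constants are data, not code: they were fixed once by the
# `nodulekit calibrate` loop so that the full generator -> pipeline chain
# reproduces its reference operating points, and are not tuned per run.
version: 1

dose_response:
  d50: 14.5             # J/cm^2, periphery half-kill fluence at zero-irradiance limit
  hill: 2.0
  irr_scale: 50.0       # mW/cm^2
  irr_hill: 3.0
  core_efficiency: 0.25 # core d50 multiplier (< 1: core is the more sensitive region)
  hypoxia_factor: 2.0   # multiplies effective d50 under 100% N2
  pattern: core_kill    # core_kill (cationic-dye-like) | periphery_kill (porphyrin-like)

render:
  pixel_size: 2.0           # um / pixel
  field_size: [5000.0, 5000.0]  # um
  nodule_count: 40
  diameter_range: [200.0, 600.0]  # um, day-13-like large-nodule population
  rim_depth: 100.0          # um; oxygenated rim thickness -> core radius fraction
  brightness: 4000.0        # peak channel intensity
  irradiance: 50.0          # mW/cm^2 used when a well does not specify one

noise:
  photon_scale: 0.25
  read_sigma: 5.0
  background_level: 200.0

ph_profile:
  ph_core: 5.5
  ph_edge: 7.2
  exponent: 2.0

snarf:
  pka: 6.4
  acid_peak: 580.0   # nm
  base_peak: 640.0   # nm
  sigma: 30.0        # nm, Gaussian width of each form's emission
  brightness: 3000.0

uptake:
  decay_length: 125.0   # um, peripheral-profile 1/e depth
  trap_strength: 0.5    # decades of accumulation per pH unit below edge pH
  tau: 3600.0           # s, characteristic diffusion time of a reference nodule

apoptosis:
  apoptotic_fraction: 0.97

pipeline:
  min_diameter: 30.0        # um, morphometry size filter
  low_signal_factor: 6.0    # ratio-image masking threshold in background sigmas
  plateau_tolerance: 0.02   # normalized-viability units
  replicates: 3
  doses: [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]        # J/cm^2
  irradiances: [25.0, 50.0, 100.0, 200.0, 300.0]         # mW/cm^2
  series_fluence: 15.0      # J/cm^2 used for the irradiance series
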