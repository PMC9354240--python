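# Default in-silico experiment: the four study designs in one config.
# Fuel levels in % v/v H2O2; GUV diameters in um; "bulk" = unconfined.
seed: 1
acquisition:
  frame_rate: 5.0
  duration: 60.0
  dt_integration: 0.01
  localization_sd: 0.08

conditions:
  # bulk vs confined motility
  - {label: bulk_f0,      fuel: 0.0,   guv_diameter: bulk, n_particles: 40, seed: 101}
  - {label: bulk_f0034,   fuel: 0.034, guv_diameter: bulk, n_particles: 40, seed: 102}
  - {label: conf_f0034,   fuel: 0.034, guv_diameter: 24.0, n_particles: 40, seed: 103}
  - {label: conf_f0034_ahl, fuel: 0.034, guv_diameter: 24.0, n_particles: 40,
     membrane: alpha_hemolysin, seed: 104}
  # confined fuel sweep
  - {label: conf_f0,      fuel: 0.0,   guv_diameter: 24.0, n_particles: 40, seed: 105}
  - {label: conf_f085,    fuel: 0.85,  guv_diameter: 24.0, n_particles: 40, seed: 106}
  - {label: conf_f34,     fuel: 3.4,   guv_diameter: 24.0, n_particles: 40, seed: 107}
  # size groups at 0.85% fuel
  - {label: small_f085,   fuel: 0.85,  guv_diameter: 19.0, n_particles: 15, seed: 108}
  - {label: medium_f085,  fuel: 0.85,  guv_diameter: 29.0, n_particles: 15, seed: 109}
  - {label: large_f085,   fuel: 0.85,  guv_diameter: 42.0, n_particles: 15, seed: 110}
  # crowding at 0.85% fuel (particle counts per GUV)
  - {label: crowd_low,    fuel: 0.85,  guv_diameter: 30.0, n_particles: 4,
     crowding_beta: 1500.0, seed: 111}
  - {label: crowd_medium, fuel: 0.85,  guv_diameter: 30.0, n_particles: 12,
     crowding_beta: 1500.0, seed: 112}
  - {label: crowd_high,   fuel: 0.85,  guv_diameter: 30.0, n_particles: 30,
     crowding_beta: 1500.0, seed: 113}

comparisons:
  - [bulk_f0, conf_f0]
  - [conf_f0, conf_f085]
  - [conf_f085, conf_f34]
  - [small_f085, large_f085]
  - [crowd_low, crowd_high]
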