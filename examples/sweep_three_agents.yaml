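# Placement sweep comparing the three reference nanoagents: 25 nm-core and
# 1 nm-core coated gold nanoparticles and auranofin (a 1 nm gold-bearing
# nano-object).  Kernels are synthetic; smaller agents get shorter-ranged,
# higher-amplitude kernels, mimicking the qualitative trend of simulated
# radial dose distributions.  Cluster-level ionisation rates ~10, ~1 and
# ~0.1 events/Gy respectively.
schema_version: 1
agents:
  - agent_id: aunp-25nm
    core_radius_nm: 25.0
    coating_thickness_nm: 1.0
    core_density_g_cm3: 19.32
    core_gold_mass_fraction: 1.0
    cluster_rate_per_gray: 10.0
    synthetic_kernel:
      amplitude_gy_nm2: 0.05
      attenuation_length_nm: 600.0
      support_radius_nm: 5000.0
  - agent_id: aunp-1nm
    core_radius_nm: 1.0
    coating_thickness_nm: 1.0
    core_density_g_cm3: 19.32
    core_gold_mass_fraction: 1.0
    cluster_rate_per_gray: 1.0
    synthetic_kernel:
      amplitude_gy_nm2: 0.5
      attenuation_length_nm: 500.0
      support_radius_nm: 4000.0
  - agent_id: auranofin
    core_radius_nm: 1.0
    coating_thickness_nm: 0.0
    core_density_g_cm3: 1.7
    core_gold_mass_fraction: 0.29
    cluster_rate_per_gray: 0.1
    synthetic_kernel:
      amplitude_gy_nm2: 0.5
      attenuation_length_nm: 300.0
      support_radius_nm: 2500.0
cluster:
  radius_nm: 500.0
  fill_factor: 0.1
dose_gy: 1.0
transport:
  stopping_power_ratio: 1.2
ensemble_size: 20
n_surface_points: 1000
cell:
  nucleus_radius_nm: 7000.0
  cell_radius_nm: 15000.0
  distances_nm: [7500.0, 11000.0, 14500.0, 26000.0]
  targets: [nucleus, cytoplasm]
normalize: true
seed: 1
output_dir: out_sweep
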