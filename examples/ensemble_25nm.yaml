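# Ensemble study: 500 nm radius cluster of 25 nm-core gold nanoparticles
# (1 nm citrate coating) at 10% volumetric fill, irradiated to 1 Gy.
# The kernel is synthetic (no simulated kernel tables ship with the package):
# a r^-2 exp(-r/lambda) fall-off with Auger-like bump structure.
schema_version: 1
agent:
  agent_id: aunp-25nm
  core_radius_nm: 25.0
  coating_thickness_nm: 1.0
  core_density_g_cm3: 19.32
  core_gold_mass_fraction: 1.0
  cluster_rate_per_gray: 10.0        # ~10 ionisation events per Gy per cluster
  synthetic_kernel:
    amplitude_gy_nm2: 0.05
    attenuation_length_nm: 600.0
    support_radius_nm: 5000.0
    bump_centers_nm: [60.0, 250.0]
    bump_widths_nm: [20.0, 80.0]
    bump_heights: [0.5, 0.3]
cluster:
  radius_nm: 500.0
  fill_factor: 0.1
dose_gy: 1.0
transport:
  stopping_power_ratio: 1.2          # gold/water mixture; no physical default
ensemble_size: 100
n_surface_points: 1000
cell:
  nucleus_radius_nm: 7000.0
  cell_radius_nm: 15000.0
  distances_nm: [7500.0, 11000.0, 14500.0, 26000.0]
  targets: [nucleus, cytoplasm]
lq:
  alpha_per_gy: 0.2
  beta_per_gy2: 0.05
  sensitive_volume_nm3: 1.437e12     # 7 um-radius nucleus volume
seed: 1
output_dir: out
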