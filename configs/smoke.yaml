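# Bundled end-to-end demonstration world: 30 x 40 grid, 150 societies,
# 10 traits, full neighbour design (k = 100, long range >= 2500 km).
out_dir: scratch/smoke_run
seed: 7
world:
  grid_n_lat: 30
  grid_n_lon: 40
  lat_range: [-60.0, 60.0]
  lon_range: [0.0, 80.0]
  years: 100
  n_societies: 150
  beta_env: -2.0
  beta_dist: -0.5
  mu_vertical: 0.4
  alpha_horizontal: 0.5
n_traits: 10
n_areas: 5
k_neighbors: 100
long_range_min_km: 2500.0
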