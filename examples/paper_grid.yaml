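# Full-scale experiment grid (many CPU-hours at these settings).
model:
  subunit_radius_angstrom: 13.0
grid:
  R_c: [2.1, 1.4, 1.0, 0.7, 0.46]
  phi: [0.0, 0.1, 0.2, 0.3, 0.4]
  c_urea: [1.0, 2.0, 2.5, 3.0, 4.0]
simulation:
  box_edge_angstrom: 210.0
  reduced_box: false
  duration_tu: 1000000.0
  relax_tu: 1000.0
  sample_interval: 1.0
  q: 0.2
  t_m: 10.0
  n_seeds: 4
seed: 1
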