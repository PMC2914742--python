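# Desk-scale smoke grid (finishes in minutes).
grid:
  R_c: [1.0]
  phi: [0.0, 0.2]
  c_urea: [2.0, 2.5, 3.0]
simulation:
  box_edge_angstrom: 165.0
  reduced_box: true
  duration_tu: 20000.0
  relax_tu: 100.0
  n_seeds: 2
seed: 1
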