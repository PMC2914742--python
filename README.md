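# crowdfold

Hard-sphere crowding effects on a minimal two-subunit protein-folding model,
computed two independent ways and compared quantitatively:

* **Analytic statistical thermodynamics** — the model's equilibrium follows
  from a one-dimensional histogram pair potential between two 13 Å hard
  spherical subunits (native well tuned linearly by urea concentration);
  crowding enters as a scaled-particle-theory (SPT) depletion potential of
  mean force `U_crowd(r) = W2(r) − 2 W1`, with the fused two-sphere cavity
  mapped onto a co-volume-equivalent spherocylinder.
* **Event-driven discontinuous molecular dynamics (DMD)** — the same model
  simulated with explicit hard-sphere crowders in a periodic box, with an
  Andersen (ghost-particle) thermostat. A pure-Python reference engine is
  accompanied by a numba-accelerated drop-in core (verified trajectory
  equivalence) used for production runs.

Outputs are urea denaturation curves `f_native(c_urea)`, the
half-denaturation concentration `c50`, and depletion PMFs, for crowder
size ratios `R_c = r_c / 13 Å` and volume fractions `φ` up to 0.4.
Reduced units throughout: `kT = 1`, `m = 1`, lengths in Å,
`t_u = Å·sqrt(m/kT)`.

## Layout

| module                | contents |
|-----------------------|----------|
| `crowdfold.model`     | histogram potential, urea dependence, model geometry |
| `crowdfold.thermo`    | equilibrium P(r), bin fractions, `f_native`, `c50` solvers |
| `crowdfold.spt`       | SPT insertion works, excluded volumes, crowding PMF |
| `crowdfold.dmd`       | event-driven MD engine (reference + numba fast path) |
| `crowdfold.simulate`  | system assembly, relaxation, estimators, experiment grid |
| `crowdfold.io` / `.cli` | config, TSV/XYZ/manifest output, report plots, CLI |

## CLI

Experiment grids are YAML/JSON configs (see `examples/paper_grid.yaml`):

```sh
crowdfold theory   -c examples/paper_grid.yaml -o out/theory    # analytic only
crowdfold simulate -c examples/quick_grid.yaml -o out/dmd       # DMD + theory
crowdfold analyze  -s out/samples.tsv --c-urea 2.5 -o out/ana   # re-estimate
crowdfold compare  -r out/theory -r out/dmd -o out/report       # merged report
```

Each run writes `curves.tsv`, `c50.tsv`, per-condition PMF TSVs, figures,
and a `manifest.json` recording the config snapshot, seeds and outputs.
Full paper-scale settings (210 Å box, 10⁶ t_u, 25-cell grid) are supported
via the config but take many CPU-hours; the defaults are desk-scale.

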