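# radchemxt

A radial reaction–diffusion engine for the long-time chemistry of water
radiolysis around a charged-particle track. Starting from a late
heterogeneous-stage snapshot (~500 ns) — either discrete species
coordinates or pre-binned radial concentrations — the engine evolves one
cylindrically symmetric concentration histogram per species out to the
homogeneous biochemical stage (≥ 1 ms), using:

- **Crank–Nicolson cylindrical diffusion** per species across radial bins,
  with a smoothness condition at the axis and a zero-flux boundary at
  `r_max` (standing in for the balance with neighbouring tracks), solved
  through tridiagonal (Thomas) elimination;
- **explicit forward-Euler reactions** bin by bin, each bin treated as a
  locally homogeneous reactor, with dissolved O₂ as a fixed continuum
  concentration set via Henry's law;
- **Lie operator splitting** (diffusion, then reactions, per step) on a
  staged time-step schedule (0.5 ns near the hand-over time up to 10 ns
  beyond 1 ms);
- a **flattening switch**: once a distribution's relative standard
  deviation drops below a threshold (default 5%), it collapses to a single
  mass-conserving value; when all species are flat, diffusion is skipped
  and the run degenerates to homogeneous kinetics.

Observables include per-species G-values (molecules per 100 eV), category
sums (primary radicals / intra-track molecules / oxygen products), and
relative-deviation tables between runs.

Because the Monte Carlo track-structure front-end is out of scope, the
package ships a **synthetic track generator** (Poisson counts, Gaussian
radial profile, axial homogeneity, optional core+penumbra mixture and
pre-snapshot O₂-scavenging conversion) and two **independent well-mixed
oracles** (adaptive stiff ODE integration and an exact Gillespie SSA) used
to validate the solver in its homogeneous limit.

## Layout

| module | contents |
|---|---|
| `radchemxt.chemistry` | species/reactions, bundled editable rate & diffusion table (`data/default_network.yaml`), Henry's-law O₂, network validation |
| `radchemxt.radial_field` | radial grid, concentration fields, binning of positions, G-values, category sums, deviations, dose–fluence geometry, CSV dialects |
| `radchemxt.solver` | CN matrices, Thomas solver, diffusion/reaction steps, splitting, schedule, flattening, run driver |
| `radchemxt.synthetic_track` | track snapshot fixtures, uniform "dummy" states, low/high-density presets |
| `radchemxt.oracle` | well-mixed ODE and SSA reference engines, per-track volume from fluence |
| `radchemxt.io_cli` | YAML config loading, run manifests, `radchemxt` CLI |

Internal units are nm / ns / mol L⁻¹; rate constants are accepted in
M⁻¹ s⁻¹ at the I/O boundary.

## CLI

```sh
# synthetic snapshot (positions CSV) for 1000 pooled dilute tracks
radchemxt synth --preset low --seed 1 --n-tracks 1000 --out track.csv

# evolve it under a config; writes snapshots, G-values and a manifest
radchemxt run --config config.yaml --initial track.csv --out results/run1

# well-mixed reference trajectory on the same network
radchemxt oracle --config config.yaml --mode ode --t-end 10000 --out ode.csv

# per-time, per-species relative deviations between two runs
radchemxt compare results/run1 results/run2 --out deviations.csv
```

A minimal `config.yaml`:

```yaml
po2: 0.21                      # fraction of 1 atm, converted via Henry's law
solver: {t_end_ns: 1.0e6, record_times_ns: [1.0e3, 1.0e4, 1.0e5, 1.0e6]}
beam: {let_kev_per_um: 0.2}
track: {preset: low, seed: 1, n_tracks: 1000}
```

All grid/schedule defaults (20 nm bins, 5 µm radius, 10 µm track length,
the staged dt table, 500 ns hand-over) apply when omitted. Every value in
the bundled reaction table can be overridden from the config.

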