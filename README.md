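# steadypm

A reduced-complexity, steady-state air quality model for estimating
annual-average changes in fine particulate matter (PM2.5) concentrations
caused by marginal changes in precursor emissions. It is aimed at exposure
and health-impact analysts who need source-attributable PM2.5 fields —
including intraurban gradients near sources and long-range transport — but
cannot run a full Eulerian chemical transport model (CTM) for every scenario.

Chronic PM2.5 exposure dominates the monetized health damages of air
pollution, so the quantity of interest is the *annual-average change* in
total PM2.5 (primary plus secondary sulfate, nitrate, ammonium and organic
aerosol) per unit change in emissions of VOC, SO<sub>x</sub>,
NO<sub>x</sub>, NH<sub>3</sub> and primary PM2.5.

## Model

The model solves a discretized reaction–advection–diffusion balance for
marginal concentration changes *C<sub>i</sub>* of nine species
(primary PM2.5; VOC/SOA; SO<sub>x</sub>/pSO<sub>4</sub>;
NO<sub>x</sub>/pNO<sub>3</sub>; NH<sub>3</sub>/pNH<sub>4</sub>):

∂C/∂t = −∇·(v̄ C̄) − ∇·(ṽ C̃) − ∇·(v′C′) + Σ R + E − d

to steady state, using *annual-average* fields extracted (or here,
synthesized) from hourly CTM-style meteorology:

- **Grid** — a variable-resolution rectangular grid (quadtree splitting,
  default 48→24→12→6→3→1 km) refined where people live, with fixed vertical
  layers and only the coarsest horizontal resolution above ≈1500 m; the
  grid can also refine dynamically from population × concentration-gradient
  scores while the solver runs.
- **Transport** — first-order upwind advection by the annual-mean wind
  (flux form, mass conserving on variable-resolution interfaces); a
  symmetric "deviation advection" exchange proportional to the annual mean
  absolute wind deviation |Ũ| (sub-annual variability resolved by the
  parent model); and a combined local (K-theory) / nonlocal (convective
  M2u/M2d) boundary-layer mixing closure.
- **Chemistry** — first-order SO<sub>2</sub>→sulfate conversion with an
  hourly-averaged rate constant k<sub>S</sub>, and instantaneous
  gas/particle partitioning of the NO<sub>x</sub>/pNO<sub>3</sub>,
  NH<sub>3</sub>/pNH<sub>4</sub> and VOC/SOA pairs by annual-average
  marginal partitioning fractions f<sub>p</sub> (applied last each step).
- **Removal** — dry deposition in ground cells via serial resistances
  v<sub>dd</sub> = (r<sub>a</sub>+r<sub>b</sub>+r<sub>c</sub>)⁻¹ (plus
  settling for particles) and first-order wet scavenging everywhere.
- **Time stepping** — explicit pseudo-time iteration with a
  CFL-limited step Δt = C<sub>max</sub> / (3 max((|U|+|Ũ|)/Δx, …)) until the
  population-weighted total-PM2.5 change converges. All operators are
  linear in C, so responses superpose across scenarios.
- **Evaluation** — paired-comparison statistics (MB, ME, MFB, MFE, model
  ratio, slope/intercept/R²) with optional area or population weighting.

Emission scenarios are GeoJSON features (points, lines, polygons; amounts
may be negative for reductions) with optional stack attributes; elevated
sources are injected at the layer given by a Briggs-type plume rise using
pre-averaged wind-speed moments. A seeded synthetic-field generator
produces physically plausible annual-average archives so the entire
pipeline is testable without CTM output.

## Worked example

`examples/03_point_source_steady_state.py` builds the bundled demo — a
96 × 96 km domain, 24 km base cells refined to 3 km over one urban cluster
of a million people, a synthetic field archive, and a single ground-level
point source emitting 100 short tons/yr of primary PM2.5 in the cluster —
and solves it to steady state:

```
converged: True after 1100 iterations (dt = 32.1 s)
population-weighted mean total PM2.5 change: 1.267e-02 ug m^-3
area-weighted mean total PM2.5 change:       1.403e-03 ug m^-3
```

The population-weighted exposure change is ~9× the area-weighted change
because the plume peaks in the populated, finely gridded cluster — the
behavior the variable-resolution grid is designed to capture. The same run
is available from the shell:

```sh
steadypm make-demo --seed 1 --outdir demo
steadypm run demo/config.yaml
```

Other examples cover grid construction, the hourly-to-annual preprocessor
estimators, plume rise, and the comparison statistics. The other CLI
subcommands are `evaluate` (stats tables from paired CSV data) and
`grid-export` (grid cells as GeoJSON).

## Layout

- `src/steadypm/grid.py` — variable-resolution grid, population surfaces,
  refinement, area weighting
- `src/steadypm/fields.py` — annual-average parameter archive,
  hourly-to-annual estimators, synthetic generator, NetCDF I/O
- `src/steadypm/emissions.py` — scenario ingestion, Briggs plume rise,
  source gridding
- `src/steadypm/solver.py` — operators, CFL step, steady-state iteration
- `src/steadypm/evaluate.py` — comparison statistics and weighted means
- `src/steadypm/run.py`, `src/steadypm/cli.py` — orchestration and the
  thin command-line interface
- `docs/methods.md` — modeling assumptions, parameter choices, numerical
  details and limitations
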