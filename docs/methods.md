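# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `steadypm`, in the order the pipeline uses them. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and species

The model predicts *marginal* annual-average concentration changes: the
steady-state response of nine coupled species (primary PM2.5, VOC, SOA,
SO<sub>x</sub> gas, particulate sulfate, NO<sub>x</sub> gas, particulate
nitrate, NH<sub>3</sub> gas, particulate ammonium) to changes in annual
emissions. Because every operator is linear in the concentrations,
responses scale and superpose across scenarios, and concentration changes
may legitimately be negative (emission reductions). Total PM2.5 is the sum
of the five particle species. Aerosol thermodynamic coupling between the
inorganic species, ozone chemistry, and time-resolved output are out of
scope.

Gas precursors are tracked as the mass of the particle they can form:
SO<sub>2</sub> as sulfate-equivalent (×96.0626/64.0638), NO<sub>2</sub> as
nitrate-equivalent (×62.0049/46.0055), NH<sub>3</sub> as
ammonium-equivalent (×18.0385/17.0305), VOC as SOA-potential mass (yield
1.0 by default, configurable). The conversion happens once, at emission
ingestion, so the chemistry and partitioning operators conserve tracked
mass without stoichiometric bookkeeping inside the solver.

## Grid

Horizontal cells form a quadtree-style hierarchy over a rectangular
domain: a cell splits into `divisors[level]²` children while its footprint
population exceeds `pop_threshold` and it remains above the minimum size.
The default divisor ladder (2, 2, 2, 2, 3) produces the
48→24→12→6→3→1 km size sequence. All edges live on an exact integer
lattice (units of the finest size), so neighbor matching, nesting checks
and face fractions are exact. Layers are fixed interface heights (default
ten layers from a 50 m ground layer to 3300 m); layers whose bottom is at
or above the cap height (default 1500 m) use only the coarsest footprint,
since horizontal concentration variability decays with altitude.

Face fractions `f` are the share of a cell's face covered by each
neighbor: a coarse cell next to two fine cells lists both with f = 0.5;
fractions on interior faces sum to one; boundary faces list no neighbors.
Cell bounds are half-open `[min, max)`, so point lookups are unambiguous.

**Dynamic refinement.** The refinement score of a ground footprint is
(population density, persons m⁻²) × (maximum absolute total-PM2.5
difference to any horizontal neighbor, µg m⁻³). Footprints above the split
threshold are split; complete sibling groups all below the merge threshold
(default split/4) are merged — but never below the population-only
baseline: a parent whose population would re-split it under the static
rule stays split, so a zero-concentration state leaves the static grid
unchanged. Remapping between grids is volume-weighted over exact footprint
overlaps and conserves mass to rounding. Thresholds are configuration
parameters rather than fixed constants. During a run, refinement checks
execute every `refine_every` iterations (default 10 000), after which
fields are conservatively re-interpolated and emissions re-gridded.

**Geometry weighting.** Emission geometries are allocated to cells by
count (points), length (lines) or area (polygons); portions outside the
domain are dropped with a warning (optionally renormalized), since
scenario files may extend past the domain.

## Annual-average fields

The solver consumes only annual averages, but several of them are averages
of *hourly, nonlinear* quantities — averaging the inputs instead would
bias the result:

- **SO<sub>2</sub> oxidation** k<sub>S</sub> is the mean of hourly rate
  constants. The hourly rate is a gas-phase termolecular expression in
  temperature and hydroxyl concentration (low/high-pressure limits with a
  broadening factor) plus an effective aqueous term proportional to cloud
  fraction and liquid water content. The constants are configuration
  parameters (`SulfurOxidationParams`); the averaging procedure is the
  fixed part.
- **Partitioning fractions** f<sub>p</sub> average the particle share of
  consecutive-hour mass changes, f<sub>p</sub> = ⟨Δm<sub>p</sub> /
  (Δm<sub>p</sub>+Δm<sub>g</sub>)⟩. Steps with zero total change are
  skipped (n reduced); shares outside [0, 1] (opposite-signed phase
  changes) are clamped, keeping f<sub>p</sub> a valid fraction. The
  estimator is invariant to uniform mass rescaling.
- **Wind deviations** |Ũ|, |Ṽ| are means of absolute hourly departures
  from the annual mean; a wind blowing +2 and −2 m s⁻¹ in equal measure
  becomes 0 m s⁻¹ directional advection plus 2 m s⁻¹ symmetric exchange.
- **Mixing coefficients** are hourly means of a simple closure: convective
  coefficients M2u = 0.3 w*/h act only in unstable hours
  (w* the convective velocity scale, h the hourly boundary-layer height);
  K<sub>zz</sub> = κ u* z<sub>ref</sub> with a small floor; horizontal K
  scales with u*. These per-hour forms are deliberately simple — the
  model's substance is the averaging and the solver, not the closure
  constants, which are configurable.

**Face conventions.** U/Udev/K<sub>xx</sub> live on each cell's west face,
V/Vdev/K<sub>yy</sub> on the south face, W/K<sub>zz</sub> on the bottom
face. The value on a shared face is the one stored by the cell on the
positive (east/north/upper) side. A cell's east/north/top faces on the
domain boundary reuse the cell's own stored value (uniform wind across the
cell) — a package choice, since no cell owns those faces.

**Column consistency of M2u/M2d.** With the nonlocal scheme written as
"elevated cell i gains M2u<sub>i</sub>·C<sub>ground</sub>, loses
M2d<sub>i</sub>·C<sub>i</sub> downward (thickness-scaled)", column mass is
conserved for any coefficients, but a *uniform* column is a fixed point
only under the telescoping relation
M2d<sub>i</sub>Δz<sub>i</sub> = Σ<sub>k≥i, BL</sub> M2u<sub>k</sub>Δz<sub>k</sub>
(cumulative from the boundary-layer top). The generator enforces exactly
this, and the matrix-oracle tests verify both properties. The ground cell
pays the total upward flux and receives the lowest M2d flux.

**Synthetic archive.** The generator emulates the structure of a
preprocessed CTM archive under the study conditions: annual-mean ground
wind speeds of 1–8 m s⁻¹ growing to 30 m s⁻¹ at the domain top; deviations
0.6× the local speed; boundary-layer heights 600–1400 m; K<sub>zz</sub> of
5–40 m² s⁻¹ in the boundary layer (0.2 above); horizontal K of
50–400 m² s⁻¹; k<sub>S</sub> ~ 10⁻⁶ s⁻¹; partitioning fractions in
species-typical ranges (nitrate 0.15–0.55, ammonium 0.35–0.85, organics
0.1–0.4); deposition resistances of tens to hundreds of s m⁻¹; wet
scavenging rates of 10⁻⁷–5×10⁻⁶ s⁻¹. Spatial structure comes from
low-order random Fourier fields — smooth, deterministic under a seed, and
functions of position rather than of the grid, so refinement resamples the
same underlying field. k<sub>S</sub> and f<sub>p</sub> are actually derived
by running the hourly estimators on generated hourly series, then
modulated spatially. What the generator does *not* emulate: terrain,
land-use contrasts, coherent synoptic structures, diurnal covariance
between wind and mixing, or realistic emission-landscape correlation —
passing tests demonstrate the numerics and the pipeline, not skill against
real atmospheres.

## Emissions and plume rise

Scenario files are GeoJSON feature collections (ESRI shapefile reading is
not supported in this build; convert to GeoJSON first). Species attributes
VOC, NOx, NH3, SOx, PM2_5 are matched case-insensitively; missing species
are zero; amounts are annual totals in short tons/yr by default (kg and
tonnes switchable); a Julian year (3.15576×10⁷ s) converts totals to
rates. Stack attributes (height, diam, temp, velocity) must be all present
or all absent. Declared projections are checked for equality with the
grid's; no reprojection is performed.

Plume rise is Briggs-type final rise using the pre-averaged wind-speed
moments: stable branches (buoyant 2.6 (F/s)^⅓, momentum
1.5 (F<sub>m</sub>/√s)^⅓) use the mean of u^−1/3 with the stability
parameter s = (g/θ)∂θ/∂z; neutral/unstable buoyant rise
(21.425 F^¾ below F = 55 m⁴ s⁻³, else 38.71 F^0.6) and momentum rise
(3 d v<sub>s</sub>) use the mean of u^−1. The larger of the buoyant and
momentum rises is taken, the branch selected by the archive's stability
flag. The mean of u^−1.4 is computed and stored in the archive for
alternative unstable formulations but is unused by the default scheme — no
standard final-rise formula with that exponent was adopted. For lines and
polygons the rise is evaluated once, at the geometry centroid's column.
Emission reductions are treated identically to additions, including plume
rise. Rise is monotone in stack height and buoyancy flux and the injection
layer is capped at the model top.

## Solver numerics

All operators are assembled once per grid/field combination as sparse
matrices and applied as matrix-vector products; the per-operator functions
expose individual increments for testing.

- **Upwind advection in flux form:** each interface flux debits the upwind
  cell and credits the downwind cell (÷ its volume), which conserves mass
  exactly across variable-resolution interfaces — the per-cell form alone
  would not.
- **Deviation advection** exchanges |Ũ|(C<sub>j</sub>−C<sub>i</sub>)·A/V
  symmetrically, horizontal faces only: the CFL constraint carries no
  vertical deviation term, and vertical sub-annual variability is
  delegated to the mixing closure.
- **Diffusion** uses two-point fluxes 2K(C<sub>j</sub>−C<sub>i</sub>)/(Δ<sub>i</sub>+Δ<sub>j</sub>)
  per unit face area, with the face K taken from the positive-side cell.
- **Boundary conditions:** zero concentration change outside the lateral
  and top faces (inflow carries nothing, outflow and exchange remove
  mass); impermeable ground. A `sealed` mode suppresses all boundary
  exchange for conservation testing.
- **Chemistry, deposition, partitioning:** first-order transfers and
  removals as diagonal/pairwise terms. Partitioning is an idempotent
  linear projection applied *after* all other increments each step; all
  other operators read start-of-step concentrations, so their order is
  immaterial. Pair totals are conserved to one ulp by construction
  (C<sub>g</sub> ← T − C<sub>p</sub>).
- **Dry deposition:** ground cells only; gases use
  v<sub>dd</sub> = (r<sub>a</sub>+r<sub>b</sub>+r<sub>c,gas</sub>)⁻¹,
  particles add the Stokes–Cunningham settling velocity of a 0.3 µm,
  1830 kg m⁻³ particle (the model's fixed aerosol properties, used only
  here) to (r<sub>a</sub>+r<sub>b</sub>+r<sub>c,particle</sub>)⁻¹, with
  the generator setting r<sub>c,particle</sub> = r<sub>a</sub>r<sub>b</sub>v<sub>s</sub>.
- **Wet deposition:** class-specific first-order rates (particle, SO₂,
  other gas) in every cell.

**Time step.** Δt = C<sub>max</sub>/(3·max over cells of
(|U|+|Ũ|)/Δx, (|V|+|Ṽ|)/Δy, |W|/Δz), with a 10⁻³ m s⁻¹ wind floor so the
calm case stays finite, and C<sub>max</sub> = 1 by default. Because the
advective CFL bound does not by itself stabilize explicit diffusion,
mixing and removal, the step is additionally capped by a Gershgorin bound:
Δt ≤ 0.9 C<sub>max</sub>/max<sub>i</sub>(total first-order loss rate of
cell i). The steady solution is provably independent of Δt (the fixed
point solves P(MC+S) = 0 with C in the range of the partitioning
projection P), which the Δt-halving test confirms to well under 0.5%.

**Convergence.** The monitored scalar is the population-weighted (area
fallback) ground-level mean total-PM2.5 change; the run stops when its
change over a 100-iteration window falls below 10⁻⁶ relative (absolute
floor 10⁻¹² for near-zero scenarios), up to 10⁶ iterations, and flags
non-convergence instead of raising. Blow-ups (non-finite concentrations)
raise an error naming the first offending cell, species and operator.

**Verification strategy.** The test suite assembles the full step operator
independently — dense matrices built by plain per-cell/per-face loops that
transcribe the discretized equations (`tests/_oracles.py`) — and checks
the package's sparse operators entry-by-entry, the iterated steady state
against a direct solve of (I−A)C = b on sub-100-cell grids and on the
457-cell demo, mass budgets to 10⁻⁹, and linearity/superposition to 10⁻⁶.

## Evaluation statistics

MB, ME, MFB, MFE use per-pair formulas with the fractional denominators
(Y<sub>i</sub>+X<sub>i</sub>); MR is the mean per-pair ratio. Pairs with
X+Y = 0 are excluded from fractional metrics and pairs with X = 0 from MR,
with exclusion tallies on the result object. Fractional metrics are stored
as fractions and rendered ×100 with a percent sign. With weights, all
means are weighted and the regression is weighted least squares; R² is the
weighted squared Pearson correlation by default, with the unweighted value
also reported (both conventions exist in practice). With a single pair the
means are defined and the regression fields are NaN, flagged via
`regression_defined`.

## Problem sizes and defaults used in the shipped runs

The bundled demo uses a 96 × 96 km domain, 24 km base cells with divisors
(2, 2, 2) down to 3 km over one urban cluster of 10⁶ people, seven layers
to 3500 m (two above the 1500 m cap), 457 cells in total, and a single
ground-level 100 short-ton/yr primary-PM2.5 point source. This size keeps
every verification — including the dense direct solve of the full
9×457-species-cell system — comfortably within a desktop run while
exercising variable resolution in all three dimensions. Test grids are
smaller still (≤100 cells) where a dense oracle is compared
entry-by-entry. Hourly estimator tests use shortened series (240–2000
steps) via the configurable `n_hours`; the default remains 8760.

## Known limitations

- First-order upwind advection is numerically diffusive; fine cells in
  populated areas mitigate but do not remove this.
- The cross Reynolds terms ∇·(v′C̃) and ∇·(ṽC′) are dropped.
- The synthetic generator's closure constants are plausible defaults, not
  calibrated values; runs on real archives require a preprocessor for the
  corresponding CTM output, which this build stubs out (the archive format
  and the averaging mathematics are in place).
- Steady-state annual averaging cannot represent covariances between
  emissions timing and meteorology.
- Shapefile input, map reprojection, and GeoTIFF rasters are not
  supported; inputs must be GeoJSON / ASCII-grid in the grid's projection.
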