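"""Run orchestration: configuration, end-to-end runs, demo inputs.

A run is: load the field archive (which carries the grid), read the
emission-change scenario, grid the emissions with plume rise, iterate the
solver to steady state (optionally refining the grid dynamically), and
write the outputs: per-cell concentration changes (GeoJSON for the ground
layer, NetCDF-style archive for all cells), the convergence trace (CSV),
and provenance metadata.  Reruns with an identical configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
import yaml
from shapely.geometry import Point

from . import emissions as em
from . import solver as sv
from .evaluate import weighted_mean
from .fields import (CellFields, SynthesisParams, read_archive,
                     synthesize_archive, write_archive, _FIELD_NAMES)
from .grid import (GridConfig, RasterPopulation, RefineThresholds,
                   VariableGrid, build_static_grid, grid_to_geojson,
                   interpolate_conservative, refine_dynamic)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    field_archive: str
    emissions: list[str]
    output_dir: str
    population: str | None = None
    dynamic: bool = False
    split_threshold: float = 1e-4
    merge_threshold: float | None = None
    refine_every: int = 10_000
    cmax: float = 1.0
    tol: float = 1e-6
    check_every: int = 100
    max_iter: int = 1_000_000
    units: str = "short_tons"
    soa_yield: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = os.path.dirname(os.path.abspath(path))
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        grid_opts = raw.get("grid", {})
        solver_opts = raw.get("solver", {})
        unit_opts = raw.get("units", {})

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        ems = paths.get("emissions", [])
        if isinstance(ems, str):
            ems = [ems]
        return cls(
            field_archive=resolve(paths.get("field_archive", "")),
            emissions=[resolve(p) for p in ems],
            output_dir=resolve(paths.get("output_dir", "output")),
            population=(resolve(paths["population"])
                        if paths.get("population") else None),
            dynamic=bool(grid_opts.get("dynamic", False)),
            split_threshold=float(grid_opts.get("split_threshold", 1e-4)),
            merge_threshold=(float(grid_opts["merge_threshold"])
                             if grid_opts.get("merge_threshold") is not None else None),
            refine_every=int(grid_opts.get("refine_every", 10_000)),
            cmax=float(solver_opts.get("cmax", 1.0)),
            tol=float(solver_opts.get("tol", 1e-6)),
            check_every=int(solver_opts.get("check_every", 100)),
            max_iter=int(solver_opts.get("max_iter", 1_000_000)),
            units=str(unit_opts.get("emissions", "short_tons")),
            soa_yield=float(unit_opts.get("soa_yield", 1.0)),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("logging", "INFO")),
        )

    def validate(self) -> list[str]:
        """Return every problem found (empty list means valid)."""
        problems = []
        if not self.field_archive or not os.path.exists(self.field_archive):
            problems.append(f"field archive not found: {self.field_archive!r}")
        if not self.emissions:
            problems.append("no emissions files configured")
        for p in self.emissions:
            if not os.path.exists(p):
                problems.append(f"emissions file not found: {p!r}")
        if self.population is not None and not os.path.exists(self.population):
            problems.append(f"population file not found: {self.population!r}")
        if self.dynamic and self.population is None:
            problems.append("dynamic grid refinement requires a population surface")
        if not (0.0 < self.cmax <= 1.0):
            problems.append(f"cmax must be in (0, 1], got {self.cmax}")
        if self.tol <= 0:
            problems.append(f"convergence tolerance must be positive, got {self.tol}")
        if self.units not in em.UNIT_GRAMS:
            problems.append(f"unknown emission unit {self.units!r}")
        return problems

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def interpolate_fields(old_grid: VariableGrid, new_grid: VariableGrid,
                       fields: CellFields) -> CellFields:
    """Area-weighted remap of the archive onto a refined/coarsened grid."""
    stacked = np.column_stack([getattr(fields, name) for name in _FIELD_NAMES])
    remapped = interpolate_conservative(old_grid, new_grid, stacked)
    kw = {name: remapped[:, k] for k, name in enumerate(_FIELD_NAMES)}
    kw["plume_unstable"] = (kw["plume_unstable"] >= 0.5).astype(float)
    return CellFields(**kw)


def run(config: RunConfig) -> dict:
    """Execute an end-to-end run; returns a summary dict of the outputs."""
    problems = config.validate()
    if problems:
        raise ConfigError("invalid run configuration:\n  - " + "\n  - ".join(problems))
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    grid, fields = read_archive(config.field_archive)
    records = em.read_emissions(config.emissions, grid_crs=grid.crs)
    source = em.grid_emissions(records, grid, fields, units=config.units,
                               soa_yield=config.soa_yield)
    cc = sv.ConvergenceConfig(tol=config.tol, check_every=config.check_every,
                              max_iter=config.max_iter)
    state = sv.SolverState.create(grid, fields, source, cmax=config.cmax)
    if config.dynamic:
        pop = RasterPopulation.read_ascii(config.population)
        thresholds = RefineThresholds(config.split_threshold, config.merge_threshold)
        conc, diagnostics = _run_dynamic(state, records, pop, thresholds, config, cc)
        grid, fields = state.grid, state.fields
    else:
        conc, diagnostics = sv.run_to_steady_state(state, cc)

    os.makedirs(config.output_dir, exist_ok=True)
    outputs = write_outputs(config, grid, conc, diagnostics)
    return {"diagnostics": {k: v for k, v in diagnostics.items() if k != "trace"},
            "outputs": outputs,
            "population_weighted_total_pm25": weighted_mean(
                sv.total_pm25(conc), grid, "population"),
            "area_weighted_total_pm25": weighted_mean(
                sv.total_pm25(conc), grid, "area")}


def _run_dynamic(state, records, pop, thresholds, config, cc):
    """Alternate solve chunks with score-based grid refinement."""
    it_limit = cc.max_iter
    converged = False
    while state.iteration < it_limit:
        chunk = sv.ConvergenceConfig(
            tol=cc.tol, check_every=cc.check_every,
            max_iter=min(it_limit, state.iteration + config.refine_every))
        conc, diagnostics = sv.run_to_steady_state(state, chunk)
        new_grid, new_conc = refine_dynamic(state.grid, conc, pop, thresholds)
        changed = new_grid.n_cells != state.grid.n_cells or \
            new_grid.footprint_leaves != state.grid.footprint_leaves
        if changed:
            log.info("dynamic refinement: %d -> %d cells at iteration %d",
                     state.grid.n_cells, new_grid.n_cells, state.iteration)
            new_fields = interpolate_fields(state.grid, new_grid, state.fields)
            new_source = em.grid_emissions(records, new_grid, new_fields,
                                           units=config.units,
                                           soa_yield=config.soa_yield)
            old_iter = state.iteration
            state2 = sv.SolverState.create(new_grid, new_fields, new_source,
                                           cmax=config.cmax, conc=new_conc)
            state2.iteration = old_iter
            state2.history = state.history
            state.__dict__.update(state2.__dict__)
        elif diagnostics["converged"]:
            converged = True
            break
    conc = state.conc
    diagnostics = {"iterations": state.iteration, "converged": converged,
                   "dt": state.dt, "monitor": state.history[-1][1],
                   "trace": list(state.history)}
    return conc, diagnostics


def write_outputs(config: RunConfig, grid: VariableGrid, conc: np.ndarray,
                  diagnostics: dict) -> dict:
    out = {}
    values = {name: conc[:, i] for i, name in enumerate(sv.SPECIES)}
    values["TotalPM25"] = sv.total_pm25(conc)

    gj_path = os.path.join(config.output_dir, "concentrations.geojson")
    with open(gj_path, "w") as fh:
        json.dump(grid_to_geojson(grid, values, layer=0), fh, sort_keys=True)
    out["concentrations_geojson"] = gj_path

    nc_path = os.path.join(config.output_dir, "concentrations.nc")
    ds = xr.Dataset({k: ("cell", v) for k, v in values.items()})
    ds.attrs["units"] = "ug m-3"
    ds.to_netcdf(nc_path, engine="scipy")
    out["concentrations_nc"] = nc_path

    trace_path = os.path.join(config.output_dir, "convergence.csv")
    with open(trace_path, "w") as fh:
        fh.write("iteration,pop_weighted_total_pm25\n")
        for it, q in diagnostics["trace"]:
            fh.write(f"{it},{q!r}\n")
    out["convergence_csv"] = trace_path

    prov_path = os.path.join(config.output_dir, "provenance.json")
    with open(prov_path, "w") as fh:
        json.dump({
            "config_digest": config.digest(),
            "seed": config.seed,
            "iterations": diagnostics["iterations"],
            "converged": diagnostics["converged"],
            "dt_seconds": diagnostics["dt"],
            "n_cells": int(grid.n_cells),
        }, fh, sort_keys=True, indent=1)
    out["provenance_json"] = prov_path
    return out


# ---------------------------------------------------------------------------
# demo bundle
# ---------------------------------------------------------------------------

DEMO_LAYER_TOPS = (50.0, 150.0, 350.0, 700.0, 1500.0, 2500.0, 3500.0)


def make_demo(seed: int, outdir, point_source_tons: float = 100.0) -> str:
    """Write a ready-to-run demo bundle; returns the config path.

    The bundle holds a small synthetic domain (96 x 96 km, 24 km base cells
    refined to 3 km over one urban cluster, 7 layers), a synthetic field
    archive, a single ground-level point source of 100 short tons/yr of
    primary PM2.5 in the cluster, the population raster, and the run
    configuration.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)

    # population: one urban cluster on a 3 km raster
    n_pix = 32
    cellsize = 3000.0
    xs = (np.arange(n_pix) + 0.5) * cellsize
    cx, cy = 52_000.0, 44_000.0
    gx = np.exp(-0.5 * ((xs - cx) / 9000.0) ** 2)
    gy = np.exp(-0.5 * ((xs - cy) / 9000.0) ** 2)
    pop = 1.0e6 * np.outer(gy, gx) / np.outer(gy, gx).sum()
    pop *= 1.0 + 0.05 * rng.standard_normal(pop.shape)
    pop = np.clip(pop, 0.0, None)
    raster = RasterPopulation(pop[::-1], 0.0, 0.0, cellsize)  # row 0 north
    pop_path = os.path.join(outdir, "population.asc")
    raster.write_ascii(pop_path)

    cfg = GridConfig(domain_bounds=(0.0, 0.0, 96_000.0, 96_000.0),
                     base_size=24_000.0, divisors=(2, 2, 2),
                     pop_threshold=30_000.0, high_res_cap_height=1500.0,
                     layer_tops=DEMO_LAYER_TOPS, crs="local-meters")
    grid = build_static_grid(raster, cfg)
    fields = synthesize_archive(grid, seed, SynthesisParams())
    archive_path = os.path.join(outdir, "archive.nc")
    write_archive(archive_path, grid, fields, metadata={"seed": seed})

    emis_path = os.path.join(outdir, "emissions.geojson")
    rec = em.EmissionRecord(Point(cx, cy), {"PM2_5": point_source_tons})
    em.write_emissions([rec], emis_path, crs=cfg.crs)

    config = {
        "paths": {
            "field_archive": "archive.nc",
            "emissions": ["emissions.geojson"],
            "population": "population.asc",
            "output_dir": "output",
        },
        "grid": {"dynamic": False},
        "solver": {"cmax": 1.0, "tol": 1.0e-6, "check_every": 100,
                   "max_iter": 200000},
        "units": {"emissions": "short_tons", "soa_yield": 1.0},
        "seed": seed,
        "logging": "INFO",
    }
    cfg_path = os.path.join(outdir, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
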