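"""Variable-resolution rectangular grid.

The horizontal domain is tiled by a quadtree-style hierarchy of square cells:
a coarse base grid is recursively subdivided (per-level integer split factors)
wherever the resident population exceeds a threshold, so cells are small in
cities and large in rural or remote areas.  The vertical dimension uses fixed
layer interfaces; above a cap height (default 1500 m) only the coarsest
horizontal resolution is used, because horizontal concentration variability
decays with altitude.

All cell edges lie on an exact integer lattice whose unit is the finest cell
size, which makes neighbor matching and nesting checks exact rather than
floating-point.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import box, shape, mapping
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

FACES = ("W", "E", "S", "N", "B", "A")

#: default vertical layer interface heights (m): a 50 m ground layer
#: stretching to the domain top.
DEFAULT_LAYER_TOPS = (50.0, 120.0, 210.0, 330.0, 500.0, 750.0,
                      1100.0, 1600.0, 2300.0, 3300.0)


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the variable-resolution grid.

    Parameters
    ----------
    domain_bounds:
        (xmin, ymin, xmax, ymax) in projected meters.  Width and height must
        be integer multiples of ``base_size``.
    base_size:
        Edge length (m) of the coarsest (unsplit) cells.
    divisors:
        Per-level split factors.  The default (2, 2, 2, 2, 3) yields the
        48 -> 24 -> 12 -> 6 -> 3 -> 1 km cell-size ladder.
    pop_threshold:
        A cell is split while the population inside its footprint exceeds
        this number of persons (and it can still be split).
    min_size:
        Optional floor on cell edge length; must equal ``base_size`` divided
        by a leading product of ``divisors``.
    high_res_cap_height:
        Layers whose bottom is at or above this altitude (m) use only the
        coarsest horizontal resolution.
    layer_tops:
        Vertical layer interface heights (m), ground layer first.
    crs:
        Free-form projection descriptor carried through to outputs.
    """

    domain_bounds: tuple[float, float, float, float]
    base_size: float = 48000.0
    divisors: tuple[int, ...] = (2, 2, 2, 2, 3)
    pop_threshold: float = 10000.0
    min_size: float | None = None
    high_res_cap_height: float = 1500.0
    layer_tops: tuple[float, ...] = DEFAULT_LAYER_TOPS
    crs: str | None = None

    def __post_init__(self):
        x0, y0, x1, y1 = self.domain_bounds
        if not (x1 > x0 and y1 > y0):
            raise GridError("domain_bounds must satisfy xmax > xmin, ymax > ymin")
        for d in self.divisors:
            if int(d) != d or d < 2:
                raise GridError("each split divisor must be an integer >= 2")
        for name, v in (("nx", (x1 - x0) / self.base_size),
                        ("ny", (y1 - y0) / self.base_size)):
            if abs(v - round(v)) > 1e-9:
                raise GridError(
                    f"domain extent must be an integer multiple of base_size ({name}={v})")
        if self.min_size is not None:
            s = self.base_size
            ok = math.isclose(self.min_size, s)
            for d in self.divisors:
                s /= d
                ok = ok or math.isclose(self.min_size, s)
            if not ok:
                raise GridError(
                    "min_size must equal base_size divided by a leading product "
                    f"of the divisors {self.divisors}")
        tops = self.layer_tops
        if any(b >= a for b, a in zip(tops, tops[1:])) or tops[0] <= 0:
            raise GridError("layer_tops must be strictly increasing and positive")

    # --- integer lattice helpers -------------------------------------------------
    @property
    def max_level(self) -> int:
        if self.min_size is None:
            return len(self.divisors)
        s, lvl = self.base_size, 0
        while not math.isclose(s, self.min_size):
            s /= self.divisors[lvl]
            lvl += 1
        return lvl

    @property
    def size_units(self) -> tuple[int, ...]:
        """Edge length of a cell at each level, in units of the finest size."""
        out = [1]
        for d in reversed(self.divisors):
            out.append(out[-1] * d)
        return tuple(reversed(out))

    @property
    def unit_size(self) -> float:
        """Finest lattice unit in meters."""
        return self.base_size / self.size_units[0]

    @property
    def nx_base(self) -> int:
        x0, _, x1, _ = self.domain_bounds
        return round((x1 - x0) / self.base_size)

    @property
    def ny_base(self) -> int:
        _, y0, _, y1 = self.domain_bounds
        return round((y1 - y0) / self.base_size)


@dataclass
class GridCell:
    """Read-only view of one cell of a :class:`VariableGrid`."""

    id: int
    layer: int
    bounds: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)
    dx: float
    dy: float
    dz: float
    population: float
    neighbors: dict[str, list[tuple[int, float]]]
    is_lateral_boundary: bool
    is_top: bool
    is_ground: bool

    @property
    def polygon(self):
        xmin, xmax, ymin, ymax = self.bounds
        return box(xmin, ymin, xmax, ymax)

    @property
    def area(self) -> float:
        return self.dx * self.dy

    @property
    def volume(self) -> float:
        return self.dx * self.dy * self.dz


class VariableGrid:
    """Variable-resolution grid: quadtree horizontal footprints x fixed layers.

    Cells are stored in a flat, deterministically ordered table (layer-major,
    then row-major south to north).  Horizontal footprints are identical for
    all layers below ``high_res_cap_height``; layers above use the base
    (coarsest) footprint.
    """

    def __init__(self, config: GridConfig,
                 leaves: Sequence[tuple[int, int, int]],
                 leaf_population: Sequence[float]):
        self.config = config
        idx = sorted(range(len(leaves)),
                     key=lambda k: (leaves[k][2], leaves[k][1], leaves[k][0]))
        self._leaves = [tuple(leaves[k]) for k in idx]          # (level, x0u, y0u)
        self._leaf_pop = [float(leaf_population[k]) for k in idx]
        self._check_tiling()
        self._build_cells()
        self._topology: list[dict[str, list[tuple[int, float]]]] | None = None
        self._ground_below: list[list[tuple[int, float]]] | None = None

    # -- construction ------------------------------------------------------------
    def _check_tiling(self):
        cfg = self.config
        su = cfg.size_units
        total = 0
        seen = set()
        for (lvl, x0u, y0u) in self._leaves:
            if (lvl, x0u, y0u) in seen:
                raise GridError("duplicate footprint leaf")
            seen.add((lvl, x0u, y0u))
            s = su[lvl]
            if x0u % s or y0u % s:
                raise GridError("footprint not aligned to its level lattice")
            total += s * s
        dom = (cfg.nx_base * su[0]) * (cfg.ny_base * su[0])
        if total != dom:
            raise GridError(
                f"footprint leaves do not tile the domain (area {total} != {dom} units^2)")

    def _build_cells(self):
        cfg = self.config
        su0 = cfg.size_units[0]
        base_leaves = [(0, i * su0, j * su0)
                       for j in range(cfg.ny_base) for i in range(cfg.nx_base)]
        base_pop_map = {}
        for (lvl, x0u, y0u), p in zip(self._leaves, self._leaf_pop):
            key = (x0u // su0, y0u // su0)
            base_pop_map[key] = base_pop_map.get(key, 0.0) + p

        tops = cfg.layer_tops
        bottoms = (0.0,) + tops[:-1]
        level_arr, x0u_arr, y0u_arr, layer_arr, pop_arr = [], [], [], [], []
        self._layer_slices: list[slice] = []
        n = 0
        for L, (bot, top) in enumerate(zip(bottoms, tops)):
            if bot < cfg.high_res_cap_height:
                lay_leaves, lay_pop = self._leaves, self._leaf_pop
            else:
                lay_leaves = base_leaves
                lay_pop = [base_pop_map.get((x // su0, y // su0), 0.0)
                           for (_, x, y) in base_leaves]
            for (lvl, x0u, y0u), p in zip(lay_leaves, lay_pop):
                level_arr.append(lvl)
                x0u_arr.append(x0u)
                y0u_arr.append(y0u)
                layer_arr.append(L)
                pop_arr.append(p)
            self._layer_slices.append(slice(n, n + len(lay_leaves)))
            n += len(lay_leaves)
        self.level = np.asarray(level_arr, dtype=np.int64)
        self.x0u = np.asarray(x0u_arr, dtype=np.int64)
        self.y0u = np.asarray(y0u_arr, dtype=np.int64)
        self.layer = np.asarray(layer_arr, dtype=np.int64)
        self.population = np.asarray(pop_arr, dtype=float)
        su = np.asarray(cfg.size_units, dtype=np.int64)
        self.szu = su[self.level]
        unit = cfg.unit_size
        x0, y0 = cfg.domain_bounds[0], cfg.domain_bounds[1]
        self.xmin = x0 + self.x0u * unit
        self.ymin = y0 + self.y0u * unit
        self.dx = self.szu * unit
        self.dy = self.szu * unit
        self.xmax = self.xmin + self.dx
        self.ymax = self.ymin + self.dy
        dz = np.diff((0.0,) + tuple(tops))
        self.dz = dz[self.layer]
        self.zbottom = np.asarray((0.0,) + tuple(tops[:-1]))[self.layer]
        self.ztop = np.asarray(tops)[self.layer]

    # -- basic queries -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.level.size

    @property
    def n_layers(self) -> int:
        return len(self.config.layer_tops)

    @property
    def layer_tops(self):
        return self.config.layer_tops

    @property
    def domain_bounds(self):
        return self.config.domain_bounds

    @property
    def crs(self):
        return self.config.crs

    @property
    def high_res_cap_height(self):
        return self.config.high_res_cap_height

    @property
    def footprint_leaves(self) -> list[tuple[int, int, int]]:
        return list(self._leaves)

    def layer_cells(self, layer: int) -> np.ndarray:
        return np.arange(self._layer_slices[layer].start, self._layer_slices[layer].stop)

    @property
    def ground_cells(self) -> np.ndarray:
        return self.layer_cells(0)

    @property
    def area(self) -> np.ndarray:
        return self.dx * self.dy

    @property
    def volume(self) -> np.ndarray:
        return self.dx * self.dy * self.dz

    def cell(self, i: int) -> GridCell:
        topo = self.face_topology()
        nbrs = topo[i]
        lateral = any(len(nbrs[f]) == 0 for f in ("W", "E", "S", "N"))
        return GridCell(
            id=i, layer=int(self.layer[i]),
            bounds=(float(self.xmin[i]), float(self.xmax[i]),
                    float(self.ymin[i]), float(self.ymax[i])),
            dx=float(self.dx[i]), dy=float(self.dy[i]), dz=float(self.dz[i]),
            population=float(self.population[i]),
            neighbors=nbrs,
            is_lateral_boundary=lateral,
            is_top=int(self.layer[i]) == self.n_layers - 1,
            is_ground=int(self.layer[i]) == 0,
        )

    def cells(self) -> Iterable[GridCell]:
        for i in range(self.n_cells):
            yield self.cell(i)

    # -- topology ----------------------------------------------------------------
    def face_topology(self) -> list[dict[str, list[tuple[int, float]]]]:
        """Per-cell neighbor table: face -> list of (neighbor id, fraction).

        The fraction is the share of *this* cell's face covered by the
        neighbor; fractions on interior faces sum to 1, boundary faces have
        empty lists.
        """
        if self._topology is not None:
            return self._topology
        n = self.n_cells
        topo = [{f: [] for f in FACES} for _ in range(n)]
        # horizontal neighbors, per layer
        for L in range(self.n_layers):
            ids = self.layer_cells(L)
            by_xmax: dict[int, list[int]] = {}
            by_xmin: dict[int, list[int]] = {}
            by_ymax: dict[int, list[int]] = {}
            by_ymin: dict[int, list[int]] = {}
            for i in ids:
                by_xmax.setdefault(int(self.x0u[i] + self.szu[i]), []).append(i)
                by_xmin.setdefault(int(self.x0u[i]), []).append(i)
                by_ymax.setdefault(int(self.y0u[i] + self.szu[i]), []).append(i)
                by_ymin.setdefault(int(self.y0u[i]), []).append(i)
            for i in ids:
                x0, y0, s = int(self.x0u[i]), int(self.y0u[i]), int(self.szu[i])
                for face, cands, lo_attr in (
                        ("W", by_xmax.get(x0, ()), "y"),
                        ("E", by_xmin.get(x0 + s, ()), "y"),
                        ("S", by_ymax.get(y0, ()), "x"),
                        ("N", by_ymin.get(y0 + s, ()), "x")):
                    for j in cands:
                        if lo_attr == "y":
                            lo = max(y0, int(self.y0u[j]))
                            hi = min(y0 + s, int(self.y0u[j] + self.szu[j]))
                        else:
                            lo = max(x0, int(self.x0u[j]))
                            hi = min(x0 + s, int(self.x0u[j] + self.szu[j]))
                        if hi > lo:
                            topo[i][face].append((int(j), (hi - lo) / s))
        # vertical neighbors: footprint-overlap fractions of this cell's area
        for L in range(1, self.n_layers):
            below = self.layer_cells(L - 1)
            above = self.layer_cells(L)
            bucket: dict[tuple[int, int], list[int]] = {}
            su0 = self.config.size_units[0]
            for j in below:
                key = (int(self.x0u[j]) // su0, int(self.y0u[j]) // su0)
                bucket.setdefault(key, []).append(j)
            for i in above:
                x0, y0, s = int(self.x0u[i]), int(self.y0u[i]), int(self.szu[i])
                keys = {(bx, by)
                        for bx in range(x0 // su0, (x0 + s - 1) // su0 + 1)
                        for by in range(y0 // su0, (y0 + s - 1) // su0 + 1)}
                my_area = s * s
                for key in keys:
                    for j in bucket.get(key, ()):
                        ox = (min(x0 + s, int(self.x0u[j] + self.szu[j]))
                              - max(x0, int(self.x0u[j])))
                        oy = (min(y0 + s, int(self.y0u[j] + self.szu[j]))
                              - max(y0, int(self.y0u[j])))
                        if ox > 0 and oy > 0:
                            frac = (ox * oy) / my_area
                            topo[i]["B"].append((int(j), frac))
                            topo[j]["A"].append((int(i), (ox * oy) / (self.szu[j] ** 2)))
        for d in topo:
            for f in FACES:
                d[f].sort()
        self._topology = topo
        return topo

    def ground_below(self, i: int) -> list[tuple[int, float]]:
        """Ground-layer cells under cell i, with footprint-area fractions of i."""
        if self._ground_below is None:
            su0 = self.config.size_units[0]
            bucket: dict[tuple[int, int], list[int]] = {}
            for j in self.ground_cells:
                key = (int(self.x0u[j]) // su0, int(self.y0u[j]) // su0)
                bucket.setdefault(key, []).append(int(j))
            out: list[list[tuple[int, float]]] = []
            for c in range(self.n_cells):
                x0, y0, s = int(self.x0u[c]), int(self.y0u[c]), int(self.szu[c])
                lst: list[tuple[int, float]] = []
                keys = {(bx, by)
                        for bx in range(x0 // su0, (x0 + s - 1) // su0 + 1)
                        for by in range(y0 // su0, (y0 + s - 1) // su0 + 1)}
                for key in keys:
                    for j in bucket.get(key, ()):
                        ox = (min(x0 + s, int(self.x0u[j] + self.szu[j]))
                              - max(x0, int(self.x0u[j])))
                        oy = (min(y0 + s, int(self.y0u[j] + self.szu[j]))
                              - max(y0, int(self.y0u[j])))
                        if ox > 0 and oy > 0:
                            lst.append((j, (ox * oy) / (s * s)))
                lst.sort()
                out.append(lst)
            self._ground_below = out
        return self._ground_below[i]

    # -- geometry queries ----------------------------------------------------------
    def locate(self, x: float, y: float, layer: int = 0) -> int | None:
        """Cell containing the point under half-open [min, max) bounds."""
        xb0, yb0, xb1, yb1 = self.config.domain_bounds
        if not (xb0 <= x < xb1 and yb0 <= y < yb1):
            return None
        for i in self.layer_cells(layer):
            if (self.xmin[i] <= x < self.xmax[i]
                    and self.ymin[i] <= y < self.ymax[i]):
                return int(i)
        return None


def area_weights(geometry: BaseGeometry, grid: VariableGrid, layer: int = 0,
                 renormalize: bool = False) -> list[tuple[int, float]]:
    """Fractions of a geometry (count/length/area) inside each cell of a layer.

    Portions outside the domain are dropped with a warning; if
    ``renormalize`` is set, remaining weights are rescaled to sum to 1.
    """
    if geometry is None or geometry.is_empty:
        raise GridError("empty geometry")
    gtype = geometry.geom_type
    out: dict[int, float] = {}
    if gtype in ("Point", "MultiPoint"):
        pts = [geometry] if gtype == "Point" else list(geometry.geoms)
        for p in pts:
            i = grid.locate(p.x, p.y, layer)
            if i is not None:
                out[i] = out.get(i, 0.0) + 1.0 / len(pts)
    elif gtype in ("LineString", "MultiLineString"):
        total = geometry.length
        for i in grid.layer_cells(layer):
            cellbox = box(grid.xmin[i], grid.ymin[i], grid.xmax[i], grid.ymax[i])
            if geometry.intersects(cellbox):
                seg = geometry.intersection(cellbox)
                if seg.length > 0:
                    out[int(i)] = seg.length / total
    elif gtype in ("Polygon", "MultiPolygon"):
        total = geometry.area
        if total <= 0:
            raise GridError("degenerate polygon geometry")
        for i in grid.layer_cells(layer):
            cellbox = box(grid.xmin[i], grid.ymin[i], grid.xmax[i], grid.ymax[i])
            if geometry.intersects(cellbox):
                a = geometry.intersection(cellbox).area
                if a > 0:
                    out[int(i)] = a / total
    else:
        raise GridError(f"unsupported geometry type {gtype}")
    wsum = sum(out.values())
    if wsum < 1.0 - 1e-9:
        log.warning("geometry extends outside the domain; %.3g of its weight dropped",
                    1.0 - wsum)
        if renormalize and wsum > 0:
            out = {k: v / wsum for k, v in out.items()}
    return sorted(out.items())


# --- population surfaces ---------------------------------------------------------

class PopulationSurface:
    def population_in(self, xmin: float, ymin: float, xmax: float, ymax: float) -> float:
        raise NotImplementedError

    def covers(self, bounds: tuple[float, float, float, float]) -> bool:
        raise NotImplementedError


class RasterPopulation(PopulationSurface):
    """Population raster (persons per pixel) on a regular grid.

    Reads/writes the plain-text ESRI ASCII grid format.
    """

    def __init__(self, values: np.ndarray, xll: float, yll: float, cellsize: float):
        self.values = np.asarray(values, dtype=float)  # row 0 = northernmost
        self.xll = float(xll)
        self.yll = float(yll)
        self.cellsize = float(cellsize)

    @property
    def bounds(self):
        ny, nx = self.values.shape
        return (self.xll, self.yll,
                self.xll + nx * self.cellsize, self.yll + ny * self.cellsize)

    def covers(self, bounds):
        x0, y0, x1, y1 = bounds
        bx0, by0, bx1, by1 = self.bounds
        eps = 1e-6
        return bx0 <= x0 + eps and by0 <= y0 + eps and bx1 >= x1 - eps and by1 >= y1 - eps

    def population_in(self, xmin, ymin, xmax, ymax):
        ny, nx = self.values.shape
        cs = self.cellsize
        xedges = self.xll + cs * np.arange(nx + 1)
        yedges = self.yll + cs * np.arange(ny + 1)  # south to north
        wx = np.clip(np.minimum(xmax, xedges[1:]) - np.maximum(xmin, xedges[:-1]),
                     0.0, None) / cs
        wy = np.clip(np.minimum(ymax, yedges[1:]) - np.maximum(ymin, yedges[:-1]),
                     0.0, None) / cs
        # values row 0 is northernmost: flip y weights
        return float(np.einsum("y,x,yx->", wy[::-1], wx, self.values))

    @classmethod
    def read_ascii(cls, path) -> "RasterPopulation":
        header = {}
        with open(path) as fh:
            lines = fh.readlines()
        nh = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                nh += 1
            else:
                break
        values = np.loadtxt(lines[nh:])
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value")
        if nodata is not None:
            values = np.where(values == nodata, 0.0, values)
        return cls(values, header["xllcorner"], header["yllcorner"], header["cellsize"])

    def write_ascii(self, path):
        ny, nx = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {self.xll!r}\nyllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\nNODATA_value -9999\n")
            for row in self.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


class PolygonPopulation(PopulationSurface):
    """Population as a table of polygons with a population attribute."""

    def __init__(self, polygons: Sequence[BaseGeometry], populations: Sequence[float]):
        self.polygons = list(polygons)
        self.populations = [float(p) for p in populations]

    def covers(self, bounds):
        if not self.polygons:
            return False
        xs0, ys0, xs1, ys1 = zip(*(g.bounds for g in self.polygons))
        x0, y0, x1, y1 = bounds
        return min(xs0) <= x0 and min(ys0) <= y0 and max(xs1) >= x1 and max(ys1) >= y1

    def population_in(self, xmin, ymin, xmax, ymax):
        cell = box(xmin, ymin, xmax, ymax)
        total = 0.0
        for g, p in zip(self.polygons, self.populations):
            if g.area > 0 and g.intersects(cell):
                total += p * g.intersection(cell).area / g.area
        return total

    @classmethod
    def read_geojson(cls, path, attribute: str = "population") -> "PolygonPopulation":
        with open(path) as fh:
            gj = json.load(fh)
        polys, pops = [], []
        for feat in gj.get("features", []):
            polys.append(shape(feat["geometry"]))
            props = {k.lower(): v for k, v in (feat.get("properties") or {}).items()}
            pops.append(float(props.get(attribute.lower(), 0.0)))
        return cls(polys, pops)


# --- grid construction -----------------------------------------------------------

def build_static_grid(population_surface: PopulationSurface,
                      grid_config: GridConfig) -> VariableGrid:
    """Build the population-refined static grid.

    A cell is recursively split into ``divisors[level]**2`` children while the
    population in its footprint exceeds ``pop_threshold`` and it is above the
    minimum size.  Refinement acts on the shared horizontal footprint; layers
    above the cap height always use the base footprint.
    """
    cfg = grid_config
    if not population_surface.covers(cfg.domain_bounds):
        raise GridError("population surface does not cover the model domain")
    su = cfg.size_units
    unit = cfg.unit_size
    x0, y0 = cfg.domain_bounds[0], cfg.domain_bounds[1]
    max_level = cfg.max_level
    leaves: list[tuple[int, int, int]] = []
    pops: list[float] = []
    stack = [(0, i * su[0], j * su[0])
             for j in range(cfg.ny_base) for i in range(cfg.nx_base)]
    while stack:
        lvl, xu, yu = stack.pop()
        s = su[lvl]
        pop = population_surface.population_in(
            x0 + xu * unit, y0 + yu * unit,
            x0 + (xu + s) * unit, y0 + (yu + s) * unit)
        if lvl < max_level and pop > cfg.pop_threshold:
            d = cfg.divisors[lvl]
            cs = su[lvl + 1]
            for cj in range(d):
                for ci in range(d):
                    stack.append((lvl + 1, xu + ci * cs, yu + cj * cs))
        else:
            leaves.append((lvl, xu, yu))
            pops.append(pop)
    return VariableGrid(cfg, leaves, pops)


@dataclass(frozen=True)
class RefineThresholds:
    """Thresholds for dynamic refinement.

    The refinement score of a footprint is (population density, persons m^-2)
    x (max absolute total-PM2.5 difference to any horizontal neighbor,
    ug m^-3), evaluated on the ground layer.  Footprints with score above
    ``split`` are split; sibling groups all below ``merge`` are merged.
    """

    split: float
    merge: float | None = None

    def __post_init__(self):
        if self.split <= 0:
            raise GridError("split threshold must be positive")
        if self.merge is not None and self.merge <= 0:
            raise GridError("merge threshold must be positive")

    @property
    def merge_value(self) -> float:
        return self.merge if self.merge is not None else self.split / 4.0


def refinement_scores(grid: VariableGrid, total_pm: np.ndarray) -> np.ndarray:
    """Per-ground-cell score: population density x max |neighbor PM difference|."""
    topo = grid.face_topology()
    scores = np.zeros(grid.n_cells)
    for i in grid.ground_cells:
        gmax = 0.0
        for f in ("W", "E", "S", "N"):
            for j, _ in topo[i][f]:
                gmax = max(gmax, abs(float(total_pm[j] - total_pm[i])))
        dens = grid.population[i] / (grid.dx[i] * grid.dy[i])
        scores[i] = dens * gmax
    return scores


def refine_dynamic(grid: VariableGrid, concentrations: np.ndarray,
                   population_surface: PopulationSurface,
                   thresholds: RefineThresholds,
                   total_pm: np.ndarray | None = None
                   ) -> tuple[VariableGrid, np.ndarray]:
    """Split/merge footprints by refinement score; conservatively remap.

    ``concentrations`` is (n_cells, n_species); ``total_pm`` defaults to the
    concentration sum over species.  Returns the new grid and the
    mass-conservatively interpolated concentrations.
    """
    conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if conc.shape[0] != grid.n_cells:
        conc = conc.T
    if total_pm is None:
        total_pm = conc.sum(axis=1)
    scores = refinement_scores(grid, total_pm)
    cfg = grid.config
    su = cfg.size_units
    max_level = cfg.max_level

    # ground-cell score per footprint leaf
    leaf_score = {}
    for i in grid.ground_cells:
        leaf_score[(int(grid.level[i]), int(grid.x0u[i]), int(grid.y0u[i]))] = scores[i]

    new_leaves: list[tuple[int, int, int]] = []
    split_set = set()
    for leaf in grid.footprint_leaves:
        lvl, xu, yu = leaf
        if lvl < max_level and leaf_score.get(leaf, 0.0) > thresholds.split:
            d = cfg.divisors[lvl]
            cs = su[lvl + 1]
            split_set.add(leaf)
            for cj in range(d):
                for ci in range(d):
                    new_leaves.append((lvl + 1, xu + ci * cs, yu + cj * cs))
        else:
            new_leaves.append(leaf)

    # merge complete sibling groups whose members all score below the merge
    # threshold -- but never coarsen below the population-only baseline (a
    # parent whose population would re-split it under the static rule stays
    # split)
    merge_thr = thresholds.merge_value
    by_parent: dict[tuple[int, int, int], list[tuple[int, int, int]]] = {}
    for leaf in new_leaves:
        lvl, xu, yu = leaf
        if lvl == 0:
            continue
        ps = su[lvl - 1]
        by_parent.setdefault((lvl - 1, (xu // ps) * ps, (yu // ps) * ps), []).append(leaf)
    merged_children = set()
    merged_parents = []
    for parent, children in by_parent.items():
        d = cfg.divisors[parent[0]]
        if len(children) != d * d:
            continue
        if parent in split_set:
            continue
        plvl, pxu, pyu = parent
        parent_pop = population_surface.population_in(
            cfg.domain_bounds[0] + pxu * cfg.unit_size,
            cfg.domain_bounds[1] + pyu * cfg.unit_size,
            cfg.domain_bounds[0] + (pxu + su[plvl]) * cfg.unit_size,
            cfg.domain_bounds[1] + (pyu + su[plvl]) * cfg.unit_size)
        if parent_pop > cfg.pop_threshold:
            continue
        if all(leaf_score.get(c, 0.0) < merge_thr for c in children):
            merged_children.update(children)
            merged_parents.append(parent)
    final_leaves = [lf for lf in new_leaves if lf not in merged_children] + merged_parents
    final_pop = [population_surface.population_in(
        cfg.domain_bounds[0] + xu * cfg.unit_size,
        cfg.domain_bounds[1] + yu * cfg.unit_size,
        cfg.domain_bounds[0] + (xu + su[lvl]) * cfg.unit_size,
        cfg.domain_bounds[1] + (yu + su[lvl]) * cfg.unit_size)
        for (lvl, xu, yu) in final_leaves]
    new_grid = VariableGrid(cfg, final_leaves, final_pop)
    new_conc = interpolate_conservative(grid, new_grid, conc)
    return new_grid, new_conc


def interpolate_conservative(old: VariableGrid, new: VariableGrid,
                             conc: np.ndarray) -> np.ndarray:
    """Volume-weighted remap between nested grids; preserves total mass."""
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    out = np.zeros((new.n_cells, conc.shape[1]))
    su0 = old.config.size_units[0]
    for L in range(old.n_layers):
        bucket: dict[tuple[int, int], list[int]] = {}
        for j in old.layer_cells(L):
            key = (int(old.x0u[j]) // su0, int(old.y0u[j]) // su0)
            bucket.setdefault(key, []).append(int(j))
        for i in new.layer_cells(L):
            x0, y0, s = int(new.x0u[i]), int(new.y0u[i]), int(new.szu[i])
            acc = np.zeros(conc.shape[1])
            keys = {(bx, by)
                    for bx in range(x0 // su0, (x0 + s - 1) // su0 + 1)
                    for by in range(y0 // su0, (y0 + s - 1) // su0 + 1)}
            for key in keys:
                for j in bucket.get(key, ()):
                    ox = (min(x0 + s, int(old.x0u[j] + old.szu[j]))
                          - max(x0, int(old.x0u[j])))
                    oy = (min(y0 + s, int(old.y0u[j] + old.szu[j]))
                          - max(y0, int(old.y0u[j])))
                    if ox > 0 and oy > 0:
                        acc += conc[j] * (ox * oy)
            out[i] = acc / (s * s)
    return out


# --- I/O -------------------------------------------------------------------------

def grid_to_geojson(grid: VariableGrid, values: dict[str, np.ndarray] | None = None,
                    layer: int | None = None) -> dict:
    """Export cells (optionally one layer) as a GeoJSON FeatureCollection."""
    feats = []
    ids = grid.layer_cells(layer) if layer is not None else range(grid.n_cells)
    for i in ids:
        props = {
            "cell_id": int(i),
            "layer": int(grid.layer[i]),
            "level": int(grid.level[i]),
            "x0u": int(grid.x0u[i]),
            "y0u": int(grid.y0u[i]),
            "dz": float(grid.dz[i]),
            "population": float(grid.population[i]),
        }
        if values:
            for k, v in values.items():
                props[k] = float(v[i])
        feats.append({
            "type": "Feature",
            "geometry": mapping(box(grid.xmin[i], grid.ymin[i],
                                    grid.xmax[i], grid.ymax[i])),
            "properties": props,
        })
    out = {"type": "FeatureCollection", "features": feats}
    if grid.crs:
        out["crs_descriptor"] = grid.crs
    return out


def grid_to_arrays(grid: VariableGrid) -> dict:
    """Cell-table arrays for the gridded archive (exact reconstruction)."""
    return {
        "cell_level": grid.level.copy(),
        "cell_x0u": grid.x0u.copy(),
        "cell_y0u": grid.y0u.copy(),
        "cell_layer": grid.layer.copy(),
        "cell_population": grid.population.copy(),
    }


def grid_from_arrays(config: GridConfig, arrays: dict) -> VariableGrid:
    ground = arrays["cell_layer"] == 0
    leaves = list(zip(arrays["cell_level"][ground].tolist(),
                      arrays["cell_x0u"][ground].tolist(),
                      arrays["cell_y0u"][ground].tolist()))
    pops = arrays["cell_population"][ground].tolist()
    return VariableGrid(config, leaves, pops)
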