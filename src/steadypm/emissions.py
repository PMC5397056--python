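"""Emission-change scenarios: ingestion, plume rise, and gridding.

Scenarios are vector features (points, lines, polygons) carrying *changes*
in annual emissions of the five emitted species (VOC, NOx, NH3, SOx, primary
PM2.5); amounts may be negative for reduction scenarios.  Elevated sources
carry stack attributes from which a Briggs-type plume rise determines the
vertical injection layer.  Gridding splits each record's mass over the cells
of its injection layer by area weighting and converts annual totals to
volumetric rates (ug m^-3 s^-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import shape, mapping
from shapely.geometry.base import BaseGeometry

from . import grid as gridmod
from .fields import CellFields, GRAVITY, SECONDS_PER_YEAR
from .grid import VariableGrid, area_weights

EMITTED_SPECIES = ("VOC", "NOx", "NH3", "SOx", "PM2_5")
_STACK_KEYS = ("height", "diam", "temp", "velocity")

#: grams per emission unit
UNIT_GRAMS = {
    "short_tons": 907184.74,
    "tonnes": 1.0e6,
    "kg": 1.0e3,
}

#: emitted gas mass -> tracked particle-equivalent mass (molar ratios).
#: Gas precursors are tracked as the mass of the particle they can form
#: (SO2 as sulfate, NO2 as nitrate, NH3 as ammonium, VOC as SOA-potential
#: mass), so chemistry and partitioning conserve tracked mass.
MOIETY_FACTOR = {
    "SOx": 96.0626 / 64.0638,
    "NOx": 62.0049 / 46.0055,
    "NH3": 18.0385 / 17.0305,
    "VOC": 1.0,       # SOA yield; configurable at gridding
    "PM2_5": 1.0,
}


class EmissionsError(ValueError):
    pass


@dataclass(frozen=True)
class StackParams:
    height: float      # m
    diam: float        # m
    temp: float        # exit temperature, K
    velocity: float    # exit velocity, m s^-1

    def __post_init__(self):
        if self.diam <= 0 or self.velocity < 0:
            raise EmissionsError("stack diameter must be positive and velocity >= 0")


@dataclass
class EmissionRecord:
    """One vector feature: geometry + annual emission changes (+ stack)."""

    geometry: BaseGeometry
    amounts: dict[str, float]
    stack: StackParams | None = None

    def __post_init__(self):
        amounts = {s: 0.0 for s in EMITTED_SPECIES}
        for k, v in self.amounts.items():
            key = _canonical_species(k)
            if key is not None:
                amounts[key] = float(v)
        self.amounts = amounts
        if not all(np.isfinite(list(amounts.values()))):
            raise EmissionsError("emission amounts must be finite")


def _canonical_species(name: str) -> str | None:
    low = name.strip().lower().replace(".", "_").replace("-", "_")
    for s in EMITTED_SPECIES:
        if low == s.lower():
            return s
    if low in ("pm25", "pm2_5", "pm_2_5"):
        return "PM2_5"
    return None


# ---------------------------------------------------------------------------
# I/O (GeoJSON)
# ---------------------------------------------------------------------------

def read_emissions(paths, grid_crs: str | None = None) -> list[EmissionRecord]:
    """Read emission records from one or more GeoJSON files.

    Species attributes are matched case-insensitively; missing species
    default to 0.  Stack attributes must be all present or all absent.  If
    both the file and the grid declare a projection, they must agree (no
    reprojection is performed).
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    records: list[EmissionRecord] = []
    for path in paths:
        try:
            with open(path) as fh:
                gj = json.load(fh)
        except (OSError, json.JSONDecodeError) as e:
            raise IOError(f"cannot parse emissions file {path}: {e}") from e
        file_crs = gj.get("crs_descriptor")
        if file_crs and grid_crs and file_crs != grid_crs:
            raise EmissionsError(
                f"emissions file CRS {file_crs!r} != grid CRS {grid_crs!r}; "
                "reproject the inputs before running")
        for feat in gj.get("features", []):
            geom = shape(feat["geometry"])
            if geom.geom_type not in ("Point", "MultiPoint", "LineString",
                                      "MultiLineString", "Polygon", "MultiPolygon"):
                raise EmissionsError(f"unsupported geometry type {geom.geom_type}")
            props = {k.lower(): v for k, v in (feat.get("properties") or {}).items()}
            amounts = {}
            for key in EMITTED_SPECIES:
                for pk, pv in props.items():
                    if _canonical_species(pk) == key:
                        amounts[key] = float(pv)
            stack_vals = [props.get(k) for k in _STACK_KEYS]
            present = [v is not None for v in stack_vals]
            if any(present) and not all(present):
                raise EmissionsError(
                    f"stack attributes must be all present or all absent, got {props}")
            stack = StackParams(*(float(v) for v in stack_vals)) if all(present) else None
            records.append(EmissionRecord(geom, amounts, stack))
    return records


def write_emissions(records, path, crs: str | None = None):
    feats = []
    for rec in records:
        props = dict(rec.amounts)
        if rec.stack is not None:
            props.update(height=rec.stack.height, diam=rec.stack.diam,
                         temp=rec.stack.temp, velocity=rec.stack.velocity)
        feats.append({"type": "Feature", "geometry": mapping(rec.geometry),
                      "properties": props})
    out = {"type": "FeatureCollection", "features": feats}
    if crs:
        out["crs_descriptor"] = crs
    with open(path, "w") as fh:
        json.dump(out, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# plume rise
# ---------------------------------------------------------------------------

def briggs_rise(stack: StackParams, wind_inv: float, wind_m13: float,
                temperature: float, s1: float, unstable: bool) -> float:
    """Briggs final plume rise (m) from pre-averaged windspeed moments.

    Buoyancy flux F = g v d^2 (Ts - Ta) / (4 Ts); momentum flux
    Fm = v^2 d^2 Ta / (4 Ts).  Stable branches use the mean of u^-1/3 with
    the stability parameter s1 = (g/theta) dtheta/dz; neutral/unstable
    branches use the mean of u^-1.  The larger of the buoyant and momentum
    rises is returned.
    """
    ts = max(stack.temp, 1.0)
    ta = temperature
    fb = GRAVITY * stack.velocity * stack.diam ** 2 * max(ts - ta, 0.0) / (4.0 * ts)
    fm = stack.velocity ** 2 * stack.diam ** 2 * ta / (4.0 * ts)
    if unstable:
        if fb > 0:
            dh_b = (38.71 * fb ** 0.6 if fb >= 55.0 else 21.425 * fb ** 0.75) * wind_inv
        else:
            dh_b = 0.0
        dh_m = 3.0 * stack.diam * stack.velocity * wind_inv
    else:
        s = max(s1, 1e-6)
        dh_b = 2.6 * (fb / s) ** (1.0 / 3.0) * wind_m13 if fb > 0 else 0.0
        dh_m = 1.5 * (fm / np.sqrt(s)) ** (1.0 / 3.0) * wind_m13 if fm > 0 else 0.0
    return max(dh_b, dh_m)


def plume_rise(record: EmissionRecord, grid: VariableGrid,
               fields: CellFields) -> int:
    """Vertical injection layer for a record; ground-level records get 0.

    For elevated sources the effective height is stack height plus Briggs
    rise computed from the annual-average plume parameters of the column at
    the geometry centroid; the layer containing that height is returned,
    capped at the top layer.
    """
    if record.stack is None:
        return 0
    c = record.geometry.centroid
    i = grid.locate(c.x, c.y, layer=0)
    if i is None:
        # source centroid outside the domain: fall back to domain-median column
        i = int(grid.ground_cells[len(grid.ground_cells) // 2])
    dh = briggs_rise(record.stack,
                     wind_inv=float(fields.plume_wind_inv[i]),
                     wind_m13=float(fields.plume_wind_m13[i]),
                     temperature=float(fields.plume_T[i]),
                     s1=float(fields.plume_s1[i]),
                     unstable=bool(fields.plume_unstable[i]))
    h_eff = record.stack.height + dh
    tops = grid.layer_tops
    for L, top in enumerate(tops):
        if h_eff < top:
            return L
    return len(tops) - 1


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

def grid_emissions(records, grid: VariableGrid, fields: CellFields,
                   units: str = "short_tons", soa_yield: float = 1.0,
                   n_species: int = 9) -> np.ndarray:
    """Convert records to a per-cell volumetric source field (ug m^-3 s^-1).

    Each record's annual amounts are split over the cells of its injection
    layer by area weighting, converted from annual mass to ug s^-1 (with the
    gas -> particle-equivalent moiety factors), and divided by cell volume.
    Returns an (n_cells, n_species) array in the solver's species order.
    """
    from .solver import SPECIES_INDEX  # local import to avoid a cycle

    if units not in UNIT_GRAMS:
        raise EmissionsError(f"unknown unit {units!r}; choose from {set(UNIT_GRAMS)}")
    ug_per_unit = UNIT_GRAMS[units] * 1e6
    emitted_to_model = {"PM2_5": "PRIM", "VOC": "VOC", "SOx": "SOX",
                        "NOx": "NOX", "NH3": "NH3"}
    source = np.zeros((grid.n_cells, n_species))
    vol = grid.volume
    for rec in records:
        layer = plume_rise(rec, grid, fields)
        weights = area_weights(rec.geometry, grid, layer=layer)
        if not weights:
            continue
        for sp, amount in rec.amounts.items():
            if amount == 0.0:
                continue
            factor = soa_yield if sp == "VOC" else MOIETY_FACTOR[sp]
            rate = amount * ug_per_unit * factor / SECONDS_PER_YEAR  # ug s^-1
            col = SPECIES_INDEX[emitted_to_model[sp]]
            for i, w in weights:
                source[i, col] += rate * w / vol[i]
    return source


def source_mass_rate(source: np.ndarray, grid: VariableGrid) -> np.ndarray:
    """Total emitted mass rate per species (ug s^-1) of a source field."""
    return source.T @ grid.volume
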