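"""Steady-state reaction-advection-diffusion solver.

Marginal concentration changes of nine species are advanced through
CFL-limited pseudo-time steps -- emissions, upwind mean advection,
symmetric deviation advection, local/nonlocal mixing, first-order sulfur
chemistry, dry and wet deposition, and (last, each step) instantaneous
gas/particle partitioning -- until the population-weighted total PM2.5
change converges.  All operators are linear in the concentrations, so the
steady solution is linear in emissions; marginal changes may be negative.

Mean advection is applied in flux form: every interface flux debits the
upwind cell and credits the downwind cell, which conserves mass across
variable-resolution interfaces.  Face-normal parameters (winds, deviations,
K) are stored on each cell's west/south/bottom faces; a cell's east, north
and top faces on the domain boundary reuse the cell's own stored values.
Boundary conditions: zero concentration change outside the lateral and top
edges, impermeable ground (deposition handles surface removal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fields import CellFields, settling_velocity
from .grid import VariableGrid

SPECIES = ("PRIM", "VOC", "SOA", "SOX", "PSO4", "NOX", "PNO3", "NH3", "PNH4")
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

PARTICLE_SPECIES = ("PRIM", "SOA", "PSO4", "PNO3", "PNH4")
GAS_SPECIES = ("VOC", "SOX", "NOX", "NH3")
#: reversible gas/particle pairs and their partitioning-fraction field
PARTITION_PAIRS = (("NOX", "PNO3", "fp_NO3"),
                   ("NH3", "PNH4", "fp_NH4"),
                   ("VOC", "SOA", "fp_org"))
TOTAL_PM_SPECIES = ("PRIM", "PSO4", "PNO3", "PNH4", "SOA")

WIND_FLOOR = 1e-3  # m s^-1, keeps the CFL time step finite in a calm archive


class NumericalBlowupError(RuntimeError):
    pass


def cfl_timestep(grid: VariableGrid, fields: CellFields, cmax: float = 1.0) -> float:
    """Courant-limited time step (s).

    dt = cmax / (3 max_i max((|U|+|Udev|)/dx, (|V|+|Vdev|)/dy, |W|/dz)),
    with a calm-wind floor on the wind magnitudes so dt stays finite.
    """
    if not (0.0 < cmax <= 1.0):
        raise ValueError("cmax must be in (0, 1]")
    rx = (np.abs(fields.U) + fields.Udev) / grid.dx
    ry = (np.abs(fields.V) + fields.Vdev) / grid.dy
    rz = np.abs(fields.W) / grid.dz
    floor = WIND_FLOOR / grid.dx
    ratio = np.max(np.maximum.reduce([rx, ry, rz, floor]))
    return float(cmax / (3.0 * ratio))


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

def _face_list(grid: VariableGrid):
    """Unique interior faces as (minus, plus, axis, area); axis in {x, y, z}.

    The face geometrically belongs to the plus-side cell (its W, S, or B
    face), whose stored face-normal parameters apply to the whole face.
    """
    topo = grid.face_topology()
    faces = []
    for i in range(grid.n_cells):
        for j, f in topo[i]["W"]:
            faces.append((j, i, "x", f * grid.dy[i] * grid.dz[i]))
        for j, f in topo[i]["S"]:
            faces.append((j, i, "y", f * grid.dx[i] * grid.dz[i]))
        for j, f in topo[i]["B"]:
            faces.append((j, i, "z", f * grid.dx[i] * grid.dy[i]))
    return faces


def _boundary_faces(grid: VariableGrid):
    """Domain-boundary faces as (cell, side, area); side in W/E/S/N/top."""
    topo = grid.face_topology()
    out = []
    for i in range(grid.n_cells):
        if not topo[i]["W"]:
            out.append((i, "W", grid.dy[i] * grid.dz[i]))
        if not topo[i]["E"]:
            out.append((i, "E", grid.dy[i] * grid.dz[i]))
        if not topo[i]["S"]:
            out.append((i, "S", grid.dx[i] * grid.dz[i]))
        if not topo[i]["N"]:
            out.append((i, "N", grid.dx[i] * grid.dz[i]))
        if grid.layer[i] == grid.n_layers - 1:
            out.append((i, "top", grid.dx[i] * grid.dy[i]))
    return out


class _COO:
    def __init__(self, n):
        self.n = n
        self.rows, self.cols, self.vals = [], [], []

    def add(self, r, c, v):
        self.rows.append(r)
        self.cols.append(c)
        self.vals.append(v)

    def tocsr(self):
        return sp.coo_matrix((self.vals, (self.rows, self.cols)),
                             shape=(self.n, self.n)).tocsr()


def assemble_advection(grid: VariableGrid, fields: CellFields,
                       sealed: bool = False) -> sp.csr_matrix:
    """Upwind mean-advection operator (s^-1), flux form."""
    vol = grid.volume
    m = _COO(grid.n_cells)
    wind = {"x": fields.U, "y": fields.V, "z": fields.W}
    for jm, ip, axis, area in _face_list(grid):
        u = float(wind[axis][ip])
        if u == 0.0:
            continue
        up = jm if u > 0 else ip
        flux = abs(u) * area  # mass rate per unit concentration, out of `up`
        down = ip if u > 0 else jm
        m.add(down, up, flux / vol[down])
        m.add(up, up, -flux / vol[up])
    if not sealed:
        for i, side, area in _boundary_faces(grid):
            if side in ("W", "E"):
                u = float(fields.U[i])
            elif side in ("S", "N"):
                u = float(fields.V[i])
            else:
                u = float(fields.W[i])
            outflow = (u < 0) if side in ("W", "S") else (u > 0)
            if outflow:
                m.add(i, i, -abs(u) * area / vol[i])
            # inflow carries zero concentration change: no term
    return m.tocsr()


def assemble_deviation(grid: VariableGrid, fields: CellFields,
                       sealed: bool = False) -> sp.csr_matrix:
    """Symmetric deviation-advection operator (s^-1); horizontal faces only."""
    vol = grid.volume
    m = _COO(grid.n_cells)
    dev = {"x": fields.Udev, "y": fields.Vdev}
    for jm, ip, axis, area in _face_list(grid):
        if axis == "z":
            continue
        ud = float(dev[axis][ip])
        if ud == 0.0:
            continue
        ex = ud * area
        m.add(ip, jm, ex / vol[ip])
        m.add(ip, ip, -ex / vol[ip])
        m.add(jm, ip, ex / vol[jm])
        m.add(jm, jm, -ex / vol[jm])
    if not sealed:
        for i, side, area in _boundary_faces(grid):
            if side in ("W", "E"):
                ud = float(fields.Udev[i])
            elif side in ("S", "N"):
                ud = float(fields.Vdev[i])
            else:
                continue
            m.add(i, i, -ud * area / vol[i])
    return m.tocsr()


def assemble_mixing(grid: VariableGrid, fields: CellFields,
                    sealed: bool = False) -> sp.csr_matrix:
    """Local (K) plus nonlocal (M2u/M2d) mixing operator (s^-1)."""
    vol = grid.volume
    m = _COO(grid.n_cells)
    kcoef = {"x": fields.Kxx, "y": fields.Kyy, "z": fields.Kzz}
    size = {"x": grid.dx, "y": grid.dy, "z": grid.dz}
    for jm, ip, axis, area in _face_list(grid):
        k = float(kcoef[axis][ip])
        if k == 0.0:
            continue
        coef = 2.0 * k / (size[axis][ip] + size[axis][jm]) * area
        m.add(ip, jm, coef / vol[ip])
        m.add(ip, ip, -coef / vol[ip])
        m.add(jm, ip, coef / vol[jm])
        m.add(jm, jm, -coef / vol[jm])
    if not sealed:
        for i, side, area in _boundary_faces(grid):
            if side in ("W", "E"):
                k, sz = float(fields.Kxx[i]), grid.dx[i]
            elif side in ("S", "N"):
                k, sz = float(fields.Kyy[i]), grid.dy[i]
            else:
                k, sz = float(fields.Kzz[i]), grid.dz[i]
            if k > 0:
                m.add(i, i, -(2.0 * k / (2.0 * sz)) * area / vol[i])
    # nonlocal convective transport within the boundary layer
    topo = grid.face_topology()
    for i in range(grid.n_cells):
        if grid.layer[i] == 0:
            continue
        m2u = float(fields.M2u[i])
        if m2u > 0:
            for g, fg in grid.ground_below(i):
                m.add(i, g, m2u * fg)
                m.add(g, g, -m2u * fg * vol[i] / vol[g])
        m2d = float(fields.M2d[i])
        if m2d > 0:
            m.add(i, i, -m2d)
            for b, fb in topo[i]["B"]:
                m.add(b, i, m2d * fb * vol[i] / vol[b])
    return m.tocsr()


def deposition_rates(grid: VariableGrid, fields: CellFields) -> np.ndarray:
    """Per-cell, per-species first-order removal rates (s^-1): dry + wet.

    Dry deposition acts only in ground cells, with velocity
    v_dd = (ra + rb + rc)^-1 for gases and v_dd = vs + (ra + rb + rc_p)^-1
    for particles (vs the gravitational settling velocity), scaled by the
    ground-layer thickness.  Wet scavenging acts in every cell with the
    class-appropriate rate (particle / SO2 / other gas).
    """
    n = grid.n_cells
    rates = np.zeros((n, N_SPECIES))
    for spn in PARTICLE_SPECIES:
        rates[:, SPECIES_INDEX[spn]] += fields.rwd_particle
    rates[:, SPECIES_INDEX["SOX"]] += fields.rwd_SO2
    for spn in ("VOC", "NOX", "NH3"):
        rates[:, SPECIES_INDEX[spn]] += fields.rwd_othergas
    ground = grid.layer == 0
    with np.errstate(divide="ignore"):
        vdd_gas = np.where(ground, 1.0 / (fields.ra + fields.rb + fields.rc_gas), 0.0)
        vdd_part = np.where(
            ground,
            settling_velocity() + 1.0 / (fields.ra + fields.rb + fields.rc_particle),
            0.0)
    for spn in GAS_SPECIES:
        rates[:, SPECIES_INDEX[spn]] += np.where(ground, vdd_gas / grid.dz, 0.0)
    for spn in PARTICLE_SPECIES:
        rates[:, SPECIES_INDEX[spn]] += np.where(ground, vdd_part / grid.dz, 0.0)
    return rates


def dry_deposition_rates(grid: VariableGrid, fields: CellFields) -> np.ndarray:
    """Dry-only removal rates (s^-1), for diagnostics and operator tests."""
    wet = wet_deposition_rates(grid, fields)
    return deposition_rates(grid, fields) - wet


def wet_deposition_rates(grid: VariableGrid, fields: CellFields) -> np.ndarray:
    n = grid.n_cells
    rates = np.zeros((n, N_SPECIES))
    for spn in PARTICLE_SPECIES:
        rates[:, SPECIES_INDEX[spn]] += fields.rwd_particle
    rates[:, SPECIES_INDEX["SOX"]] += fields.rwd_SO2
    for spn in ("VOC", "NOX", "NH3"):
        rates[:, SPECIES_INDEX[spn]] += fields.rwd_othergas
    return rates


# ---------------------------------------------------------------------------
# solver state and operators
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceConfig:
    """Steady-state detection: the relative change of the population-weighted
    total-PM2.5 mean over a ``check_every``-iteration window must drop below
    ``tol`` (with an absolute floor for near-zero scenarios)."""

    tol: float = 1e-6
    check_every: int = 100
    max_iter: int = 1_000_000
    abs_floor: float = 1e-12

    def __post_init__(self):
        if self.tol <= 0 or self.check_every < 1 or self.max_iter < 1:
            raise ValueError("invalid convergence configuration")


@dataclass
class SolverState:
    grid: VariableGrid
    fields: CellFields
    source: np.ndarray              # (n, 9) ug m^-3 s^-1
    conc: np.ndarray                # (n, 9) ug m^-3
    dt: float
    cmax: float = 1.0
    iteration: int = 0
    sealed: bool = False
    history: list = field(default_factory=list)
    _A_adv: sp.csr_matrix | None = None
    _A_dev: sp.csr_matrix | None = None
    _A_mix: sp.csr_matrix | None = None
    _T: sp.csr_matrix | None = None
    _R_dry: np.ndarray | None = None
    _R_wet: np.ndarray | None = None

    @classmethod
    def create(cls, grid: VariableGrid, fields: CellFields,
               source: np.ndarray | None = None, cmax: float = 1.0,
               conc: np.ndarray | None = None, sealed: bool = False) -> "SolverState":
        n = grid.n_cells
        if source is None:
            source = np.zeros((n, N_SPECIES))
        if conc is None:
            conc = np.zeros((n, N_SPECIES))
        dt = cfl_timestep(grid, fields, cmax)
        st = cls(grid=grid, fields=fields, source=np.asarray(source, float),
                 conc=np.asarray(conc, float).copy(), dt=dt, cmax=cmax,
                 sealed=sealed)
        st._A_adv = assemble_advection(grid, fields, sealed)
        st._A_dev = assemble_deviation(grid, fields, sealed)
        st._A_mix = assemble_mixing(grid, fields, sealed)
        st._T = (st._A_adv + st._A_dev + st._A_mix).tocsr()
        st._R_dry = dry_deposition_rates(grid, fields)
        st._R_wet = wet_deposition_rates(grid, fields)
        # The advective CFL step alone does not bound the explicit-Euler
        # stability of the diffusive/mixing/removal terms; cap dt by a
        # Gershgorin bound on the total per-cell loss rate (so the wind-based
        # CFL condition is still satisfied, with room to spare if mixing or
        # removal is the faster process).
        loss = (-st._T.diagonal()
                + (st._R_dry + st._R_wet).max(axis=1) + fields.kS)
        max_loss = float(np.max(loss))
        if max_loss > 0:
            st.dt = min(st.dt, cmax * 0.9 / max_loss)
        return st


def advect_mean(state: SolverState) -> np.ndarray:
    """Upwind mean-advection increments (ug m^-3) for one time step."""
    return state.dt * (state._A_adv @ state.conc)


def advect_deviation(state: SolverState) -> np.ndarray:
    """Symmetric deviation-advection increments for one time step."""
    return state.dt * (state._A_dev @ state.conc)


def mix(state: SolverState) -> np.ndarray:
    """Local/nonlocal mixing increments for one time step."""
    return state.dt * (state._A_mix @ state.conc)


def chem_sulfur(state: SolverState) -> np.ndarray:
    """Irreversible first-order SO2 -> particulate sulfate transfer.

    Gas-phase sulfur is tracked as sulfate-equivalent mass, so the transfer
    kS C dt leaves total tracked sulfur mass unchanged.
    """
    inc = np.zeros_like(state.conc)
    transfer = state.fields.kS * state.conc[:, SPECIES_INDEX["SOX"]] * state.dt
    inc[:, SPECIES_INDEX["SOX"]] = -transfer
    inc[:, SPECIES_INDEX["PSO4"]] = transfer
    return inc


def dry_deposition(state: SolverState) -> np.ndarray:
    return -state.conc * state._R_dry * state.dt


def wet_deposition(state: SolverState) -> np.ndarray:
    return -state.conc * state._R_wet * state.dt


def partition(conc: np.ndarray, fields: CellFields) -> np.ndarray:
    """Instantaneous gas/particle partitioning (applied last each step).

    For each reversible pair, the pair total T = Cg + Cp is redistributed as
    Cp = fp T, Cg = T - Cp, which conserves the pair total exactly.
    """
    out = conc.copy()
    for gas, part, fp_name in PARTITION_PAIRS:
        g, q = SPECIES_INDEX[gas], SPECIES_INDEX[part]
        fp = getattr(fields, fp_name)
        tot = conc[:, g] + conc[:, q]
        out[:, q] = fp * tot
        out[:, g] = tot - out[:, q]
    return out


def step(state: SolverState) -> SolverState:
    """Advance one pseudo-time step (in place; returns the state).

    All process increments are computed from the start-of-step
    concentrations and summed; partitioning is applied afterwards.
    """
    c = state.conc
    with np.errstate(invalid="ignore", over="ignore"):
        inc = state._T @ c
        inc += state.source
        inc -= c * (state._R_dry + state._R_wet)
        transfer = state.fields.kS * c[:, SPECIES_INDEX["SOX"]]
        inc[:, SPECIES_INDEX["SOX"]] -= transfer
        inc[:, SPECIES_INDEX["PSO4"]] += transfer
        c_new = c + state.dt * inc
        c_new = partition(c_new, state.fields)
    if not np.all(np.isfinite(c_new)):
        bad = np.argwhere(~np.isfinite(c_new))
        cell, spi = int(bad[0][0]), int(bad[0][1])
        op = _diagnose_blowup(state)
        raise NumericalBlowupError(
            f"non-finite concentration at iteration {state.iteration} in cell "
            f"{cell}, species {SPECIES[spi]} (first non-finite operator: {op})")
    state.conc = c_new
    state.iteration += 1
    return state


def _diagnose_blowup(state: SolverState) -> str:
    for name, fn in (("advect_mean", advect_mean),
                     ("advect_deviation", advect_deviation),
                     ("mix", mix), ("chem_sulfur", chem_sulfur),
                     ("dry_deposition", dry_deposition),
                     ("wet_deposition", wet_deposition)):
        if not np.all(np.isfinite(fn(state))):
            return name
    return "unidentified"


def total_pm25(conc: np.ndarray) -> np.ndarray:
    """Total PM2.5 change: primary + sulfate + nitrate + ammonium + SOA."""
    idx = [SPECIES_INDEX[s] for s in TOTAL_PM_SPECIES]
    return conc[:, idx].sum(axis=1)


def _monitor(state: SolverState) -> float:
    """Population-weighted (area fallback) ground-level mean total PM2.5."""
    g = state.grid.ground_cells
    w = state.grid.population[g]
    if w.sum() <= 0:
        w = state.grid.area[g]
    v = total_pm25(state.conc)[g]
    return float(np.sum(w * v) / np.sum(w))


def run_to_steady_state(state: SolverState,
                        convergence: ConvergenceConfig | None = None):
    """Iterate to steady state.

    Returns (concentrations, diagnostics); diagnostics carries the iteration
    count, a converged flag, and the convergence trace of the monitored
    population-weighted total-PM2.5 mean.
    """
    cc = convergence or ConvergenceConfig()
    q_prev = _monitor(state)
    state.history.append((state.iteration, q_prev))
    converged = False
    while state.iteration < cc.max_iter:
        for _ in range(cc.check_every):
            step(state)
        q = _monitor(state)
        state.history.append((state.iteration, q))
        if abs(q - q_prev) <= max(cc.tol * abs(q), cc.abs_floor):
            converged = True
            break
        q_prev = q
    diagnostics = {
        "iterations": state.iteration,
        "converged": converged,
        "dt": state.dt,
        "monitor": state.history[-1][1],
        "trace": list(state.history),
    }
    return state.conc, diagnostics
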