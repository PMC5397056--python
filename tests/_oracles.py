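"""Independent brute-force oracles for the solver equations.

Everything here is assembled by plain per-cell/per-face Python loops over
the :class:`GridCell` views, directly transcribing the discretized
equations (upwind advection in flux form, symmetric deviation advection,
local/nonlocal mixing, first-order chemistry and deposition, partitioning
as a projection).  It deliberately shares no assembly code with the
package's sparse-operator implementation so the two can check each other.
"""

import numpy as np

from steadypm.fields import settling_velocity
from steadypm.solver import (SPECIES_INDEX, N_SPECIES, PARTITION_PAIRS,
                             PARTICLE_SPECIES, GAS_SPECIES)


def ground_fractions(grid, i):
    """Ground cells under cell i with area fractions, by descending B faces."""
    topo = grid.face_topology()
    if grid.layer[i] == 0:
        return [(i, 1.0)]
    acc = {}
    frontier = {i: 1.0}
    layer = int(grid.layer[i])
    while layer > 0:
        nxt = {}
        for c, fc in frontier.items():
            for b, fb in topo[c]["B"]:
                # fb is the fraction of c's footprint shared with b; since
                # footprints only refine (never coarsen) going down, the
                # fractions compose multiplicatively
                nxt[b] = nxt.get(b, 0.0) + fc * fb
        frontier = nxt
        layer -= 1
    for c, fc in frontier.items():
        acc[c] = acc.get(c, 0.0) + fc
    return sorted(acc.items())


def transport_matrix(grid, fields, sealed=False):
    """Dense per-cell rate operator (s^-1): advection + deviation + mixing."""
    n = grid.n_cells
    M = np.zeros((n, n))
    topo = grid.face_topology()
    vol = grid.volume
    for i in range(n):
        dy, dx, dzi = grid.dy[i], grid.dx[i], grid.dz[i]
        # --- upwind mean advection (flux form) and deviation and local K ---
        face_specs = [
            ("W", lambda j: fields.U[i], lambda j: fields.Udev[i],
             lambda j: fields.Kxx[i], dy * dzi, grid.dx, +1),
            ("E", lambda j: fields.U[j], lambda j: fields.Udev[j],
             lambda j: fields.Kxx[j], dy * dzi, grid.dx, -1),
            ("S", lambda j: fields.V[i], lambda j: fields.Vdev[i],
             lambda j: fields.Kyy[i], dx * dzi, grid.dy, +1),
            ("N", lambda j: fields.V[j], lambda j: fields.Vdev[j],
             lambda j: fields.Kyy[j], dx * dzi, grid.dy, -1),
            ("B", lambda j: fields.W[i], lambda j: 0.0,
             lambda j: fields.Kzz[i], dx * dy, grid.dz, +1),
            ("A", lambda j: fields.W[j], lambda j: 0.0,
             lambda j: fields.Kzz[j], dx * dy, grid.dz, -1),
        ]
        for face, wind_of, dev_of, k_of, full_area, sizes, sign in face_specs:
            nbrs = topo[i][face]
            for j, f in nbrs:
                area = f * full_area
                u = wind_of(j)
                # +sign: positive wind blows from neighbor j into i
                if sign * u > 0:
                    M[i, j] += abs(u) * area / vol[i]
                elif sign * u < 0:
                    M[i, i] -= abs(u) * area / vol[i]
                ud = dev_of(j)
                if ud:
                    M[i, j] += ud * area / vol[i]
                    M[i, i] -= ud * area / vol[i]
                k = k_of(j)
                if k:
                    coef = 2.0 * k / (sizes[i] + sizes[j]) * area / vol[i]
                    M[i, j] += coef
                    M[i, i] -= coef
            if not nbrs and not sealed:
                # domain boundary: zero outside concentration change;
                # impermeable ground (no B term in layer 0)
                if face == "B":
                    continue
                if face == "A" and grid.layer[i] != grid.n_layers - 1:
                    continue
                u = wind_of(i)
                if sign * u < 0:          # outflow
                    M[i, i] -= abs(u) * full_area / vol[i]
                ud = dev_of(i)
                if ud:
                    M[i, i] -= ud * full_area / vol[i]
                k = k_of(i)
                if k:
                    M[i, i] -= 2.0 * k / (2 * sizes[i]) * full_area / vol[i]
        # --- nonlocal convective mixing ---
        if grid.layer[i] > 0:
            if fields.M2u[i] > 0:
                for g, fg in ground_fractions(grid, i):
                    M[i, g] += fields.M2u[i] * fg
                    M[g, g] -= fields.M2u[i] * fg * vol[i] / vol[g]
            if fields.M2d[i] > 0:
                M[i, i] -= fields.M2d[i]
                for b, fb in topo[i]["B"]:
                    M[b, i] += fields.M2d[i] * fb * vol[i] / vol[b]
    return M


def removal_rates(grid, fields):
    """Dense (n, n_species) first-order dry+wet removal rates (s^-1)."""
    n = grid.n_cells
    R = np.zeros((n, N_SPECIES))
    vs = settling_velocity()
    for i in range(n):
        for spn in PARTICLE_SPECIES:
            R[i, SPECIES_INDEX[spn]] += fields.rwd_particle[i]
        R[i, SPECIES_INDEX["SOX"]] += fields.rwd_SO2[i]
        for spn in ("VOC", "NOX", "NH3"):
            R[i, SPECIES_INDEX[spn]] += fields.rwd_othergas[i]
        if grid.layer[i] == 0:
            vdd_gas = 1.0 / (fields.ra[i] + fields.rb[i] + fields.rc_gas[i])
            vdd_part = vs + 1.0 / (fields.ra[i] + fields.rb[i]
                                   + fields.rc_particle[i])
            for spn in GAS_SPECIES:
                R[i, SPECIES_INDEX[spn]] += vdd_gas / grid.dz[i]
            for spn in PARTICLE_SPECIES:
                R[i, SPECIES_INDEX[spn]] += vdd_part / grid.dz[i]
    return R


def full_step_operator(grid, fields, dt, sealed=False):
    """Dense step map: C_next = A C + b_coeff, species-major (9n x 9n).

    Returns (A, P, Bsrc) with A = P (I + dt (T - R + chem)) and
    Bsrc = P dt (applied to the flattened source); the steady state solves
    (I - A) C = Bsrc S.
    """
    n = grid.n_cells
    N = n * N_SPECIES
    T = transport_matrix(grid, fields, sealed)
    R = removal_rates(grid, fields)
    M = np.zeros((N, N))
    for s in range(N_SPECIES):
        sl = slice(s * n, (s + 1) * n)
        M[sl, sl] = T
        M[sl, sl] -= np.diag(R[:, s])
    iS, iP = SPECIES_INDEX["SOX"], SPECIES_INDEX["PSO4"]
    for c in range(n):
        M[iS * n + c, iS * n + c] -= fields.kS[c]
        M[iP * n + c, iS * n + c] += fields.kS[c]
    P = np.eye(N)
    for gasn, partn, fpn in PARTITION_PAIRS:
        g, q = SPECIES_INDEX[gasn], SPECIES_INDEX[partn]
        fp = getattr(fields, fpn)
        for c in range(n):
            P[q * n + c, q * n + c] = fp[c]
            P[q * n + c, g * n + c] = fp[c]
            P[g * n + c, g * n + c] = 1.0 - fp[c]
            P[g * n + c, q * n + c] = 1.0 - fp[c]
    A = P @ (np.eye(N) + dt * M)
    return A, P, M


def steady_state_direct(grid, fields, dt, source, sealed=False):
    """Direct solve of the steady linear system; (n, 9) concentrations."""
    n = grid.n_cells
    A, P, _ = full_step_operator(grid, fields, dt, sealed)
    s_flat = np.concatenate([source[:, s] for s in range(N_SPECIES)])
    b = P @ (dt * s_flat)
    C = np.linalg.solve(np.eye(n * N_SPECIES) - A, b)
    return np.column_stack([C[s * n:(s + 1) * n] for s in range(N_SPECIES)])


def flatten(conc):
    return np.concatenate([conc[:, s] for s in range(conc.shape[1])])


def unflatten(vec, n):
    return np.column_stack([vec[s * n:(s + 1) * n] for s in range(N_SPECIES)])
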