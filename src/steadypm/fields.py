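"""Annual-average per-cell parameter archive and its synthesis.

The solver consumes only *annual-average* physical and chemical parameters:
face-normal winds and their absolute deviations, turbulent and convective
mixing coefficients, an SO2 oxidation rate constant, gas/particle
partitioning fractions, deposition parameters, and plume-rise moments.  In an
operational setting these come from hourly output of a comprehensive
chemical transport model; this module implements the hourly-to-annual
averaging mathematics and a seeded synthetic generator that emulates the
structure of such an archive so the whole model is testable end to end.

Averaging is always done on the *hourly* quantity (e.g. the per-hour rate
constant) rather than evaluating formulas at annual-mean inputs, which
matters because the dependencies are nonlinear.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import xarray as xr

from .grid import GridConfig, VariableGrid, grid_to_arrays, grid_from_arrays

GRAVITY = 9.80665          # m s^-2
VON_KARMAN = 0.4
SECONDS_PER_YEAR = 3.15576e7   # Julian year

#: fixed aerosol properties used only for dry deposition
PARTICLE_DIAMETER = 0.3e-6     # m
PARTICLE_DENSITY = 1830.0      # kg m^-3
AIR_VISCOSITY = 1.81e-5        # kg m^-1 s^-1
MEAN_FREE_PATH = 6.8e-8        # m


def settling_velocity(diameter: float = PARTICLE_DIAMETER,
                      density: float = PARTICLE_DENSITY) -> float:
    """Stokes settling velocity with Cunningham slip correction (m s^-1)."""
    kn = 2.0 * MEAN_FREE_PATH / diameter
    cc = 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))
    return density * diameter ** 2 * GRAVITY * cc / (18.0 * AIR_VISCOSITY)


class FieldsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# archive container
# ---------------------------------------------------------------------------

#: archive variables: (name, ground_only) -- all are float arrays over cells
_FIELD_NAMES = (
    "U", "V", "W", "Udev", "Vdev",
    "Kxx", "Kyy", "Kzz", "M2u", "M2d",
    "kS", "fp_NO3", "fp_NH4", "fp_org",
    "ra", "rb", "rc_gas", "rc_particle",
    "rwd_particle", "rwd_SO2", "rwd_othergas",
    "plume_wind", "plume_wind_inv", "plume_wind_m13", "plume_wind_m14",
    "plume_T", "plume_s1", "plume_unstable", "blh",
)


@dataclass
class CellFields:
    """Per-cell annual-average parameters on a :class:`VariableGrid`.

    Face conventions: ``U``/``Udev``/``Kxx`` live on each cell's west face
    (positive eastward), ``V``/``Vdev``/``Kyy`` on the south face (positive
    northward), ``W``/``Kzz`` on the bottom face (positive upward).  ``M2u``
    is the nonlocal upward convective coefficient of an elevated
    boundary-layer cell (gain from the ground cell, s^-1); ``M2d`` the
    downward coefficient (loss to the cell below, s^-1); both are zero in the
    ground layer and above the boundary layer.  ``fp_*`` are marginal
    gas->particle partitioning fractions; deposition resistances (s m^-1) are
    meaningful in the ground layer; ``rwd_*`` are wet scavenging rates
    (s^-1); the ``plume_*`` scalars are the pre-averaged plume-rise inputs
    (mean windspeed and its -1, -1/3, -1.4 power means, temperature, Briggs
    stability parameter, unstable-class flag) and ``blh`` the boundary-layer
    height (m).
    """

    U: np.ndarray
    V: np.ndarray
    W: np.ndarray
    Udev: np.ndarray
    Vdev: np.ndarray
    Kxx: np.ndarray
    Kyy: np.ndarray
    Kzz: np.ndarray
    M2u: np.ndarray
    M2d: np.ndarray
    kS: np.ndarray
    fp_NO3: np.ndarray
    fp_NH4: np.ndarray
    fp_org: np.ndarray
    ra: np.ndarray
    rb: np.ndarray
    rc_gas: np.ndarray
    rc_particle: np.ndarray
    rwd_particle: np.ndarray
    rwd_SO2: np.ndarray
    rwd_othergas: np.ndarray
    plume_wind: np.ndarray
    plume_wind_inv: np.ndarray
    plume_wind_m13: np.ndarray
    plume_wind_m14: np.ndarray
    plume_T: np.ndarray
    plume_s1: np.ndarray
    plume_unstable: np.ndarray
    blh: np.ndarray

    def __post_init__(self):
        n = None
        for f in dc_fields(self):
            arr = np.asarray(getattr(self, f.name), dtype=float)
            setattr(self, f.name, arr)
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise FieldsError(f"field {f.name} length {arr.size} != {n}")
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.U.size

    def validate(self):
        for name in ("Udev", "Vdev", "Kxx", "Kyy", "Kzz", "M2u", "M2d", "kS",
                     "rwd_particle", "rwd_SO2", "rwd_othergas"):
            if np.any(getattr(self, name) < 0):
                raise FieldsError(f"{name} must be non-negative")
        for name in ("fp_NO3", "fp_NH4", "fp_org"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise FieldsError(f"{name} must lie in [0, 1]")
        if np.any(self.blh <= 0):
            raise FieldsError("boundary-layer height must be positive")

    @classmethod
    def zeros(cls, n: int) -> "CellFields":
        kw = {name: np.zeros(n) for name in _FIELD_NAMES}
        kw["blh"] = np.full(n, 1000.0)
        kw["plume_T"] = np.full(n, 288.0)
        kw["plume_s1"] = np.full(n, 5e-4)
        return cls(**kw)

    def replace(self, **kw) -> "CellFields":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# hourly-to-annual preprocessor mathematics
# ---------------------------------------------------------------------------

@dataclass
class SulfurOxidationParams:
    """Constants of the SO2 -> particulate sulfate rate parameterization.

    The gas-phase pathway (oxidation by the hydroxyl radical) uses a
    termolecular low/high-pressure-limit expression; the aqueous pathway
    (in-cloud oxidation by hydrogen peroxide) is modeled as an effective
    first-order rate proportional to cloud fraction and liquid water content.
    Only the hourly *averaging* is fixed by the model; the constants are
    configurable.
    """

    k0_300: float = 3.3e-31        # cm^6 molec^-2 s^-1 at 300 K
    k0_exponent: float = 4.3
    kinf: float = 1.6e-12          # cm^3 molec^-1 s^-1
    broadening: float = 0.6
    air_density: float = 2.5e19    # molec cm^-3
    aqueous_coeff: float = 1.0e-4  # s^-1 per (kg water / kg air)


def hourly_sulfur_rate(T: np.ndarray, HO: np.ndarray,
                       cloud_fraction: np.ndarray | None = None,
                       liquid_water: np.ndarray | None = None,
                       params: SulfurOxidationParams | None = None) -> np.ndarray:
    """Per-hour first-order SO2 oxidation rate constant (s^-1)."""
    p = params or SulfurOxidationParams()
    T = np.asarray(T, dtype=float)
    HO = np.asarray(HO, dtype=float)
    k0 = p.k0_300 * (300.0 / T) ** p.k0_exponent * p.air_density
    ratio = k0 / p.kinf
    k_gas = (k0 / (1.0 + ratio)) * p.broadening ** (1.0 / (1.0 + np.log10(ratio) ** 2))
    rate = k_gas * HO
    if cloud_fraction is not None and liquid_water is not None:
        rate = rate + p.aqueous_coeff * np.asarray(cloud_fraction, float) \
            * np.asarray(liquid_water, float)
    return rate


def average_rate_constant(hourly_T, hourly_HO, hourly_cloud_fraction=None,
                          hourly_liquid_water=None,
                          params: SulfurOxidationParams | None = None) -> float:
    """Annual-average SO2 oxidation rate: the mean of the *hourly* rates.

    Because the rate depends nonlinearly on temperature and HO*, this differs
    from the rate evaluated at annual-mean inputs.
    """
    T = np.asarray(hourly_T, dtype=float)
    HO = np.asarray(hourly_HO, dtype=float)
    if T.shape != HO.shape:
        raise FieldsError("hourly series lengths differ")
    for s in (hourly_cloud_fraction, hourly_liquid_water):
        if s is not None and np.asarray(s).shape != T.shape:
            raise FieldsError("hourly series lengths differ")
    return float(np.mean(hourly_sulfur_rate(
        T, HO, hourly_cloud_fraction, hourly_liquid_water, params)))


def partitioning_fraction(m_gas, m_particle) -> float:
    """Marginal annual-average particle-phase fraction of a gas/particle pair.

    For each consecutive pair of hours the particle share of the total mass
    change is computed and the shares are averaged.  Steps with zero total
    change are skipped (and n reduced); shares outside [0, 1] (opposite-signed
    phase changes) are clamped into [0, 1].
    """
    mg = np.asarray(m_gas, dtype=float)
    mp = np.asarray(m_particle, dtype=float)
    if mg.shape != mp.shape:
        raise FieldsError("gas and particle series lengths differ")
    if mg.size < 2:
        raise FieldsError("need at least two time steps")
    dg = np.diff(mg)
    dp = np.diff(mp)
    tot = dp + dg
    keep = tot != 0
    if not np.any(keep):
        raise FieldsError("all steps have zero total mass change")
    frac = np.clip(dp[keep] / tot[keep], 0.0, 1.0)
    return float(np.mean(frac))


@dataclass
class HourlyMet:
    """Hourly meteorological series used by the averaging preprocessor."""

    blh: np.ndarray                 # boundary-layer height (m)
    ustar: np.ndarray               # friction velocity (m s^-1)
    heat_flux: np.ndarray           # kinematic surface heat flux (K m s^-1)
    temperature: np.ndarray         # K

    def __post_init__(self):
        shp = np.asarray(self.blh).shape
        for f in dc_fields(self):
            arr = np.asarray(getattr(self, f.name), dtype=float)
            if arr.shape != shp:
                raise FieldsError("hourly met series lengths differ")
            setattr(self, f.name, arr)
        if np.any(self.blh <= 0):
            raise FieldsError("boundary-layer height must be positive")


@dataclass
class MixingClosureParams:
    """Constants of the per-hour local/nonlocal mixing closure."""

    conv_coeff: float = 0.3     # M2u = conv_coeff * wstar / blh when unstable
    kzz_z_ref: float = 50.0     # m, vertical diffusivity evaluation height
    kh_coeff: float = 10.0      # horizontal K = kh_coeff * ustar * kzz_z_ref
    kzz_floor: float = 0.05     # m^2 s^-1


def hourly_mixing(met: HourlyMet, params: MixingClosureParams | None = None):
    """Per-hour (M2u, M2d, Kzz, Kxx, Kyy) from the closure.

    Convective (nonlocal) coefficients are active only in unstable hours
    (positive surface heat flux); local diffusion acts in all hours.
    For this single-cell form the downward coefficient equals the upward one
    (the generator rescales M2d per column to conserve column mass).
    """
    p = params or MixingClosureParams()
    unstable = met.heat_flux > 0
    wstar = np.where(
        unstable,
        (GRAVITY / met.temperature * np.abs(met.heat_flux) * met.blh) ** (1.0 / 3.0),
        0.0)
    m2u = np.where(unstable, p.conv_coeff * wstar / met.blh, 0.0)
    m2d = m2u.copy()
    kzz = np.maximum(VON_KARMAN * met.ustar * p.kzz_z_ref, p.kzz_floor)
    kh = p.kh_coeff * met.ustar * p.kzz_z_ref
    return m2u, m2d, kzz, kh, kh.copy()


def average_mixing_coefficients(met: HourlyMet,
                                params: MixingClosureParams | None = None):
    """Arithmetic hourly mean of the per-hour mixing coefficients."""
    per_hour = hourly_mixing(met, params)
    return tuple(float(np.mean(v)) for v in per_hour)


def average_deviations(hourly_u, hourly_v, mean_u=None, mean_v=None):
    """Annual-mean absolute wind deviations |u - <u>|, |v - <v>|."""
    u = np.asarray(hourly_u, dtype=float)
    v = np.asarray(hourly_v, dtype=float)
    mu = float(np.mean(u)) if mean_u is None else float(mean_u)
    mv = float(np.mean(v)) if mean_v is None else float(mean_v)
    return float(np.mean(np.abs(u - mu))), float(np.mean(np.abs(v - mv)))


# ---------------------------------------------------------------------------
# synthetic archive generator
# ---------------------------------------------------------------------------

@dataclass
class SynthesisParams:
    """Study conditions emulated by the synthetic archive.

    Ground-layer annual-mean wind speeds fall in 1-8 m s^-1 and grow with
    height up to ``top_speed`` at the domain top; wind-speed deviations are a
    fixed fraction of the local speed; the boundary layer, mixing
    coefficients, oxidation rate, partitioning fractions and deposition
    parameters vary smoothly in space within physically typical ranges.
    """

    wind_direction_deg: float = 250.0    # meteorological "from", degrees
    ground_speed_range: tuple[float, float] = (1.0, 8.0)
    top_speed: float = 30.0
    deviation_fraction: float = 0.6
    vertical_wind: float = 0.0           # annual-mean W (m s^-1)
    blh_range: tuple[float, float] = (600.0, 1400.0)
    m2u_range: tuple[float, float] = (2e-4, 8e-4)   # s^-1
    kzz_bl_range: tuple[float, float] = (5.0, 40.0)   # m^2 s^-1 inside BL
    kzz_ft: float = 0.2                  # m^2 s^-1 above BL
    kh_range: tuple[float, float] = (50.0, 400.0)
    kS_range: tuple[float, float] = (5e-7, 4e-6)    # s^-1
    fp_NO3_range: tuple[float, float] = (0.15, 0.55)
    fp_NH4_range: tuple[float, float] = (0.35, 0.85)
    fp_org_range: tuple[float, float] = (0.1, 0.4)
    ra_range: tuple[float, float] = (20.0, 120.0)   # s m^-1
    rb_range: tuple[float, float] = (20.0, 80.0)
    rc_gas_range: tuple[float, float] = (50.0, 400.0)
    rwd_particle_range: tuple[float, float] = (5e-7, 5e-6)  # s^-1
    rwd_SO2_range: tuple[float, float] = (3e-7, 3e-6)
    rwd_othergas_range: tuple[float, float] = (1e-7, 1e-6)
    temperature: float = 288.0           # K
    stability_s1: float = 5e-4           # s^-2, Briggs stability parameter
    unstable_fraction: float = 0.5
    calm: bool = False
    n_hours: int = 8760


class _SmoothField:
    """Smooth deterministic random field: a low-order random Fourier series.

    Values are resolution independent (functions of position, not of the
    grid), so refining the grid samples the same underlying field.
    """

    def __init__(self, rng: np.random.Generator, domain_bounds, n_modes: int = 6):
        x0, y0, x1, y1 = domain_bounds
        self.scale = max(x1 - x0, y1 - y0)
        self.kx = rng.uniform(0.5, 3.0, n_modes) * 2 * np.pi / self.scale
        self.ky = rng.uniform(0.5, 3.0, n_modes) * 2 * np.pi / self.scale
        self.phase = rng.uniform(0, 2 * np.pi, n_modes)
        self.amp = rng.uniform(0.5, 1.0, n_modes)
        self.amp /= self.amp.sum()

    def unit(self, x, y):
        """Smooth field in [0, 1]."""
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        v = np.sum(self.amp * np.sin(self.kx * x + self.ky * y + self.phase), axis=-1)
        return 0.5 * (1.0 + v)  # sum of amps <= 1 keeps v in [-1, 1]

    def ranged(self, x, y, lo, hi):
        return lo + (hi - lo) * self.unit(x, y)


def synthesize_archive(grid: VariableGrid, seed: int,
                       params: SynthesisParams | None = None,
                       return_hourly: bool = False):
    """Generate a physically plausible annual-average archive on ``grid``.

    Identical (grid, seed, params) give a bit-identical archive.  When
    ``return_hourly`` is set, also returns the domain-representative hourly
    series from which kS and the partitioning fractions were derived.
    """
    p = params or SynthesisParams()
    rng = np.random.default_rng(seed)
    n = grid.n_cells
    cf = CellFields.zeros(n)
    xc = 0.5 * (grid.xmin + grid.xmax)
    yc = 0.5 * (grid.ymin + grid.ymax)
    zc = 0.5 * (grid.zbottom + grid.ztop)
    ztop_domain = grid.layer_tops[-1]

    f_speed = _SmoothField(rng, grid.domain_bounds)
    f_dir = _SmoothField(rng, grid.domain_bounds)
    f_blh = _SmoothField(rng, grid.domain_bounds)
    f_misc = [_SmoothField(rng, grid.domain_bounds) for _ in range(12)]

    # domain-representative hourly series -> kS and partitioning fractions
    hrs = np.arange(p.n_hours)
    diurnal = np.sin(2 * np.pi * hrs / 24.0)
    seasonal = np.cos(2 * np.pi * hrs / max(p.n_hours, 24))
    hourly = {
        "T": 288.0 + 8.0 * seasonal + 5.0 * diurnal + rng.normal(0, 1.0, p.n_hours),
        "HO": np.clip(1.5e6 * np.clip(diurnal, 0, None)
                      + rng.normal(0, 1e5, p.n_hours), 0, None),
        "cloud_fraction": np.clip(rng.beta(2, 3, p.n_hours), 0, 1),
        "liquid_water": np.clip(rng.gamma(2.0, 1e-4, p.n_hours), 0, None),
    }
    kS_base = average_rate_constant(hourly["T"], hourly["HO"],
                                    hourly["cloud_fraction"], hourly["liquid_water"])

    def hourly_pair(phi, tau=12.0, noise=0.05):
        """Gas/particle mass series relaxing toward particle fraction phi."""
        total = 10.0 + 2.0 * np.sin(2 * np.pi * hrs / 24.0) \
            + rng.normal(0, 0.2, p.n_hours)
        part = np.empty(p.n_hours)
        part[0] = phi * total[0]
        for j in range(1, p.n_hours):
            target = phi * total[j]
            part[j] = part[j - 1] + (target - part[j - 1]) / tau \
                + rng.normal(0, noise)
        part = np.clip(part, 0, total)
        return total - part, part

    pair_fp = {}
    for name, rng_lohi in (("NO3", p.fp_NO3_range), ("NH4", p.fp_NH4_range),
                           ("org", p.fp_org_range)):
        phi = 0.5 * (rng_lohi[0] + rng_lohi[1])
        g, q = hourly_pair(phi)
        pair_fp[name] = partitioning_fraction(g, q)
        hourly[f"m_gas_{name}"] = g
        hourly[f"m_particle_{name}"] = q

    if p.calm:
        speed_ground = np.zeros(n)
        speed = np.zeros(n)
        direction = np.zeros(n)
    else:
        lo, hi = p.ground_speed_range
        # keep ground speeds strictly inside the band
        speed_ground = f_speed.ranged(xc, yc, lo + 0.05 * (hi - lo),
                                      hi - 0.05 * (hi - lo))
        # speeds grow with height toward top_speed
        frac = np.clip(zc / ztop_domain, 0.0, 1.0) ** 1.3
        speed = speed_ground + (p.top_speed - speed_ground) * frac
        direction = np.deg2rad(270.0 - p.wind_direction_deg) \
            + np.deg2rad(40.0) * (f_dir.unit(xc, yc) - 0.5)

    # face-normal winds evaluated at face centers (same smooth fields)
    cf.U = speed * np.cos(direction)
    cf.V = speed * np.sin(direction)
    cf.W = np.full(n, 0.0 if p.calm else p.vertical_wind)
    cf.Udev = np.abs(cf.U) * (0.0 if p.calm else p.deviation_fraction)
    cf.Vdev = np.abs(cf.V) * (0.0 if p.calm else p.deviation_fraction)

    blh_ground = f_blh.ranged(xc, yc, *p.blh_range)
    # boundary-layer height is a column property: take it from the ground cell
    blh = np.empty(n)
    for i in range(n):
        below = grid.ground_below(i)
        blh[i] = sum(f * blh_ground[j] for j, f in below) if below else blh_ground[i]
    cf.blh = blh

    in_bl = grid.zbottom < blh
    kzz_bl = f_misc[0].ranged(xc, yc, *p.kzz_bl_range)
    cf.Kzz = np.where(in_bl, kzz_bl, p.kzz_ft)
    if p.calm:
        cf.Kzz = np.full(n, p.kzz_ft)
    kh = f_misc[1].ranged(xc, yc, *p.kh_range)
    cf.Kxx = kh if not p.calm else np.full(n, p.kzz_ft)
    cf.Kyy = cf.Kxx.copy()

    # nonlocal convective coefficients: M2u on elevated boundary-layer cells;
    # M2d from the telescoping column relation
    #   M2d_i dz_i = sum_{k >= i, in BL} M2u_k dz_k
    # which conserves column mass and makes a uniform column a fixed point.
    m2u = np.zeros(n)
    if not p.calm:
        m2u_ground = f_misc[2].ranged(xc, yc, *p.m2u_range)
        elevated_bl = (grid.layer > 0) & (grid.zbottom < blh)
        for i in np.nonzero(elevated_bl)[0]:
            below = grid.ground_below(i)
            m2u[i] = sum(f * m2u_ground[j] for j, f in below)
    cf.M2u = m2u
    cf.M2d = _telescoped_m2d(grid, m2u)

    ks_mod = f_misc[3].ranged(xc, yc, 0.7, 1.3)
    lo, hi = p.kS_range
    cf.kS = np.clip(kS_base * ks_mod, lo, hi)

    for name, key, rng_lohi in (("fp_NO3", "NO3", p.fp_NO3_range),
                                ("fp_NH4", "NH4", p.fp_NH4_range),
                                ("fp_org", "org", p.fp_org_range)):
        base = pair_fp[key]
        mod = f_misc[4].ranged(xc, yc, -0.5, 0.5) * (rng_lohi[1] - rng_lohi[0])
        setattr(cf, name, np.clip(base + mod, *rng_lohi))

    ground = grid.layer == 0
    cf.ra = np.where(ground, f_misc[5].ranged(xc, yc, *p.ra_range), 0.0) + ~ground * 1.0
    cf.rb = np.where(ground, f_misc[6].ranged(xc, yc, *p.rb_range), 0.0) + ~ground * 1.0
    cf.rc_gas = np.where(ground, f_misc[7].ranged(xc, yc, *p.rc_gas_range), 0.0) \
        + ~ground * 1.0
    vs = settling_velocity()
    cf.rc_particle = cf.ra * cf.rb * vs

    cf.rwd_particle = f_misc[8].ranged(xc, yc, *p.rwd_particle_range)
    cf.rwd_SO2 = f_misc[9].ranged(xc, yc, *p.rwd_SO2_range)
    cf.rwd_othergas = f_misc[10].ranged(xc, yc, *p.rwd_othergas_range)

    wind_floor = np.maximum(speed, 0.5)
    cf.plume_wind = speed
    cf.plume_wind_inv = 1.0 / wind_floor
    cf.plume_wind_m13 = wind_floor ** (-1.0 / 3.0)
    cf.plume_wind_m14 = wind_floor ** (-1.4)
    cf.plume_T = np.full(n, p.temperature)
    cf.plume_s1 = np.full(n, p.stability_s1)
    cf.plume_unstable = (f_misc[11].unit(xc, yc) < p.unstable_fraction).astype(float)

    cf.validate()
    if return_hourly:
        return cf, hourly
    return cf


def _telescoped_m2d(grid: VariableGrid, m2u: np.ndarray) -> np.ndarray:
    """Per-cell M2d from the column-mass-conserving telescoping relation."""
    m2d = np.zeros(grid.n_cells)
    topo = grid.face_topology()
    # process columns from the top down: M2d_i dz_i = M2u_i dz_i + sum_above
    for L in range(grid.n_layers - 1, 0, -1):
        for i in grid.layer_cells(L):
            above_flux = 0.0
            for j, f in topo[i]["A"]:
                above_flux += f * m2d[j] * grid.dz[j]
            if m2u[i] > 0 or above_flux > 0:
                m2d[i] = (m2u[i] * grid.dz[i] + above_flux) / grid.dz[i]
    return m2d


# ---------------------------------------------------------------------------
# archive I/O (NetCDF-style gridded layout)
# ---------------------------------------------------------------------------

def archive_to_dataset(grid: VariableGrid, fields: CellFields,
                       metadata: dict | None = None) -> xr.Dataset:
    data = {name: ("cell", getattr(fields, name)) for name in _FIELD_NAMES}
    for k, v in grid_to_arrays(grid).items():
        data[k] = ("cell", v)
    cfg = grid.config
    attrs = {
        "domain_bounds": list(cfg.domain_bounds),
        "base_size": cfg.base_size,
        "divisors": list(cfg.divisors),
        "pop_threshold": cfg.pop_threshold,
        "high_res_cap_height": cfg.high_res_cap_height,
        "layer_tops": list(cfg.layer_tops),
        "crs": cfg.crs or "",
    }
    for k, v in (metadata or {}).items():
        attrs[f"meta_{k}"] = v
    return xr.Dataset(data, attrs=attrs)


def write_archive(path, grid: VariableGrid, fields: CellFields,
                  metadata: dict | None = None):
    archive_to_dataset(grid, fields, metadata).to_netcdf(path, engine="scipy")


def read_archive(path) -> tuple[VariableGrid, CellFields]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    a = ds.attrs
    cfg = GridConfig(
        domain_bounds=tuple(float(v) for v in a["domain_bounds"]),
        base_size=float(a["base_size"]),
        divisors=tuple(int(v) for v in np.atleast_1d(a["divisors"])),
        pop_threshold=float(a["pop_threshold"]),
        high_res_cap_height=float(a["high_res_cap_height"]),
        layer_tops=tuple(float(v) for v in a["layer_tops"]),
        crs=(a.get("crs") or None),
    )
    arrays = {k: ds[k].values for k in
              ("cell_level", "cell_x0u", "cell_y0u", "cell_layer", "cell_population")}
    arrays = {k: v.astype(np.int64) if k != "cell_population" else v
              for k, v in arrays.items()}
    grid = grid_from_arrays(cfg, arrays)
    kw = {name: ds[name].values for name in _FIELD_NAMES}
    return grid, CellFields(**kw)
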