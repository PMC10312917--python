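"""Desk-scale k-space pseudospectral solver for linear heterogeneous acoustics.

Integrates the first-order coupled acoustic equations (pressure and
particle velocity) on a regular 2D or 3D grid with spectral spatial
derivatives evaluated on staggered grids, an exact-in-homogeneous-media
k-space dispersion correction, a split-field absorbing boundary layer, and
a narrowband power-law absorption term.  The source is a focused
spherical-cap bowl (circular arc in 2D) driven with a ramped tone burst;
the per-voxel maximum pressure is recorded once the first wavefront has
arrived, which is the quantity hydrophone raster scans report.

Analytic oracles (Rayleigh-Sommerfeld bowl integral, free-space Green's
function superposition, layered-medium plane-wave transmission) live here
too, so the solver can be validated without external data.

Units: grid spacing in mm at the interface, SI internally; pressure in Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special

from .ct_props import AcousticMediumMap
from .transducer import TransducerGeometry
from .volume import VoxelVolume

__all__ = [
    "SimulationConfig",
    "BowlSource",
    "GridSource",
    "PressureField",
    "ppw",
    "cfl",
    "make_bowl_source",
    "simulate",
    "rayleigh_free_field",
    "on_axis_bowl_pressure",
    "point_source_field",
    "tone_amplitude",
    "measure_layer_transmission",
    "layer_transmission_coefficient",
]

_NEPER_PER_DB = 1.0 / 8.685889638065035  # 20 * log10(e) dB per neper


def ppw(sound_speed: float, f0: float, dx_mm: float) -> float:
    """Grid points per wavelength: (c / f0) / dx."""
    if sound_speed <= 0 or f0 <= 0 or dx_mm <= 0:
        raise ValueError("sound speed, frequency and spacing must be positive")
    return (sound_speed / f0) / (dx_mm * 1e-3)


def cfl(sound_speed: float, dt_s: float, dx_mm: float) -> float:
    """Courant-Friedrichs-Lewy number: c * dt / dx."""
    if sound_speed <= 0 or dt_s <= 0 or dx_mm <= 0:
        raise ValueError("sound speed, time step and spacing must be positive")
    return sound_speed * dt_s / (dx_mm * 1e-3)


@dataclass
class SimulationConfig:
    """Time stepping, source drive, and boundary-layer settings.

    ``dt=None`` derives the step from ``cfl_target`` and the medium's
    maximum sound speed; ``t_end=None`` simulates two crossings of the grid
    diagonal at the slowest speed so the focus fully forms.  The burst is
    ``n_cycles`` of a sinusoid at ``f0`` with raised-cosine ramps of
    ``ramp_cycles`` at both ends.  ``source_amplitude`` is the mass-source
    density amplitude injected at the source voxels (kg m^-3 s^-1); the
    recorded field is proportional to it.
    """

    f0: float = 250e3  # Hz
    source_amplitude: float = 1.0
    n_cycles: float = 15.0
    ramp_cycles: float = 2.0
    dt: float | None = None  # s
    cfl_target: float = 0.2
    t_end: float | None = None  # s
    pml_thickness: int = 10  # voxels
    pml_alpha: float = 2.0  # Np per voxel at the outer edge (quartic profile)
    periodic_axes: tuple[int, ...] = ()
    record_from_arrival: bool = True
    dtype: str = "float64"

    def __post_init__(self):
        if self.f0 <= 0 or self.n_cycles <= 0:
            raise ValueError("f0 and n_cycles must be positive")
        if not 0 < self.cfl_target <= 0.3:
            raise ValueError("cfl_target must lie in (0, 0.3]")
        if self.pml_thickness < 8:
            raise ValueError("absorbing layer must be at least 8 voxels thick")


@dataclass
class BowlSource:
    """Voxelized spherical-cap (3D) or circular-arc (2D) source.

    ``indices`` are the grid indices of the source voxels; all lie at the
    bowl's focal distance (within half a voxel) from ``focus_index``.
    ``weights`` scale the drive per voxel (uniform, unapodized bowl).
    """

    indices: np.ndarray  # (N, ndim) int
    weights: np.ndarray  # (N,)
    focus_index: np.ndarray  # (ndim,) float, geometric focus in voxels
    apex_index: np.ndarray  # (ndim,) float
    axis: int  # grid axis of propagation (+direction)
    geom: TransducerGeometry = None

    def __len__(self):
        return len(self.indices)


@dataclass
class GridSource:
    """Arbitrary driven voxel set (e.g. a phased line emitting an oblique
    plane wave).  ``delays`` shift each voxel's burst in seconds."""

    indices: np.ndarray  # (N, ndim) int
    weights: np.ndarray | None = None
    delays: np.ndarray | None = None  # s

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.weights is None:
            self.weights = np.ones(len(self.indices))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=float)

    def __len__(self):
        return len(self.indices)


@dataclass
class PressureField:
    """Per-voxel maximum pressure (Pa) of a run.

    If the run was given probe points, ``probe_traces`` holds the pressure
    time series at those voxels ((n_steps, n_probes), hydrophone-style)
    and ``probe_dt`` their sampling step.
    """

    max_pressure: np.ndarray
    spacing: tuple  # mm
    probe_traces: np.ndarray | None = None
    probe_dt: float | None = None

    def __post_init__(self):
        self.max_pressure = np.asarray(self.max_pressure)
        if (self.max_pressure < 0).any():
            raise ValueError("maximum pressure must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def ndim(self):
        return self.max_pressure.ndim

    def save(self, path):
        if self.ndim != 3:
            raise ValueError("NIfTI export supports 3D fields only")
        VoxelVolume(self.max_pressure.astype(np.float32), self.spacing).save(path)


def make_bowl_source(
    geom: TransducerGeometry,
    grid_shape,
    dx_mm: float,
    apex_index: float | None = None,
    pml_clearance: int = 10,
) -> BowlSource:
    """Voxelize the bowl on the simulation grid.

    The beam axis is grid axis 0 (increasing), laterally centered.  A voxel
    belongs to the source iff its center lies within half a voxel of the
    sphere of radius ``focal_distance`` around the geometric focus, between
    the inner and outer aperture half-angles.  Raises if the cap would be
    clipped by the grid or intrude into the absorbing layer.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    ndim = len(grid_shape)
    if ndim not in (2, 3):
        raise ValueError("bowl sources are supported on 2D or 3D grids")
    F = geom.focal_distance / dx_mm  # voxels
    th_out = geom.outer_half_angle
    th_in = geom.inner_half_angle
    if apex_index is None:
        apex_index = pml_clearance + 2.0
    apex = np.array([apex_index] + [(n - 1) / 2.0 for n in grid_shape[1:]])
    focus = apex.copy()
    focus[0] += F

    # analytic cap extents, for the clipping check
    ax_lo = apex_index
    ax_hi = apex_index + F * (1 - np.cos(th_out))
    lat_half = F * np.sin(th_out)
    lo_ok = ax_lo >= pml_clearance + 1 and ax_hi <= grid_shape[0] - pml_clearance - 2
    lat_ok = all(
        (n - 1) / 2.0 - lat_half >= pml_clearance + 1 and (n - 1) / 2.0 + lat_half <= n - pml_clearance - 2
        for n in grid_shape[1:]
    )
    if not (lo_ok and lat_ok):
        raise ValueError("bowl clipped by grid (or intrudes into the absorbing layer)")

    coords = np.meshgrid(*(np.arange(n, dtype=float) for n in grid_shape), indexing="ij", sparse=True)
    v = [c - f for c, f in zip(coords, focus)]
    r = np.sqrt(sum(x**2 for x in v))
    with np.errstate(invalid="ignore"):
        # angle from the bowl axis, seen from the center of curvature
        cos_t = np.clip(-v[0] / np.maximum(r, 1e-12), -1.0, 1.0)
    band = np.abs(r - F) <= 0.5
    sel = band & (cos_t >= np.cos(th_out)) & (cos_t <= np.cos(th_in))
    idx = np.argwhere(sel)
    if len(idx) == 0:
        raise ValueError("degenerate bowl: no source voxels on this grid")
    return BowlSource(
        indices=idx,
        weights=np.ones(len(idx)),
        focus_index=focus,
        apex_index=apex,
        axis=0,
        geom=geom,
    )


def _tone_burst(t: np.ndarray, f0: float, n_cycles: float, ramp_cycles: float) -> np.ndarray:
    """Sinusoidal burst with raised-cosine ramps at both ends."""
    T = n_cycles / f0
    Tr = min(ramp_cycles / f0, T / 2)
    env = np.zeros_like(t)
    on = (t >= 0) & (t < T)
    env[on] = 1.0
    if Tr > 0:
        up = on & (t < Tr)
        env[up] = 0.5 * (1 - np.cos(np.pi * t[up] / Tr))
        dn = on & (t > T - Tr)
        env[dn] = 0.5 * (1 - np.cos(np.pi * (T - t[dn]) / Tr))
    return env * np.sin(2 * np.pi * f0 * t)


def simulate(
    medium: AcousticMediumMap,
    source,
    config: SimulationConfig,
    probes=None,
) -> PressureField:
    """Run the k-space pseudospectral time loop and record max pressure.

    ``source`` is a :class:`BowlSource` or any object with ``indices`` and
    ``weights`` attributes.  ``probes`` optionally lists voxel indices at
    which the full pressure time series is recorded (like hydrophone
    points).  Deterministic: no randomness anywhere.
    """
    c = np.ascontiguousarray(medium.sound_speed, dtype=config.dtype)
    rho0 = np.ascontiguousarray(medium.density, dtype=config.dtype)
    ndim = c.ndim
    shape = c.shape
    if len(set(medium.spacing)) != 1:
        raise ValueError("the solver requires an isotropic grid")
    dx = medium.spacing[0] * 1e-3  # m
    c_max = float(c.max())
    c_min = float(c.min())

    dt = config.dt if config.dt is not None else config.cfl_target * dx / c_max
    courant = c_max * dt / dx
    if courant > 0.3 + 1e-9:
        raise ValueError(f"CFL number {courant:.3f} exceeds the stable limit 0.3; refusing to run")
    diag = np.sqrt(sum((n * dx) ** 2 for n in shape))
    t_end = config.t_end if config.t_end is not None else 2.0 * diag / c_min
    n_steps = int(np.ceil(t_end / dt))

    # spectral operators (real FFT along the last axis)
    ks = []
    for ax, n in enumerate(shape):
        if ax == ndim - 1:
            k1 = 2 * np.pi * np.fft.rfftfreq(n, d=dx)
        else:
            k1 = 2 * np.pi * np.fft.fftfreq(n, d=dx)
        sh = [1] * ndim
        sh[ax] = len(k1)
        ks.append(k1.reshape(sh))
    kmag = np.sqrt(sum(k**2 for k in ks))
    kappa = np.sinc(c_max * kmag * dt / (2 * np.pi))  # np.sinc includes the pi
    grad_op = [1j * k * kappa * np.exp(1j * k * dx / 2) for k in ks]
    div_op = [1j * k * kappa * np.exp(-1j * k * dx / 2) for k in ks]

    # split-field absorbing layer: quartic profile, applied twice per update
    pml = []
    for ax, n in enumerate(shape):
        fac = np.ones(n, dtype=config.dtype)
        if ax not in config.periodic_axes:
            L = config.pml_thickness
            i = np.arange(n, dtype=float)
            depth = np.maximum(L - i, 0) + np.maximum(i - (n - 1 - L), 0)
            sigma = config.pml_alpha * (depth / L) ** 4 * (c_max / dx)
            fac = np.exp(-sigma * dt / 2).astype(config.dtype)
        sh = [1] * ndim
        sh[ax] = n
        pml.append(fac.reshape(sh))

    # density on staggered (half-step) grids for the velocity update;
    # harmonic averaging preserves the effective impedance of sharp interfaces
    rho_sg = [2.0 / (1.0 / rho0 + 1.0 / np.roll(rho0, -1, axis=ax)) for ax in range(ndim)]

    # narrowband power-law absorption as per-step exponential decay
    alpha_db = np.asarray(medium.absorption, dtype=float) * (config.f0 / medium.f_ref) ** medium.power_law_exponent
    alpha_np = alpha_db * 100.0 * _NEPER_PER_DB  # Np/m at f0
    decay = np.exp(-alpha_np * medium.sound_speed * dt).astype(config.dtype)

    src_idx = tuple(np.asarray(source.indices)[:, a] for a in range(ndim))
    weights = np.asarray(source.weights, dtype=config.dtype)
    t = np.arange(n_steps) * dt
    delays = getattr(source, "delays", None)
    if delays is None:
        drive = config.source_amplitude * _tone_burst(t, config.f0, config.n_cycles, config.ramp_cycles)
        drive_mat = None
    else:
        drive = None
        drive_mat = config.source_amplitude * _tone_burst(
            t[:, None] - np.asarray(delays, dtype=float)[None, :],
            config.f0,
            config.n_cycles,
            config.ramp_cycles,
        )

    # record max |p| only after the first wavefront could have arrived
    if config.record_from_arrival and len(src_idx[0]) > 0:
        src_mask = np.zeros(shape, dtype=bool)
        src_mask[src_idx] = True
        dist = ndimage.distance_transform_edt(~src_mask) * dx
        record_step = np.ceil(dist / (c_max * dt)).astype(np.int64)
    else:
        record_step = np.zeros(shape, dtype=np.int64)

    if probes is not None:
        probes = np.asarray(probes, dtype=int)
        probe_idx = tuple(probes[:, a] for a in range(ndim))
        traces = np.zeros((n_steps, len(probes)), dtype=config.dtype)
    u = [np.zeros(shape, dtype=config.dtype) for _ in range(ndim)]
    rho_split = [np.zeros(shape, dtype=config.dtype) for _ in range(ndim)]
    p = np.zeros(shape, dtype=config.dtype)
    p_max = np.zeros(shape, dtype=config.dtype)
    c2 = c**2
    inv_rho_sg = [dt / r for r in rho_sg]
    absorbing = bool((alpha_np > 0).any())

    all_axes = tuple(range(ndim))
    rfft = np.fft.rfftn
    irfft = np.fft.irfftn

    for n in range(n_steps):
        P = rfft(p)
        for ax in range(ndim):
            dp = irfft(grad_op[ax] * P, s=shape, axes=all_axes)
            u[ax] = pml[ax] * (pml[ax] * u[ax] - inv_rho_sg[ax] * dp)
            if absorbing:
                # symmetric damping of velocity and density leaves the
                # impedance untouched and yields the nominal dB/cm decay
                u[ax] *= decay
        for ax in range(ndim):
            du = irfft(div_op[ax] * rfft(u[ax]), s=shape, axes=all_axes)
            rho_split[ax] = pml[ax] * (pml[ax] * rho_split[ax] - dt * rho0 * du)
        if drive is not None:
            s_n = drive[n]
            if s_n != 0.0:
                inj = (dt / ndim) * s_n * weights
                for ax in range(ndim):
                    rho_split[ax][src_idx] += inj
        else:
            inj = (dt / ndim) * drive_mat[n] * weights
            for ax in range(ndim):
                rho_split[ax][src_idx] += inj
        if absorbing:
            for ax in range(ndim):
                rho_split[ax] *= decay
        p = c2 * sum(rho_split)
        if probes is not None:
            traces[n] = p[probe_idx]
        np.maximum(p_max, np.abs(p), out=p_max, where=(record_step <= n))
        if n % 500 == 0 and not np.isfinite(p).all():
            raise RuntimeError(f"non-finite pressure at step {n} (t={n * dt:.3e} s); aborting")

    if not np.isfinite(p_max).all():
        raise RuntimeError("non-finite pressure in recorded field")
    if probes is not None:
        return PressureField(p_max, medium.spacing, probe_traces=traces, probe_dt=dt)
    return PressureField(p_max, medium.spacing)


def tone_amplitude(trace: np.ndarray, dt: float, f0: float, t_start: float, n_periods: int = 8) -> float:
    """Amplitude of the f0 component of a probe trace by quadrature
    demodulation over an integer number of periods starting at ``t_start``.

    Insensitive to off-band transients, unlike a broadband max; this is the
    right way to compare a tone-burst run with a single-frequency analytic
    solution.
    """
    n0 = int(round(t_start / dt))
    n1 = n0 + int(round(n_periods / (f0 * dt)))
    if n0 < 0 or n1 > len(trace):
        raise ValueError("demodulation window exceeds the recorded trace")
    t = np.arange(n0, n1) * dt
    seg = np.asarray(trace[n0:n1], dtype=float)
    return float(2.0 * np.abs(np.mean(seg * np.exp(-2j * np.pi * f0 * t))))


# ---------------------------------------------------------------------------
# analytic oracles


def rayleigh_free_field(
    geom: TransducerGeometry,
    points_mm,
    f0: float | None = None,
    c: float = 1500.0,
    rho: float = 1000.0,
    u0: float = 1.0,
    nodes_per_wavelength: float = 20.0,
):
    """Rayleigh-Sommerfeld field of the bowl in a homogeneous medium (3D).

    Numerical quadrature of ``p(r) = -i w rho u0 / (2 pi) * Int e^{ikR}/R dS``
    over the spherical cap (annular opening excluded), with surface nodes
    at least ``nodes_per_wavelength`` per wavelength apart.  ``u0`` is the
    uniform normal surface velocity (m/s); returns complex pressure (Pa) at
    each query point.
    """
    f0 = f0 if f0 is not None else geom.f0
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) * 1e-3  # m
    F = geom.focal_distance * 1e-3
    k = 2 * np.pi * f0 / c
    lam = c / f0
    h = lam / nodes_per_wavelength  # node pitch along the surface (m)

    d = np.asarray(geom.propagation, dtype=float)
    apex = np.asarray(geom.origin, dtype=float) * 1e-3
    focus = apex + F * d
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    th = np.arange(geom.inner_half_angle, geom.outer_half_angle, h / F) + h / (2 * F)
    th = th[th < geom.outer_half_angle]
    total = np.zeros(len(pts), dtype=complex)
    for theta in th:
        ring_r = F * np.sin(theta)
        n_phi = max(8, int(np.ceil(2 * np.pi * ring_r / h)))
        phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
        nodes = (
            focus[None, :]
            - F * np.cos(theta) * d[None, :]
            + ring_r * (np.cos(phi)[:, None] * e1[None, :] + np.sin(phi)[:, None] * e2[None, :])
        )
        dS = F**2 * np.sin(theta) * (h / F) * (2 * np.pi / n_phi)
        R = np.linalg.norm(pts[:, None, :] - nodes[None, :, :], axis=2)
        total += dS * np.sum(np.exp(1j * k * R) / R, axis=1)
    w = 2 * np.pi * f0
    return -1j * w * rho * u0 / (2 * np.pi) * total


def on_axis_bowl_pressure(geom: TransducerGeometry, z_mm, f0=None, c=1500.0, rho=1000.0, u0=1.0):
    """Closed-form on-axis Rayleigh field of the bowl (annulus-aware).

    On the axis the surface integral reduces to an integral over the
    source-to-field distance R, giving
    ``p = -(rho c u0) (F / h) (e^{ikR_out} - e^{ikR_in})`` for a cap, where
    h is the distance from the center of curvature.  Used as an independent
    check of the numerical quadrature.
    """
    f0 = f0 if f0 is not None else geom.f0
    z = np.atleast_1d(np.asarray(z_mm, dtype=float)) * 1e-3  # along axis, from apex
    F = geom.focal_distance * 1e-3
    k = 2 * np.pi * f0 / c

    def cap_term(theta_edge):
        # R at the cap edge for a field point at axial distance h from the center
        hdist = F - z  # signed: positive between apex and focus
        return np.sqrt(F**2 + hdist**2 - 2 * F * hdist * np.cos(theta_edge))

    hdist = F - z
    if np.any(np.abs(hdist) < 1e-9):
        raise ValueError("closed form is singular exactly at the focus; evaluate nearby instead")
    R_in = cap_term(geom.inner_half_angle)
    R_out = cap_term(geom.outer_half_angle)
    return -(rho * c * u0) * (F / hdist) * (np.exp(1j * k * R_out) - np.exp(1j * k * R_in))


def point_source_field(src_points_mm, strengths, field_points_mm, f0, c, ndim=2):
    """Free-space Green's-function superposition for mass sources.

    ``strengths`` are the complex amplitudes of the integrated mass-source
    rate of each source element (the solver's per-voxel amplitude times the
    voxel volume).  Solves ``(grad^2 + k^2) p = i w S delta`` per element:
    Hankel kernel in 2D, spherical kernel in 3D.  This is the discrete
    quadrature of the Rayleigh integral over the solver's own source
    voxelization, so it shares the source geometry error with the solver
    and isolates the propagation physics.
    """
    src = np.atleast_2d(np.asarray(src_points_mm, dtype=float)) * 1e-3
    pts = np.atleast_2d(np.asarray(field_points_mm, dtype=float)) * 1e-3
    S = np.broadcast_to(np.asarray(strengths, dtype=complex), (len(src),))
    k = 2 * np.pi * f0 / c
    R = np.linalg.norm(pts[:, None, :] - src[None, :, :], axis=2)
    R = np.maximum(R, 1e-9)
    w = 2 * np.pi * f0
    if ndim == 2:
        G = (1j / 4) * special.hankel1(0, k * R)
    elif ndim == 3:
        G = np.exp(1j * k * R) / (4 * np.pi * R)
    else:
        raise ValueError("ndim must be 2 or 3")
    return -1j * w * np.sum(S[None, :] * G, axis=1)


def measure_layer_transmission(
    thickness_voxels: int = 8,
    mode: int = 0,
    dx_mm: float = 0.4,
    grid_shape=(300, 128),
    f0: float = 250e3,
    c_outer: float = 1500.0,
    rho_outer: float = 1000.0,
    c_layer: float = 3000.0,
    rho_layer: float = 2200.0,
    n_cycles: float = 40.0,
):
    """Measure plane-wave transmission through a flat layer with the solver.

    A phased line source in a laterally periodic 2D domain launches an
    oblique plane wave; periodicity quantizes the lateral wavenumber, so the
    realized incidence angle is ``asin(mode * lambda / L_y)``.  Transmission
    is the ratio of the f0 amplitudes (quadrature-demodulated at probe
    points behind the layer) between a run with the layer and a free-field
    reference, which cancels the source coupling exactly.  Returns
    ``(T_measured, incidence_deg)`` for comparison against
    :func:`layer_transmission_coefficient`.
    """
    nx, ny = grid_shape
    lam_mm = c_outer / f0 * 1e3
    sin_th = mode * lam_mm / (ny * dx_mm)
    if not 0 <= sin_th < 1:
        raise ValueError("mode is too high for this domain: no propagating angle")
    theta = float(np.degrees(np.arcsin(sin_th)))
    i_src, i_layer, i_meas = 40, nx // 2, nx // 2 + thickness_voxels + 50
    ys = np.arange(ny)
    src = GridSource(
        indices=np.stack([np.full(ny, i_src), ys], axis=1),
        delays=sin_th * (ys * dx_mm * 1e-3) / c_outer,
    )
    cfg = SimulationConfig(
        f0=f0,
        n_cycles=n_cycles,
        pml_thickness=30,
        pml_alpha=1.0,
        periodic_axes=(1,),
        t_end=(n_cycles / f0) + 50e-6,
    )
    probes = [[i_meas, j] for j in range(0, ny, max(1, ny // 8))]

    def one(with_layer):
        c = np.full(grid_shape, c_outer)
        rho = np.full(grid_shape, rho_outer)
        if with_layer:
            c[i_layer : i_layer + thickness_voxels, :] = c_layer
            rho[i_layer : i_layer + thickness_voxels, :] = rho_layer
        med = AcousticMediumMap(c, rho, np.zeros(grid_shape), (dx_mm, dx_mm))
        field = simulate(med, src, cfg, probes=probes)
        t_arr = (i_meas - i_src) * dx_mm * 1e-3 / (c_outer * np.cos(np.radians(theta)))
        amps = [
            tone_amplitude(field.probe_traces[:, k], field.probe_dt, f0, t_arr + 40e-6, 12)
            for k in range(field.probe_traces.shape[1])
        ]
        return float(np.mean(amps))

    return one(True) / one(False), theta


def layer_transmission_coefficient(
    c1: float,
    rho1: float,
    c2: float,
    rho2: float,
    thickness_mm: float,
    f: float,
    incidence_from_normal_deg: float = 0.0,
) -> complex:
    """Plane-wave pressure transmission through a fluid layer.

    Classic three-medium (outer medium - layer - outer medium) result with
    interference across the layer:
    ``T = 1 / (cos phi - (i/2)(Z2/Z1 + Z1/Z2) sin phi)`` with
    ``phi = k2 cos(theta2) d`` and angle-dependent impedances
    ``Z = rho c / cos(theta)``.  Beyond the critical angle the layer wave
    is evanescent (tunnelling); the same expression holds with a complex
    angle and a warning is emitted.  The trivial through-layer propagation
    phase is omitted; ``abs()`` gives the amplitude ratio.
    """
    if thickness_mm < 0 or f <= 0:
        raise ValueError("thickness must be non-negative and frequency positive")
    th1 = np.deg2rad(incidence_from_normal_deg)
    s2 = (c2 / c1) * np.sin(th1)
    if abs(s2) > 1:
        warnings.warn(
            f"incidence {incidence_from_normal_deg:.1f} deg is beyond the critical angle; "
            "layer wave is evanescent"
        )
    cos1 = np.cos(th1)
    cos2 = np.sqrt(complex(1.0 - s2**2))
    Z1 = rho1 * c1 / cos1
    Z2 = rho2 * c2 / cos2
    k2 = 2 * np.pi * f / c2
    phi = k2 * cos2 * thickness_mm * 1e-3
    return complex(1.0 / (np.cos(phi) - 0.5j * (Z2 / Z1 + Z1 / Z2) * np.sin(phi)))
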