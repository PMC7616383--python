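"""Explicit finite-difference solver for the 2D acoustic wave equation.

The scheme is second-order in time and tenth-order in space, on a regular
grid, with an absorbing sponge layer implemented as a first-order damping
term ``u_tt + 2*eta*u_t = c^2 (lap(u) + s)``. Discretised with centred
differences::

    u[n+1] = a * (2 u[n] + dt^2 c^2 (L u[n] + s[n])) - a*b * u[n-1]

with ``a = 1/(1 + eta*dt)`` and ``b = 1 - eta*dt``. Keeping the damping in
this symmetric central-difference form matters: the time-reversed
propagation of the exact transpose of this recursion is again a damped
wave propagation, which is what makes the discrete adjoint in
:mod:`svifwi.adjoint` exact to machine precision.

A module-level :data:`simulation_counter` counts every wave propagation
(forward and adjoint); the variance update of the inference loop is
required to perform none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .containers import (
    AcquisitionGeometry,
    DensityModel,
    ShotGather,
    VelocityModel,
    Wavelet,
    WavefieldStore,
)

__all__ = [
    "SolverConfig",
    "StabilityReport",
    "check_stability",
    "laplacian",
    "simulate_shot",
    "simulate_shot_variable_density",
    "lowpass_filter",
    "sponge_profile",
    "simulation_counter",
    "COURANT_LIMIT",
]

# 10th-order centred stencils (exact rational weights).
_D2_WEIGHTS = np.array(
    [1 / 3150, -5 / 1008, 5 / 126, -5 / 21, 5 / 3,
     -5269 / 1800,
     5 / 3, -5 / 21, 5 / 126, -5 / 1008, 1 / 3150])
_D1_WEIGHTS = np.array(
    [-1 / 1260, 5 / 504, -5 / 84, 5 / 21, -5 / 6, 0.0,
     5 / 6, -5 / 21, 5 / 84, -5 / 504, 1 / 1260])

# Worst-case eigenvalue bound of the 2D stencil gives the explicit-scheme
# Courant limit  c*dt/dx <= 2 / sqrt(2 * sum|w|).
_ABS_SUM_1D = float(np.abs(_D2_WEIGHTS).sum())
COURANT_LIMIT = 2.0 / np.sqrt(2.0 * _ABS_SUM_1D)

#: Number of wave propagations executed since import (instrumentation).
simulation_counter = 0


def laplacian(field: np.ndarray, dx: float) -> np.ndarray:
    """Tenth-order centred approximation of the 2D Laplacian.

    Cells within five points of the edge see an implicit zero padding
    (homogeneous Dirichlet); in practice these cells always lie inside
    the absorbing sponge. Zero padding keeps the operator symmetric,
    which the exact discrete adjoint relies on.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2 or min(field.shape) < 11:
        raise ValueError("field must be 2D with at least 11 points per axis")
    w = _D2_WEIGHTS / dx**2
    out = correlate1d(field, w, axis=0, mode="constant")
    out += correlate1d(field, w, axis=1, mode="constant")
    return out


def _gradient1d(field: np.ndarray, dx: float, axis: int,
                mode: str = "constant") -> np.ndarray:
    return correlate1d(field, _D1_WEIGHTS / dx, axis=axis, mode=mode)


@dataclass
class SolverConfig:
    """Numerical choices for the time stepper.

    sponge_cells : width of the absorbing taper (cells, each side).
    sponge_strength : dimensionless damping; eta_max = strength * c_ref / L
        with L the sponge width in metres and c_ref the (fixed) reference
        speed. 20 attenuates a normally incident wave by ~e^-7 per
        transit.
    sponge_reference_speed : reference speed (m/s) that scales the
        damping. Fixed, rather than the model maximum, so the absorber
        does not change as the inversion updates the model.
    source_mode : 'nearest' or 'bilinear' injection/extraction stencil.
    check_every : steps between mid-run overflow checks.
    """

    sponge_cells: int = 40
    sponge_strength: float = 20.0
    sponge_reference_speed: float = 1500.0
    source_mode: str = "nearest"
    check_every: int = 50

    def __post_init__(self):
        if self.sponge_cells < 0:
            raise ValueError("sponge_cells must be >= 0")
        if self.source_mode not in ("nearest", "bilinear"):
            raise ValueError("source_mode must be 'nearest' or 'bilinear'")


@dataclass
class StabilityReport:
    courant: float
    courant_limit: float
    stable: bool
    points_per_wavelength: float | None
    dispersion_warning: bool
    dt: float
    dx: float

    def raise_if_unstable(self) -> None:
        if not self.stable:
            raise ValueError(
                f"explicit scheme unstable: Courant number {self.courant:.4f} "
                f"exceeds the stencil limit {self.courant_limit:.4f} "
                f"(dt={self.dt:g} s, dx={self.dx:g} m)")


def check_stability(model: VelocityModel, dt: float,
                    frequency: float | None = None,
                    ppw_threshold: float = 4.0) -> StabilityReport:
    """Courant/dispersion check for the explicit 10th-order scheme.

    ``frequency`` (Hz), when given, is used to compute points per minimum
    wavelength ``c_min / (f * dx)``; a value below ``ppw_threshold``
    raises the dispersion warning flag (informational only).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    c_max = float(model.c.max())
    nu = c_max * dt / model.dx
    ppw = None
    warn = False
    if frequency is not None and frequency > 0:
        ppw = float(model.c.min()) / (frequency * model.dx)
        warn = ppw < ppw_threshold
    return StabilityReport(
        courant=nu, courant_limit=COURANT_LIMIT, stable=nu <= COURANT_LIMIT,
        points_per_wavelength=ppw, dispersion_warning=warn, dt=dt,
        dx=model.dx)


def sponge_profile(shape: tuple[int, int], n_cells: int, strength: float,
                   c_max: float, dx: float, dt: float) -> np.ndarray:
    """Damping coefficient eta (1/s): quadratic ramp into the boundary."""
    nz, nx = shape
    eta = np.zeros(shape)
    if n_cells == 0:
        return eta
    eta_max = strength * c_max / (n_cells * dx)
    if eta_max * dt >= 1.0:
        # keep (1 - eta*dt) positive; cap rather than destabilise
        eta_max = 0.9 / dt
    ramp = (np.arange(n_cells, 0, -1) / n_cells) ** 2 * eta_max
    prof_z = np.zeros(nz)
    prof_z[:n_cells] = np.maximum(prof_z[:n_cells], ramp)
    prof_z[nz - n_cells:] = np.maximum(prof_z[nz - n_cells:], ramp[::-1])
    prof_x = np.zeros(nx)
    prof_x[:n_cells] = np.maximum(prof_x[:n_cells], ramp)
    prof_x[nx - n_cells:] = np.maximum(prof_x[nx - n_cells:], ramp[::-1])
    return np.maximum(prof_z[:, None], prof_x[None, :])


def _point_stencil(model: VelocityModel, pos, mode: str):
    """Grid indices and weights for one physical (z, x) position."""
    if mode == "nearest":
        iz, ix = model.to_index(tuple(pos))
        return np.array([iz]), np.array([ix]), np.array([1.0])
    # bilinear
    fz = (pos[0] - model.origin[0]) / model.dx
    fx = (pos[1] - model.origin[1]) / model.dx
    iz0, ix0 = int(np.floor(fz)), int(np.floor(fx))
    tz, tx = fz - iz0, fx - ix0
    izs, ixs, ws = [], [], []
    for dz, wz in ((0, 1 - tz), (1, tz)):
        for dxi, wx in ((0, 1 - tx), (1, tx)):
            if wz * wx == 0.0:
                continue
            iz, ix = iz0 + dz, ix0 + dxi
            if not (0 <= iz < model.nz and 0 <= ix < model.nx):
                raise ValueError(f"position {pos} falls outside the grid")
            izs.append(iz)
            ixs.append(ix)
            ws.append(wz * wx)
    return np.array(izs), np.array(ixs), np.array(ws)


def _damping_factors(model: VelocityModel, dt: float, config: SolverConfig):
    eta = sponge_profile(model.shape, config.sponge_cells,
                         config.sponge_strength,
                         config.sponge_reference_speed, model.dx, dt)
    a = 1.0 / (1.0 + eta * dt)
    b = 1.0 - eta * dt
    return a, b


def _make_extractor(receivers):
    """Vectorised trace extraction over arbitrary point stencils."""
    n_rec = len(receivers)
    if n_rec == 0:
        return lambda u: np.empty(0)
    iz = np.concatenate([s[0] for s in receivers])
    ix = np.concatenate([s[1] for s in receivers])
    w = np.concatenate([s[2] for s in receivers])
    rec_id = np.concatenate([np.full(len(s[0]), k, dtype=int)
                             for k, s in enumerate(receivers)])
    if len(iz) == n_rec and np.all(w == 1.0):
        return lambda u: u[iz, ix]
    return lambda u: np.bincount(rec_id, weights=u[iz, ix] * w,
                                 minlength=n_rec)


def _check_finite(u: np.ndarray, step: int) -> None:
    m = np.abs(u).max()
    if not np.isfinite(m) or m > 1e30:
        raise RuntimeError(
            f"wave simulation became unstable at step {step} "
            f"(max |u| = {m:g}); check the Courant number and the model")


def _propagate(c2: np.ndarray, a: np.ndarray, b: np.ndarray, dt: float,
               dx: float, nt: int, injections, receivers,
               record_wavefield: bool, check_every: int):
    """Shared forward time loop.

    injections : list of (iz, ix, weights, series) source-density terms.
    receivers : list of (iz, ix, weights) extraction stencils.
    Returns (traces[nt, n_rec], snapshots[nt+1, nz, nx] or None) where
    trace sample n is the field u[n+1] at the receiver, and snapshot n
    is u[n] (snapshot 0 is the zero initial field).
    """
    global simulation_counter
    simulation_counter += 1

    nz, nx = c2.shape
    dt2 = dt * dt
    ab = a * b
    u_prev = np.zeros((nz, nx))
    u_cur = np.zeros((nz, nx))
    traces = np.zeros((nt, len(receivers)))
    snaps = np.zeros((nt + 1, nz, nx)) if record_wavefield else None

    inv_dx2 = 1.0 / dx**2
    w2 = _D2_WEIGHTS * inv_dx2
    extract = _make_extractor(receivers)
    for n in range(nt):
        lap = correlate1d(u_cur, w2, axis=0, mode="constant")
        lap += correlate1d(u_cur, w2, axis=1, mode="constant")
        for iz, ix, w, series in injections:
            lap[iz, ix] += w * (series[n] * inv_dx2)
        u_next = a * (2.0 * u_cur + dt2 * c2 * lap) - ab * u_prev
        traces[n] = extract(u_next)
        if record_wavefield:
            snaps[n + 1] = u_next
        u_prev, u_cur = u_cur, u_next
        if (n + 1) % check_every == 0:
            _check_finite(u_cur, n + 1)
    _check_finite(u_cur, nt)
    return traces, snaps


def simulate_shot(model: VelocityModel, geometry: AcquisitionGeometry,
                  wavelet: Wavelet, source_index: int = 0,
                  record_wavefield: bool = False,
                  config: SolverConfig | None = None):
    """Propagate one shot through the constant-density acoustic equation.

    The simulation runs for ``wavelet.nt`` steps of ``wavelet.dt``
    (pad the wavelet with zeros to set the record length). Returns
    ``(ShotGather, WavefieldStore | None)``.
    """
    config = config or SolverConfig()
    check_stability(model, wavelet.dt).raise_if_unstable()
    a, b = _damping_factors(model, wavelet.dt, config)
    c2 = model.c ** 2

    siz, six, sw = _point_stencil(model, geometry.sources[source_index],
                                  config.source_mode)
    injections = [(siz, six, sw, wavelet.samples)]
    receivers = [_point_stencil(model, p, config.source_mode)
                 for p in geometry.receivers]

    traces, snaps = _propagate(c2, a, b, wavelet.dt, model.dx, wavelet.nt,
                               injections, receivers, record_wavefield,
                               config.check_every)
    gather = ShotGather(traces, wavelet.dt, source_index,
                        source_positions=geometry.sources[[source_index]],
                        receiver_positions=geometry.receivers)
    store = None
    if record_wavefield:
        store = WavefieldStore(snaps, wavelet.dt, decimation=1,
                               meta={"a": a, "b": b, "dx": model.dx,
                                     "kind": "forward"})
    return gather, store


def simulate_shot_variable_density(model: VelocityModel,
                                   density: DensityModel,
                                   geometry: AcquisitionGeometry,
                                   wavelet: Wavelet, source_index: int = 0,
                                   config: SolverConfig | None = None) -> ShotGather:
    """Variable-density acoustic propagation (pressure formulation).

    Solves ``c^-2 p_tt = lap(p) - grad(ln rho) . grad(p) + s``, which is
    the div(rho^-1 grad p) operator multiplied through by rho. The
    density-gradient term is discretised with the matching 10th-order
    first-derivative stencil, so with uniform density it vanishes
    identically and the scheme coincides with :func:`simulate_shot` to
    machine precision. Used only for observed-data generation.
    """
    config = config or SolverConfig()
    if density.shape != model.shape:
        raise ValueError("density grid must be conformal with the model")
    check_stability(model, wavelet.dt).raise_if_unstable()

    global simulation_counter
    simulation_counter += 1

    a, b = _damping_factors(model, wavelet.dt, config)
    c2 = model.c ** 2
    dt, dx, nt = wavelet.dt, model.dx, wavelet.nt
    dt2 = dt * dt
    ab = a * b
    # replicate-edge boundary: the density field has no jump at the
    # domain edge, only the inclusions contribute to grad(ln rho)
    ln_rho = np.log(density.rho)
    gz = _gradient1d(ln_rho, dx, axis=0, mode="nearest")
    gx = _gradient1d(ln_rho, dx, axis=1, mode="nearest")
    has_rho_term = bool(np.ptp(density.rho) > 0)

    siz, six, sw = _point_stencil(model, geometry.sources[source_index],
                                  config.source_mode)
    receivers = [_point_stencil(model, p, config.source_mode)
                 for p in geometry.receivers]
    extract = _make_extractor(receivers)

    u_prev = np.zeros(model.shape)
    u_cur = np.zeros(model.shape)
    traces = np.zeros((nt, geometry.n_receivers))
    inv_dx2 = 1.0 / dx**2
    for n in range(nt):
        rhs = laplacian(u_cur, dx)
        if has_rho_term:
            rhs -= gz * _gradient1d(u_cur, dx, axis=0)
            rhs -= gx * _gradient1d(u_cur, dx, axis=1)
        rhs[siz, six] += sw * (wavelet.samples[n] * inv_dx2)
        u_next = a * (2.0 * u_cur + dt2 * c2 * rhs) - ab * u_prev
        traces[n] = extract(u_next)
        u_prev, u_cur = u_cur, u_next
        if (n + 1) % config.check_every == 0:
            _check_finite(u_cur, n + 1)
    _check_finite(u_cur, nt)
    return ShotGather(traces, dt, source_index,
                      source_positions=geometry.sources[[source_index]],
                      receiver_positions=geometry.receivers)


def _lowpass_response(nt: int, dt: float, cutoff: float,
                      order: int = 8) -> np.ndarray:
    """Real Butterworth-magnitude transfer function on the rFFT grid."""
    nyquist = 0.5 / dt
    if not 0 < cutoff < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={nyquist:g} Hz), got {cutoff:g}")
    f = np.fft.rfftfreq(nt, dt)
    return 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))


def lowpass_filter(gather: ShotGather, cutoff: float,
                   order: int = 8) -> ShotGather:
    """Zero-phase low-pass filter applied trace-wise.

    Implemented as multiplication by a real Butterworth magnitude
    response in the frequency domain. A real, even transfer function
    makes the filter matrix exactly symmetric, which the misfit gradient
    exploits (the adjoint of the filter is the filter itself). Applied
    identically to observed and predicted data in the multiscale
    inversion loop.
    """
    h = _lowpass_response(gather.nt, gather.dt, cutoff, order)
    filtered = np.fft.irfft(h[:, None] * np.fft.rfft(gather.traces, axis=0),
                            n=gather.nt, axis=0)
    return ShotGather(filtered, gather.dt, gather.source_index,
                      gather.source_positions, gather.receiver_positions)
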