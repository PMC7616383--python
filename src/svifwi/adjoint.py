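"""Adjoint-state gradient of the waveform misfit.

The misfit for one shot is ``Gamma = 1/2 ||G d - G L(m)||^2`` with G the
zero-phase low-pass filter (identity when no cutoff is given). Its
gradient with respect to the pixel sound speeds is obtained with two
propagations: the forward solve (stored), and a backward solve of the
*exact algebraic transpose* of the forward recursion driven by the
residual injected at the receivers. The zero-lag correlation of the two
stored wavefields then yields the gradient image that the variational
inference loop recycles for both the mean and the standard-deviation
update.

Writing the forward step as ``u[n+1] = A u[n] + B u[n-1] + g[n]`` with
``A = diag(a) (2 I + dt^2 diag(c^2) L)`` and ``B = -diag(a b)``, the
adjoint recursion is ``lam[m] = A^T lam[m+1] + B^T lam[m+2] + R^T r[m-1]``
run backwards in time, where ``A^T v = 2 a v + dt^2 L (c^2 a v)``. Because
this is a true transpose (damping applied before the Laplacian, Laplacian
of ``c^2 * v`` rather than ``c^2 * L v``), the dot-product identity
``<F s, r> = <s, F^T r>`` holds to machine precision, and the assembled
gradient matches finite differences of the misfit to first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from . import solver as _solver
from .containers import (
    AcquisitionGeometry,
    ShotGather,
    VelocityModel,
    Wavelet,
    WavefieldStore,
)
from .solver import (
    SolverConfig,
    _damping_factors,
    _check_finite,
    _lowpass_response,
    _point_stencil,
    _D2_WEIGHTS,
    check_stability,
    simulate_shot,
)

__all__ = [
    "Residual",
    "GradientImage",
    "backpropagate_adjoint",
    "imaging_condition",
    "shot_gradient",
    "extract_source_series",
    "margin_mask",
]


@dataclass
class Residual:
    """Observed-minus-predicted traces, after identical filtering."""

    traces: np.ndarray  # (nt, n_receivers)
    dt: float

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("residual traces must be 2D (nt, n_receivers)")


@dataclass
class GradientImage:
    """Per-pixel misfit derivative d(Gamma)/dc, masked in the sponge."""

    delta_m: np.ndarray
    dx: float

    def __post_init__(self):
        self.delta_m = np.asarray(self.delta_m, dtype=float)
        if not np.all(np.isfinite(self.delta_m)):
            raise ValueError("gradient contains non-finite values")

    def __add__(self, other: "GradientImage") -> "GradientImage":
        return GradientImage(self.delta_m + other.delta_m, self.dx)


def margin_mask(shape: tuple[int, int], margin_cells: int) -> np.ndarray:
    """Boolean mask that is True in the imaging region (sponge excluded)."""
    mask = np.zeros(shape, dtype=bool)
    m = margin_cells
    if m == 0:
        mask[:] = True
    else:
        mask[m:-m, m:-m] = True
    return mask


def backpropagate_adjoint(model: VelocityModel,
                          geometry: AcquisitionGeometry,
                          residual: Residual,
                          config: SolverConfig | None = None) -> WavefieldStore:
    """Solve the transpose propagation driven by the residual.

    The residual trace sample ``r[m-1]`` is injected at the receiver
    stencils while stepping ``m = nt .. 1`` backwards; the returned store
    holds ``lam[m]`` at snapshot index m (snapshot 0 stays zero), aligned
    with the forward store for the zero-lag correlation.
    """
    config = config or SolverConfig()
    if residual.traces.shape[1] != geometry.n_receivers:
        raise ValueError("residual does not conform to the geometry")
    check_stability(model, residual.dt).raise_if_unstable()

    _solver.simulation_counter += 1

    nt = residual.traces.shape[0]
    dt, dx = residual.dt, model.dx
    dt2 = dt * dt
    a, b = _damping_factors(model, dt, config)
    ab = a * b
    c2 = model.c ** 2
    w2 = _D2_WEIGHTS / dx**2

    receivers = [_point_stencil(model, p, config.source_mode)
                 for p in geometry.receivers]
    r_iz = np.concatenate([s[0] for s in receivers])
    r_ix = np.concatenate([s[1] for s in receivers])
    r_w = np.concatenate([s[2] for s in receivers])
    r_id = np.concatenate([np.full(len(s[0]), k, dtype=int)
                           for k, s in enumerate(receivers)])

    snaps = np.zeros((nt + 1, *model.shape))
    lam_next = np.zeros(model.shape)   # lam[m+1]
    lam_next2 = np.zeros(model.shape)  # lam[m+2]
    for m in range(nt, 0, -1):
        v = a * lam_next
        cv = c2 * v
        lam = 2.0 * v - ab * lam_next2
        lam += dt2 * (correlate1d(cv, w2, axis=0, mode="constant")
                      + correlate1d(cv, w2, axis=1, mode="constant"))
        np.add.at(lam, (r_iz, r_ix), r_w * residual.traces[m - 1, r_id])
        snaps[m] = lam
        lam_next2 = lam_next
        lam_next = lam
        if m % config.check_every == 0:
            _check_finite(lam, m)
    return WavefieldStore(snaps, dt, decimation=1,
                          meta={"a": a, "b": b, "dx": dx, "kind": "adjoint"})


def extract_source_series(adjoint_store: WavefieldStore,
                          model: VelocityModel,
                          geometry: AcquisitionGeometry,
                          source_index: int = 0,
                          config: SolverConfig | None = None) -> np.ndarray:
    """Read the adjoint field back at the source stencil.

    Returns the series ``s[n] = dt^2/dx^2 * (c^2 a lam[n+1])`` summed over
    the source stencil, which is the exact transpose ``F^T r`` of the
    wavelet-to-data map evaluated on the injected residual. Used by the
    dot-product (adjoint identity) diagnostics.
    """
    config = config or SolverConfig()
    a = adjoint_store.meta["a"]
    dt = adjoint_store.dt
    iz, ix, w = _point_stencil(model, geometry.sources[source_index],
                               config.source_mode)
    lam = adjoint_store.snapshots  # lam[m] at index m
    c2a = (model.c ** 2 * a)[iz, ix]
    nt = adjoint_store.n_stored - 1
    scale = dt * dt / model.dx**2
    return np.array([
        float((lam[n + 1, iz, ix] * c2a * w).sum()) * scale
        for n in range(nt)])


def imaging_condition(forward: WavefieldStore, adjoint: WavefieldStore,
                      model: VelocityModel,
                      margin_cells: int | None = None) -> GradientImage:
    """Zero-lag correlation of forward and adjoint wavefields.

    Accumulates, over every stored step, the product of the adjoint field
    with the (damped) second time derivative of the forward field,
    weighted by the derivative of the wave operator with respect to sound
    speed; under the ``c^2``-scaled operator used here the weight reduces
    to ``-2/c``. With decimation 1 this is the exact discrete derivative
    d(Gamma)/dc of the misfit the propagator computes.
    """
    if forward.grid_shape != adjoint.grid_shape:
        raise ValueError("forward and adjoint stores live on different grids")
    if forward.n_stored != adjoint.n_stored:
        raise ValueError("forward and adjoint stores are misaligned in time")
    if forward.decimation != 1 or adjoint.decimation != 1:
        raise ValueError("the exact imaging condition requires decimation 1")

    a = forward.meta["a"]
    b = forward.meta["b"]
    u = forward.snapshots       # u[n] at index n, u[0] = 0
    lam = adjoint.snapshots     # lam[m] at index m
    nt = forward.n_stored - 1

    acc = np.zeros(forward.grid_shape)
    inv_a = 1.0 / a
    for n in range(nt):
        ddu = u[n + 1] * inv_a - 2.0 * u[n]
        if n >= 1:
            ddu += b * u[n - 1]
        acc += (a * lam[n + 1]) * ddu
    delta = -(2.0 / model.c) * acc
    if margin_cells is None:
        margin_cells = 0
    delta[~margin_mask(model.shape, margin_cells)] = 0.0
    return GradientImage(delta, model.dx)


def source_illumination(forward: WavefieldStore) -> np.ndarray:
    """Zero-lag autocorrelation of the forward wavefield.

    ``I(x) = sum_t u_p(x, t)^2`` — the diagonal pseudo-Hessian used to
    precondition gradients so that poorly illuminated pixels far from
    the transducers receive comparable update magnitudes.
    """
    return np.sum(forward.snapshots ** 2, axis=0)


def shot_gradient(model: VelocityModel, geometry: AcquisitionGeometry,
                  wavelet: Wavelet, observed: ShotGather,
                  cutoff: float | None = None,
                  config: SolverConfig | None = None,
                  filter_order: int = 8,
                  return_illumination: bool = False):
    """Misfit value and gradient for one shot.

    Runs the forward solve, filters observed and predicted traces
    identically at ``cutoff`` (no filtering when None), forms the
    residual, backpropagates it (filtered once more, because the adjoint
    of the symmetric filter is the filter itself), and applies the
    imaging condition. Returns ``(GradientImage, misfit)`` with
    ``misfit = 1/2 ||G d - G d_p||^2``; descending this misfit means
    stepping along ``-delta_m``.
    """
    config = config or SolverConfig()
    source_index = observed.source_index
    predicted, fwd_store = simulate_shot(model, geometry, wavelet,
                                         source_index,
                                         record_wavefield=True, config=config)
    if observed.traces.shape != predicted.traces.shape:
        raise ValueError(
            f"observed gather shape {observed.traces.shape} does not match "
            f"the simulation {predicted.traces.shape}")

    raw = observed.traces - predicted.traces
    if cutoff is not None:
        h = _lowpass_response(observed.nt, wavelet.dt, cutoff, filter_order)
        spec = np.fft.rfft(raw, axis=0)
        filtered = np.fft.irfft(h[:, None] * spec, n=observed.nt, axis=0)
        misfit = 0.5 * float(np.sum(filtered**2))
        adj_src = np.fft.irfft(h[:, None]**2 * spec, n=observed.nt, axis=0)
    else:
        misfit = 0.5 * float(np.sum(raw**2))
        adj_src = raw

    adj_store = backpropagate_adjoint(model, geometry,
                                      Residual(adj_src, wavelet.dt), config)
    grad = imaging_condition(fwd_store, adj_store, model,
                             margin_cells=config.sponge_cells)
    if return_illumination:
        return grad, misfit, source_illumination(fwd_store)
    return grad, misfit
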