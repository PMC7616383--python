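"""Core data containers for acoustic full-waveform inversion.

Everything is held on a regular 2D grid in (z, x) row-major order with
0-based indices. Physical coordinates are metres; the grid covers the
half-open extent ``[origin, origin + n * dx)`` along each axis. Sound
speeds are m/s, densities g/cm^3, time in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "VelocityModel",
    "DensityModel",
    "Wavelet",
    "AcquisitionGeometry",
    "ShotGather",
    "WavefieldStore",
    "ricker",
]


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2D array, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass
class VelocityModel:
    """Sound-speed model ``c`` on a regular grid.

    Parameters
    ----------
    c : ndarray, shape (nz, nx)
        Sound speed in m/s, strictly positive.
    dx : float
        Grid spacing in metres (isotropic).
    origin : tuple of float
        Physical (z, x) coordinate of grid index (0, 0), metres.
    """

    c: np.ndarray
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.c = _as_2d(self.c, "c")
        if not np.all(self.c > 0):
            raise ValueError("sound speed must be positive everywhere")
        if not self.dx > 0:
            raise ValueError("dx must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.c.shape

    @property
    def nz(self) -> int:
        return self.c.shape[0]

    @property
    def nx(self) -> int:
        return self.c.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (z, x) size of the grid in metres."""
        return (self.nz * self.dx, self.nx * self.dx)

    def to_index(self, pos: tuple[float, float]) -> tuple[int, int]:
        """Nearest-grid-point index of a physical (z, x) position."""
        iz = int(round((pos[0] - self.origin[0]) / self.dx))
        ix = int(round((pos[1] - self.origin[1]) / self.dx))
        if not (0 <= iz < self.nz and 0 <= ix < self.nx):
            raise ValueError(f"position {pos} falls outside the grid")
        return iz, ix

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "w") as f:
                f.create_dataset("c", data=self.c)
                f.attrs["dx"] = self.dx
                f.attrs["origin"] = self.origin
        else:
            np.savez(path, c=self.c, dx=self.dx, origin=self.origin)

    @classmethod
    def load(cls, path) -> "VelocityModel":
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                return cls(f["c"][()], float(f.attrs["dx"]),
                           tuple(f.attrs["origin"]))
        with np.load(path) as z:
            return cls(z["c"], float(z["dx"]), tuple(z["origin"]))


@dataclass
class DensityModel:
    """Mass density ``rho`` (g/cm^3) on the same grid as a VelocityModel."""

    rho: np.ndarray
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.rho = _as_2d(self.rho, "rho")
        if not np.all(self.rho > 0):
            raise ValueError("density must be positive everywhere")
        if not self.dx > 0:
            raise ValueError("dx must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.rho.shape


@dataclass
class Wavelet:
    """Source time signature.

    samples are pressure-source amplitudes at a fixed time step ``dt``;
    ``centre_frequency`` (Hz) is metadata used for dispersion checks.
    """

    samples: np.ndarray
    dt: float
    centre_frequency: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("wavelet contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def nt(self) -> int:
        return self.samples.size

    def scaled(self, a: float) -> "Wavelet":
        return Wavelet(a * self.samples, self.dt, self.centre_frequency)


def ricker(centre_frequency: float, dt: float, nt: int,
           t0: float | None = None) -> Wavelet:
    """Ricker wavelet (negative-normalised second derivative of a Gaussian).

    Parameters
    ----------
    centre_frequency : float
        Peak frequency in Hz.
    dt : float
        Sample interval in seconds.
    nt : int
        Number of samples.
    t0 : float, optional
        Delay of the peak; default ``1.5 / centre_frequency`` so the
        wavelet starts near zero amplitude.
    """
    if t0 is None:
        t0 = 1.5 / centre_frequency
    t = np.arange(nt) * dt - t0
    arg = (np.pi * centre_frequency * t) ** 2
    return Wavelet((1.0 - 2.0 * arg) * np.exp(-arg), dt, centre_frequency)


@dataclass
class AcquisitionGeometry:
    """Physical source and receiver positions.

    Positions are (z, x) in metres. Each position resolves onto the grid
    with a nearest-grid-point stencil (see VelocityModel.to_index).
    """

    sources: np.ndarray
    receivers: np.ndarray

    def __post_init__(self):
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.receivers = np.atleast_2d(np.asarray(self.receivers, dtype=float))
        for name, arr in (("sources", self.sources),
                          ("receivers", self.receivers)):
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must have shape (n, 2)")

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    @property
    def n_receivers(self) -> int:
        return self.receivers.shape[0]

    def source_indices(self, model: VelocityModel) -> list[tuple[int, int]]:
        return [model.to_index(tuple(p)) for p in self.sources]

    def receiver_indices(self, model: VelocityModel) -> list[tuple[int, int]]:
        return [model.to_index(tuple(p)) for p in self.receivers]

    def validate_inside(self, model: VelocityModel, margin_cells: int) -> None:
        """Fail loudly if any position lies in, or outside, the absorbing margin."""
        for name, arr in (("source", self.sources),
                          ("receiver", self.receivers)):
            for p in arr:
                iz, ix = model.to_index(tuple(p))
                if (iz < margin_cells or ix < margin_cells
                        or iz >= model.nz - margin_cells
                        or ix >= model.nx - margin_cells):
                    raise ValueError(
                        f"{name} position {tuple(p)} lies inside the "
                        f"{margin_cells}-cell absorbing margin")

    def replace(self, **kw) -> "AcquisitionGeometry":
        return dataclasses.replace(self, **kw)


@dataclass
class ShotGather:
    """Receiver traces for one source excitation.

    traces has shape (nt, n_receivers); dt is the trace sample interval.
    """

    traces: np.ndarray
    dt: float
    source_index: int = 0
    source_positions: np.ndarray | None = None
    receiver_positions: np.ndarray | None = None

    def __post_init__(self):
        self.traces = _as_2d(self.traces, "traces")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.source_index = int(self.source_index)

    @property
    def nt(self) -> int:
        return self.traces.shape[0]

    @property
    def n_receivers(self) -> int:
        return self.traces.shape[1]

    def save(self, path) -> None:
        """Write to HDF5 (``.h5``/``.hdf5``) or NPZ (anything else)."""
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "w") as f:
                f.create_dataset("traces", data=self.traces)
                f.attrs["dt"] = self.dt
                f.attrs["source_index"] = self.source_index
                if self.source_positions is not None:
                    f.create_dataset("source_positions",
                                     data=self.source_positions)
                if self.receiver_positions is not None:
                    f.create_dataset("receiver_positions",
                                     data=self.receiver_positions)
        else:
            payload = dict(traces=self.traces, dt=self.dt,
                           source_index=self.source_index)
            if self.source_positions is not None:
                payload["source_positions"] = self.source_positions
            if self.receiver_positions is not None:
                payload["receiver_positions"] = self.receiver_positions
            np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "ShotGather":
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                return cls(
                    f["traces"][()], float(f.attrs["dt"]),
                    int(f.attrs["source_index"]),
                    f["source_positions"][()] if "source_positions" in f else None,
                    f["receiver_positions"][()] if "receiver_positions" in f else None,
                )
        with np.load(path) as z:
            return cls(
                z["traces"], float(z["dt"]), int(z["source_index"]),
                z["source_positions"] if "source_positions" in z.files else None,
                z["receiver_positions"] if "receiver_positions" in z.files else None,
            )


@dataclass
class WavefieldStore:
    """Stored pressure-field history for the zero-lag imaging condition.

    ``snapshots[n]`` holds the field u at stored step n. With decimation 1
    (the default everywhere in this package) every time step is stored,
    which is what the discrete-exact gradient requires.
    """

    snapshots: np.ndarray  # (n_stored, nz, nx)
    dt: float
    decimation: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.snapshots = np.asarray(self.snapshots, dtype=float)
        if self.snapshots.ndim != 3:
            raise ValueError("snapshots must have shape (n_stored, nz, nx)")
        if self.decimation < 1:
            raise ValueError("decimation must be >= 1")

    @property
    def n_stored(self) -> int:
        return self.snapshots.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.snapshots.shape[1:]
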