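"""Synthetic phantoms, acquisition arrays, and controlled corruptions.

Provides download-free analogues of the study configurations: a circular
soft-tissue inclusion in a water background observed by a co-located
circular transducer ring (single-element sources/receivers), the
two-transducer rotating acquisition schedule, matched- versus
mismatched-density observed data, and intermittent source-position
errors for artefact experiments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AcquisitionGeometry,
    DensityModel,
    ShotGather,
    VelocityModel,
    Wavelet,
)
from .solver import SolverConfig, simulate_shot, simulate_shot_variable_density

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "CorruptionSpec",
    "make_phantom",
    "circular_array",
    "rotating_transducer_geometry",
    "corrupt_geometry",
    "generate_observed",
]


@dataclass
class Inclusion:
    """A circular inclusion: centre (z, x) in metres, diameter m."""

    centre: tuple[float, float]
    diameter: float
    speed: float
    density: float = 1.010

    def __post_init__(self):
        if self.diameter <= 0 or self.speed <= 0 or self.density <= 0:
            raise ValueError("inclusion diameter, speed, density must be > 0")


@dataclass
class PhantomSpec:
    """Grid plus background and inclusion properties.

    Speeds are m/s, densities g/cm^3. The default values give the
    circular in silico benchmark phantom: a 50 mm circle at 1540 m/s in a
    1500 m/s water background, matched density 1.010 everywhere and
    mismatched density 1.220 inside the circle.
    """

    grid_shape: tuple[int, int] = (200, 200)
    dx: float = 0.5e-3
    background_speed: float = 1500.0
    background_density: float = 1.010
    inclusions: list[Inclusion] = field(default_factory=list)
    origin: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def in_silico_circle(cls, grid_shape=(200, 200), dx=0.5e-3,
                         matched: bool = True) -> "PhantomSpec":
        """The circular phantom: 50 mm inclusion at 1540 m/s centred on
        the grid; mismatched density 1.220 g/cm^3 when ``matched`` is
        False."""
        nz, nx = grid_shape
        centre = ((nz / 2) * dx, (nx / 2) * dx)
        rho = 1.010 if matched else 1.220
        return cls(grid_shape=grid_shape, dx=dx,
                   inclusions=[Inclusion(centre, 50e-3, 1540.0, rho)])

    def digest(self) -> str:
        payload = json.dumps({
            "grid": list(self.grid_shape), "dx": self.dx,
            "bg": [self.background_speed, self.background_density],
            "inc": [[i.centre[0], i.centre[1], i.diameter, i.speed,
                     i.density] for i in self.inclusions]},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CorruptionSpec:
    """Intermittent source-position error applied to data generation only.

    fraction : fraction of sources displaced (ignored when
        ``shot_indices`` is given explicitly).
    offset : displacement magnitude (m) along the array tangent.
    shot_indices : explicit source indices to corrupt, e.g. a contiguous
        angular sector.
    """

    fraction: float = 0.25
    offset: float = 2e-3
    shot_indices: list[int] | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def make_phantom(spec: PhantomSpec) -> tuple[VelocityModel, DensityModel]:
    """Rasterise the inclusions (pixel-centre-in-shape rule)."""
    nz, nx = spec.grid_shape
    z = (np.arange(nz) + 0.0) * spec.dx + spec.origin[0]
    x = (np.arange(nx) + 0.0) * spec.dx + spec.origin[1]
    zz, xx = np.meshgrid(z, x, indexing="ij")
    c = np.full(spec.grid_shape, spec.background_speed)
    rho = np.full(spec.grid_shape, spec.background_density)
    extent_z = spec.origin[0] + nz * spec.dx
    extent_x = spec.origin[1] + nx * spec.dx
    for inc in spec.inclusions:
        r = inc.diameter / 2
        cz, cx = inc.centre
        if (cz - r < spec.origin[0] or cx - r < spec.origin[1]
                or cz + r > extent_z or cx + r > extent_x):
            raise ValueError(f"inclusion at {inc.centre} extends outside "
                             "the grid")
        inside = (zz - cz) ** 2 + (xx - cx) ** 2 <= r ** 2
        c[inside] = inc.speed
        rho[inside] = inc.density
    return (VelocityModel(c, spec.dx, spec.origin),
            DensityModel(rho, spec.dx, spec.origin))


def circular_array(n: int, diameter: float,
                   centre: tuple[float, float]) -> AcquisitionGeometry:
    """n co-located single-element sources/receivers equally spaced on a
    circle (angles measured from the +x axis, counter-clockwise)."""
    if n < 1:
        raise ValueError("need at least one transducer")
    theta = 2 * np.pi * np.arange(n) / n
    r = diameter / 2
    pos = np.column_stack([centre[0] + r * np.sin(theta),
                           centre[1] + r * np.cos(theta)])
    return AcquisitionGeometry(sources=pos, receivers=pos.copy())


def rotating_transducer_geometry(n_positions: int = 16,
                                 elements_per_transducer: int = 24,
                                 exclusion: int = 2,
                                 diameter: float = 150e-3,
                                 centre: tuple[float, float] = (0.0, 0.0),
                                 element_pitch: float = 0.3e-3):
    """Shot schedule of the two-transducer rotating acquisition.

    For each of ``n_positions`` source placements on the ring, the
    receiver transducer visits every position except the source's own
    and ``exclusion`` neighbours on each side. Each element of the
    source transducer fires in turn, so the schedule enumerates
    ``n_positions * elements_per_transducer`` sources, each paired with
    the allowed receiver positions.

    Returns ``(geometry, schedule)`` where geometry holds all element
    positions (sources then the same elements as receivers) and
    schedule is a list of dicts with the source element index and the
    allowed receiver position indices.
    """
    if n_positions <= 2 * exclusion + 1:
        raise ValueError("n_positions must exceed 2*exclusion + 1")
    r = diameter / 2
    pos_angle = 2 * np.pi * np.arange(n_positions) / n_positions
    elements = []
    for th in pos_angle:
        # elements laid out along the local tangent
        tangent = np.array([np.cos(th), -np.sin(th)])
        centre_pos = np.array([centre[0] + r * np.sin(th),
                               centre[1] + r * np.cos(th)])
        offs = (np.arange(elements_per_transducer)
                - (elements_per_transducer - 1) / 2) * element_pitch
        elements.append(centre_pos[None, :] + offs[:, None] * tangent)
    elements = np.concatenate(elements)  # (n_positions*epp, 2)

    allowed = []
    for p in range(n_positions):
        banned = {(p + d) % n_positions
                  for d in range(-exclusion, exclusion + 1)}
        allowed.append([q for q in range(n_positions) if q not in banned])

    schedule = []
    for p in range(n_positions):
        for e in range(elements_per_transducer):
            schedule.append({
                "source_element": p * elements_per_transducer + e,
                "source_position": p,
                "receiver_positions": allowed[p],
            })
    geometry = AcquisitionGeometry(sources=elements,
                                   receivers=elements.copy())
    return geometry, schedule


def corrupt_geometry(geometry: AcquisitionGeometry, spec: CorruptionSpec,
                     rng: np.random.Generator,
                     centre: tuple[float, float] | None = None
                     ) -> tuple[AcquisitionGeometry, np.ndarray]:
    """Displace a subset of source positions along the array tangent.

    The corruption models a positioning error in the *acquisition*: it
    is applied when generating observed data, never to the geometry the
    inversion assumes. Returns the corrupted geometry and the indices
    of the affected sources.
    """
    sources = geometry.sources.copy()
    n = geometry.n_sources
    if spec.shot_indices is not None:
        idx = np.asarray(sorted(spec.shot_indices), dtype=int)
    else:
        k = int(round(spec.fraction * n))
        idx = np.sort(rng.choice(n, size=k, replace=False))
    if centre is None:
        centre = tuple(sources.mean(axis=0))
    for i in idx:
        radial = sources[i] - np.asarray(centre)
        norm = np.linalg.norm(radial)
        if norm == 0:
            continue
        tangent = np.array([-radial[1], radial[0]]) / norm
        sources[i] = sources[i] + spec.offset * tangent
    return geometry.replace(sources=sources), idx


def generate_observed(velocity: VelocityModel, density: DensityModel,
                      geometry: AcquisitionGeometry, wavelet: Wavelet,
                      matched_physics: bool = True,
                      solver_config: SolverConfig | None = None,
                      time_refinement: int = 2,
                      progress=None) -> list[ShotGather]:
    """Simulate observed gathers for every source.

    matched physics -> constant-density solver; mismatched -> the
    variable-density solver on the same sound-speed model. To avoid
    committing the inverse crime, the observed data are simulated on a
    time axis refined by ``time_refinement`` and subsampled back onto
    the inversion's time grid (set refinement to 1 to disable).
    """
    solver_config = solver_config or SolverConfig()
    k = int(time_refinement)
    if k < 1:
        raise ValueError("time_refinement must be >= 1")
    if k == 1:
        fine_wavelet = wavelet
    else:
        # resample the wavelet analytically cheap: linear interpolation is
        # enough because the source is smooth and well sampled
        t_coarse = np.arange(wavelet.nt) * wavelet.dt
        t_fine = np.arange(wavelet.nt * k) * (wavelet.dt / k)
        fine_wavelet = Wavelet(np.interp(t_fine, t_coarse, wavelet.samples),
                               wavelet.dt / k, wavelet.centre_frequency)

    gathers = []
    for s in range(geometry.n_sources):
        if matched_physics:
            g, _ = simulate_shot(velocity, geometry, fine_wavelet, s,
                                 config=solver_config)
        else:
            g = simulate_shot_variable_density(velocity, density, geometry,
                                               fine_wavelet, s,
                                               config=solver_config)
        traces = g.traces[k - 1::k][:wavelet.nt] if k > 1 else g.traces
        gathers.append(ShotGather(traces, wavelet.dt, s,
                                  source_positions=geometry.sources[[s]],
                                  receiver_positions=geometry.receivers))
        if progress is not None:
            progress(s)
    return gathers
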