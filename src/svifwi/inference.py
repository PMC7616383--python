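"""Stochastic variational inference for full-waveform inversion.

The posterior over the pixel sound speeds is approximated by a
mean-field Gaussian with mean image ``mu`` and *signed* standard
deviation image ``sigma`` (the variance image is ``sigma**2``). Each
iteration draws one standard-normal field ``eps``, forms the
reparameterised sample ``m = mu + sigma * eps``, computes a single
adjoint-state gradient ``delta_m`` of the data misfit at that sample,
and then performs two updates that share the gradient::

    mu    <- mu    - alpha * delta_m
    sigma <- sigma - alpha * (eps * delta_m)

The standard-deviation update is a pure elementwise product of two
images — no wave simulation occurs inside it — which is what makes the
pixel-wise uncertainty estimate essentially free. With ``eps`` forced to
zero the loop reduces exactly to deterministic FWI.

The user-facing surface is :class:`SVIWaveTomography` (a model object
built from observed shot gathers) whose :meth:`~SVIWaveTomography.fit`
returns :class:`SVIWaveTomographyResults`.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np

from .adjoint import GradientImage, margin_mask, shot_gradient
from .containers import AcquisitionGeometry, ShotGather, VelocityModel, Wavelet
from .solver import SolverConfig

__all__ = [
    "PriorSpec",
    "VariationalParams",
    "SampleDraw",
    "InversionConfig",
    "InversionReport",
    "init_from_prior",
    "sample_model",
    "update_mean",
    "update_sigma",
    "variance_image",
    "run_inversion",
    "run_fwi",
    "SVIWaveTomography",
    "SVIWaveTomographyResults",
]


@dataclass
class PriorSpec:
    """Mean-field Gaussian prior; used only to start the reconstruction.

    mu_prior is m/s (scalar or grid), var_prior is (m/s)^2.
    """

    mu_prior: float | np.ndarray = 1480.0
    var_prior: float | np.ndarray = 4.0

    def __post_init__(self):
        if np.any(np.asarray(self.var_prior) < 0):
            raise ValueError("prior variance must be non-negative")


@dataclass
class VariationalParams:
    """Per-pixel mean and signed standard deviation of the posterior."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must share a shape")
        if not (np.all(np.isfinite(self.mu))
                and np.all(np.isfinite(self.sigma))):
            raise ValueError("variational parameters must be finite")

    def copy(self) -> "VariationalParams":
        return VariationalParams(self.mu.copy(), self.sigma.copy())


@dataclass
class SampleDraw:
    """One reparameterised draw ``model_sample = mu + sigma * eps``."""

    epsilon: np.ndarray
    model_sample: np.ndarray
    clipped: int = 0


def init_from_prior(prior: PriorSpec, grid_shape: tuple[int, int]
                    ) -> VariationalParams:
    """Broadcast the prior onto the grid: mu = mu_prior, sigma = sqrt(var)."""
    mu = np.broadcast_to(np.asarray(prior.mu_prior, dtype=float),
                         grid_shape).copy()
    sigma = np.sqrt(np.broadcast_to(np.asarray(prior.var_prior, dtype=float),
                                    grid_shape)).copy()
    return VariationalParams(mu, sigma)


def sample_model(params: VariationalParams, rng: np.random.Generator,
                 clip: tuple[float, float] | None = None,
                 deterministic: bool = False) -> SampleDraw:
    """Draw eps ~ N(0, I) per pixel and form mu + sigma * eps.

    ``deterministic`` forces eps to zero (the draw still consumes the
    generator so deterministic and stochastic runs stay aligned). The
    sample is clipped to the physical band ``clip`` before propagation;
    clip events are counted, never hidden.
    """
    eps = rng.standard_normal(params.mu.shape)
    if deterministic:
        eps = np.zeros_like(eps)
    sample = params.mu + params.sigma * eps
    clipped = 0
    if clip is not None:
        lo, hi = clip
        clipped = int(np.count_nonzero((sample < lo) | (sample > hi)))
        if clipped:
            sample = np.clip(sample, lo, hi)
    return SampleDraw(eps, sample, clipped)


def update_mean(params: VariationalParams, gradient: GradientImage,
                step: float) -> VariationalParams:
    """Descend the misfit: mu <- mu - step * delta_m; sigma untouched."""
    if gradient.delta_m.shape != params.mu.shape:
        raise ValueError("gradient shape does not match the parameters")
    return VariationalParams(params.mu - step * gradient.delta_m,
                             params.sigma)


def update_sigma(params: VariationalParams, gradient: GradientImage,
                 draw: SampleDraw, step: float) -> VariationalParams:
    """sigma <- sigma - step * (eps * delta_m), recycling the gradient.

    A pure elementwise product: the no-cost uncertainty update. No wave
    simulation may occur here (instrumented by the solver's propagation
    counter in the test suite).
    """
    if gradient.delta_m.shape != draw.epsilon.shape:
        raise ValueError("draw and gradient shapes do not match")
    if gradient.delta_m.shape != params.sigma.shape:
        raise ValueError("gradient shape does not match the parameters")
    return VariationalParams(
        params.mu, params.sigma - step * draw.epsilon * gradient.delta_m)


def variance_image(params: VariationalParams) -> np.ndarray:
    """Pixel-wise variance: the square of the signed sigma image."""
    return params.sigma ** 2


@dataclass
class InversionConfig:
    """Settings of the inversion loop.

    cutoff : low-pass pass-band (Hz) applied to observed and predicted
        data each iteration (multiscale inversion); None disables it.
    step_fraction : the step size alpha is scaled once so that the first
        mean update's max-norm equals this fraction of the prior mean,
        then held fixed; the same alpha serves both updates.
    epochs : full passes over the source list when ``iterations`` is not
        given explicitly.
    batch_size : sources per iteration, deterministic round-robin;
        default ceil(n_sources / 51).
    mc_samples : Monte-Carlo draws per iteration (1 reproduces the
        single-sample algorithm; >1 averages gradients).
    clip : physical band (m/s) applied to model samples before
        propagation, protecting solver stability.
    precondition : divide the batch gradient by the source illumination
        (diagonal pseudo-Hessian) before both updates, equalising update
        magnitudes between well and poorly illuminated pixels;
        ``precondition_eps`` regularises the division as a fraction of
        the peak illumination.
    """

    cutoff: float | None = 700e3
    step_fraction: float = 0.005
    precondition: bool = True
    precondition_eps: float = 1e-3
    epochs: int = 2
    iterations: int | None = None
    batch_size: int | None = None
    mc_samples: int = 1
    clip: tuple[float, float] | None = (1300.0, 1800.0)
    seed: int = 0
    deterministic: bool = False
    early_stop_slope_tol: float | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)

    def resolve_schedule(self, n_sources: int) -> tuple[int, int]:
        batch = self.batch_size or max(1, math.ceil(n_sources / 51))
        if self.iterations is not None:
            n_iter = self.iterations
        else:
            n_iter = self.epochs * math.ceil(n_sources / batch)
        return n_iter, batch


@dataclass
class InversionReport:
    """Per-iteration log plus the final variational images."""

    misfit: np.ndarray
    mean_variance: np.ndarray
    batches: list
    clip_events: np.ndarray
    seed: int
    step_size: float
    mu: np.ndarray
    sigma: np.ndarray
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)
    config: dict = field(default_factory=dict)
    wall_time: float = 0.0

    @property
    def n_iterations(self) -> int:
        return len(self.misfit)

    @property
    def variance(self) -> np.ndarray:
        return self.sigma ** 2

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            payload = {
                "misfit": self.misfit.tolist(),
                "mean_variance": self.mean_variance.tolist(),
                "batches": [list(map(int, b)) for b in self.batches],
                "clip_events": self.clip_events.tolist(),
                "seed": self.seed, "step_size": self.step_size,
                "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
                "dx": self.dx, "origin": list(self.origin),
                "config": self.config, "wall_time": self.wall_time,
            }
            path.write_text(json.dumps(payload))
            return
        with h5py.File(path, "w") as f:
            for name in ("misfit", "mean_variance", "clip_events",
                         "mu", "sigma"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("batches",
                             data=np.array([list(b) for b in self.batches]))
            f.attrs["seed"] = self.seed
            f.attrs["step_size"] = self.step_size
            f.attrs["dx"] = self.dx
            f.attrs["origin"] = self.origin
            f.attrs["wall_time"] = self.wall_time
            f.attrs["config"] = json.dumps(self.config)

    @classmethod
    def load(cls, path) -> "InversionReport":
        path = Path(path)
        if path.suffix == ".json":
            p = json.loads(path.read_text())
            return cls(np.asarray(p["misfit"]), np.asarray(p["mean_variance"]),
                       [list(b) for b in p["batches"]],
                       np.asarray(p["clip_events"]), p["seed"],
                       p["step_size"], np.asarray(p["mu"]),
                       np.asarray(p["sigma"]), p["dx"],
                       tuple(p["origin"]), p["config"], p["wall_time"])
        with h5py.File(path, "r") as f:
            return cls(f["misfit"][()], f["mean_variance"][()],
                       [list(b) for b in f["batches"][()]],
                       f["clip_events"][()], int(f.attrs["seed"]),
                       float(f.attrs["step_size"]), f["mu"][()],
                       f["sigma"][()], float(f.attrs["dx"]),
                       tuple(f.attrs["origin"]),
                       json.loads(f.attrs["config"]),
                       float(f.attrs["wall_time"]))


def _config_dict(config: InversionConfig) -> dict:
    d = asdict(config)
    d["clip"] = list(config.clip) if config.clip is not None else None
    return d


def run_inversion(observed: list[ShotGather],
                  geometry: AcquisitionGeometry,
                  wavelet: Wavelet,
                  grid_shape: tuple[int, int],
                  dx: float,
                  config: InversionConfig | None = None,
                  prior: PriorSpec | None = None,
                  origin: tuple[float, float] = (0.0, 0.0),
                  checkpoint_path=None,
                  checkpoint_every: int = 0,
                  callback=None) -> InversionReport:
    """The SVI-FWI loop.

    Per iteration: select the next round-robin source batch, draw one
    eps field, build the model sample, sum the shot gradients over the
    batch at the configured low-pass cutoff, then apply the mean update
    followed by the sigma update with the same gradient and draw. The
    logged mean variance averages sigma^2 over the imaging region (the
    absorbing margin, where the gradient is masked, is excluded).

    ``checkpoint_path`` + ``checkpoint_every`` enable resumable runs: the
    generator state is saved with the images, so a resumed run continues
    bit-identically.
    """
    config = config or InversionConfig()
    prior = prior or PriorSpec()
    if len(observed) != geometry.n_sources:
        raise ValueError("need one observed gather per source")
    n_iter, batch = config.resolve_schedule(geometry.n_sources)
    t_start = time.perf_counter()

    params = init_from_prior(prior, grid_shape)
    rng = np.random.default_rng(config.seed)
    misfits, mean_vars, batches = [], [], []
    clip_events = []
    alpha = None
    start_iter = 0

    if checkpoint_path is not None and Path(checkpoint_path).exists():
        ck = np.load(checkpoint_path, allow_pickle=False)
        params = VariationalParams(ck["mu"], ck["sigma"])
        rng.bit_generator.state = json.loads(str(ck["rng_state"]))
        start_iter = int(ck["iteration"])
        alpha = float(ck["alpha"]) if np.isfinite(ck["alpha"]) else None
        misfits = list(ck["misfit"])
        mean_vars = list(ck["mean_variance"])
        clip_events = list(ck["clip_events"])
        batches = [list(b) for b in ck["batches"]]

    interior = margin_mask(grid_shape, config.solver.sponge_cells)
    by_source = {g.source_index: g for g in observed}

    for it in range(start_iter, n_iter):
        batch_sources = [(it * batch + j) % geometry.n_sources
                         for j in range(batch)]
        grad_mean = np.zeros(grid_shape)
        sigma_grad = np.zeros(grid_shape)
        gamma = 0.0
        clipped = 0
        for _ in range(config.mc_samples):
            draw = sample_model(params, rng, config.clip,
                                config.deterministic)
            clipped += draw.clipped
            model_i = VelocityModel(draw.model_sample, dx, origin)
            delta = np.zeros(grid_shape)
            illum = np.zeros(grid_shape)
            for s in batch_sources:
                g, m, il = shot_gradient(model_i, geometry, wavelet,
                                         by_source[s], cutoff=config.cutoff,
                                         config=config.solver,
                                         return_illumination=True)
                delta += g.delta_m
                illum += il
                gamma += m
            if config.precondition:
                delta = delta / (illum
                                 + config.precondition_eps * illum.max())
            grad_mean += delta
            sigma_grad += draw.epsilon * delta
        grad_mean /= config.mc_samples
        sigma_grad /= config.mc_samples
        gamma /= config.mc_samples

        if alpha is None:
            gmax = float(np.abs(grad_mean).max())
            mu_scale = float(np.abs(np.asarray(prior.mu_prior)).max())
            alpha = (config.step_fraction * mu_scale / gmax
                     if gmax > 0 else 0.0)

        grad = GradientImage(grad_mean, dx)
        params = update_mean(params, grad, alpha)
        if not config.deterministic:
            params = VariationalParams(
                params.mu, params.sigma - alpha * sigma_grad)

        misfits.append(gamma)
        mean_vars.append(float(np.mean(params.sigma[interior] ** 2)))
        batches.append(batch_sources)
        clip_events.append(clipped)
        if callback is not None:
            callback(it, gamma, mean_vars[-1])

        if (checkpoint_path is not None and checkpoint_every
                and (it + 1) % checkpoint_every == 0):
            np.savez(checkpoint_path, mu=params.mu, sigma=params.sigma,
                     rng_state=json.dumps(rng.bit_generator.state),
                     iteration=it + 1,
                     alpha=alpha if alpha is not None else np.nan,
                     misfit=np.array(misfits),
                     mean_variance=np.array(mean_vars),
                     clip_events=np.array(clip_events),
                     batches=np.array(batches))

        if (config.early_stop_slope_tol is not None
                and len(mean_vars) >= 10):
            tail = np.array(mean_vars[-len(mean_vars) // 3:])
            slope = np.polyfit(np.arange(len(tail)), tail, 1)[0]
            if abs(slope) < config.early_stop_slope_tol:
                break

    return InversionReport(
        misfit=np.array(misfits), mean_variance=np.array(mean_vars),
        batches=batches, clip_events=np.array(clip_events),
        seed=config.seed, step_size=alpha or 0.0, mu=params.mu,
        sigma=params.sigma, dx=dx, origin=origin,
        config=_config_dict(config),
        wall_time=time.perf_counter() - t_start)


def run_fwi(observed: list[ShotGather], geometry: AcquisitionGeometry,
            wavelet: Wavelet, grid_shape: tuple[int, int], dx: float,
            config: InversionConfig | None = None,
            prior: PriorSpec | None = None,
            origin: tuple[float, float] = (0.0, 0.0)) -> InversionReport:
    """Deterministic FWI: gradient descent on the misfit from the prior mean.

    The classical algorithm the stochastic loop reduces to when the
    standard-normal draw is suppressed; kept as an independent reference
    path (the reduction is asserted bit-for-bit in the test suite).
    """
    config = config or InversionConfig()
    prior = prior or PriorSpec()
    n_iter, batch = config.resolve_schedule(geometry.n_sources)
    t_start = time.perf_counter()

    mu = np.broadcast_to(np.asarray(prior.mu_prior, dtype=float),
                         grid_shape).copy()
    by_source = {g.source_index: g for g in observed}
    interior = margin_mask(grid_shape, config.solver.sponge_cells)
    misfits, batches = [], []
    alpha = None
    for it in range(n_iter):
        batch_sources = [(it * batch + j) % geometry.n_sources
                         for j in range(batch)]
        model_i = VelocityModel(
            np.clip(mu, *config.clip) if config.clip else mu, dx, origin)
        delta = np.zeros(grid_shape)
        illum = np.zeros(grid_shape)
        gamma = 0.0
        for s in batch_sources:
            g, m, il = shot_gradient(model_i, geometry, wavelet,
                                     by_source[s], cutoff=config.cutoff,
                                     config=config.solver,
                                     return_illumination=True)
            delta += g.delta_m
            illum += il
            gamma += m
        if config.precondition:
            delta = delta / (illum + config.precondition_eps * illum.max())
        if alpha is None:
            gmax = float(np.abs(delta).max())
            mu_scale = float(np.abs(np.asarray(prior.mu_prior)).max())
            alpha = (config.step_fraction * mu_scale / gmax
                     if gmax > 0 else 0.0)
        mu = mu - alpha * delta
        misfits.append(gamma)
        batches.append(batch_sources)
    return InversionReport(
        misfit=np.array(misfits),
        mean_variance=np.zeros(len(misfits)),
        batches=batches, clip_events=np.zeros(len(misfits), dtype=int),
        seed=config.seed, step_size=alpha or 0.0, mu=mu,
        sigma=np.zeros(grid_shape), dx=dx, origin=origin,
        config=_config_dict(config),
        wall_time=time.perf_counter() - t_start)


class SVIWaveTomography:
    """Sound-speed tomography model with mean-field Gaussian uncertainty.

    Parameters
    ----------
    observed : list of ShotGather
        One gather per source (``source_index`` identifies the source).
    geometry : AcquisitionGeometry
        Physical source/receiver positions.
    wavelet : Wavelet
        Source signature; its length sets the simulation record.
    grid_shape, dx, origin :
        The inversion grid.
    prior : PriorSpec
        Initialisation of the variational parameters.
    config : InversionConfig
        Loop settings (cutoff, step rule, schedule, seed, solver).

    Examples
    --------
    >>> model = SVIWaveTomography(gathers, geometry, wavelet,
    ...                           grid_shape=(100, 100), dx=1e-3)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, observed, geometry, wavelet, grid_shape, dx,
                 origin=(0.0, 0.0), prior: PriorSpec | None = None,
                 config: InversionConfig | None = None):
        self.observed = list(observed)
        self.geometry = geometry
        self.wavelet = wavelet
        self.grid_shape = tuple(grid_shape)
        self.dx = float(dx)
        self.origin = origin
        self.prior = prior or PriorSpec()
        self.config = config or InversionConfig()
        self.geometry.validate_inside(
            VelocityModel(np.full(self.grid_shape, 1500.0), self.dx, origin),
            self.config.solver.sponge_cells)

    def fit(self, seed: int | None = None, deterministic: bool = False,
            checkpoint_path=None, checkpoint_every: int = 0,
            callback=None) -> "SVIWaveTomographyResults":
        """Run the inversion loop and wrap the report."""
        import dataclasses as _dc
        cfg = _dc.replace(self.config)
        if seed is not None:
            cfg.seed = seed
        if deterministic:
            cfg.deterministic = True
        report = run_inversion(self.observed, self.geometry, self.wavelet,
                               self.grid_shape, self.dx, cfg, self.prior,
                               self.origin, checkpoint_path,
                               checkpoint_every, callback)
        return SVIWaveTomographyResults(self, report)


class SVIWaveTomographyResults:
    """Fit results: final images, traces, and diagnostics."""

    def __init__(self, model: SVIWaveTomography, report: InversionReport):
        self.model = model
        self.report = report

    @property
    def mean_model(self) -> VelocityModel:
        return VelocityModel(self.report.mu, self.report.dx,
                             self.report.origin)

    @property
    def sigma(self) -> np.ndarray:
        return self.report.sigma

    @property
    def variance(self) -> np.ndarray:
        return self.report.variance

    @property
    def misfit_trace(self) -> np.ndarray:
        return self.report.misfit

    @property
    def mean_variance_trace(self) -> np.ndarray:
        return self.report.mean_variance

    def summary(self) -> str:
        """Plain-text fit summary."""
        from .qc import variance_trend
        r = self.report
        trend = variance_trend(r)
        interior = margin_mask(r.mu.shape,
                               r.config.get("solver", {}).get(
                                   "sponge_cells", 0))
        lines = [
            "SVI-FWI Results",
            "=" * 46,
            f"grid                 {r.mu.shape[0]} x {r.mu.shape[1]}"
            f"  (dx = {r.dx * 1e3:g} mm)",
            f"iterations           {r.n_iterations}",
            f"seed                 {r.seed}",
            f"step size            {r.step_size:.3e}",
            f"final misfit         {r.misfit[-1]:.4e}",
            f"mean sound speed     {np.mean(r.mu[interior]):.1f} m/s"
            f"  (range {r.mu[interior].min():.1f}"
            f"-{r.mu[interior].max():.1f})",
            f"mean variance        {r.mean_variance[-1]:.3f} (m/s)^2",
            f"peak variance iter   {trend.peak_iteration}",
            f"final/peak variance  {trend.final_peak_ratio:.3f}",
            f"variance tail slope  {trend.tail_slope:+.2e} per iteration",
            f"clipped samples      {int(r.clip_events.sum())}",
            f"wall time            {r.wall_time:.1f} s",
        ]
        return "\n".join(lines)

    def plot_images(self, axes=None):
        """Mean and variance images side by side (matplotlib axes)."""
        import matplotlib.pyplot as plt
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4))
        r = self.report
        extent = [r.origin[1] * 1e3,
                  (r.origin[1] + r.mu.shape[1] * r.dx) * 1e3,
                  (r.origin[0] + r.mu.shape[0] * r.dx) * 1e3,
                  r.origin[0] * 1e3]
        im0 = axes[0].imshow(r.mu, extent=extent, cmap="viridis")
        axes[0].set_title("mean sound speed (m/s)")
        im1 = axes[1].imshow(r.variance, extent=extent, cmap="magma")
        axes[1].set_title("variance (m/s)$^2$")
        for ax, im in zip(axes, (im0, im1)):
            ax.set_xlabel("x (mm)")
            ax.set_ylabel("z (mm)")
            ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return axes

    def plot_traces(self, ax=None):
        """Misfit and mean-variance evolution per iteration."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        it = np.arange(1, self.report.n_iterations + 1)
        ax.plot(it, self.report.mean_variance, label="mean variance")
        ax.set_xlabel("iteration")
        ax.set_ylabel("mean variance (m/s)$^2$")
        ax2 = ax.twinx()
        ax2.semilogy(it, self.report.misfit, "C1--", label="misfit")
        ax2.set_ylabel("misfit")
        ax.legend(loc="upper left")
        return ax

    def save(self, path) -> None:
        self.report.save(path)
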