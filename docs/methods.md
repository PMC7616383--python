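# Methods

`svifwi` reconstructs a 2D sound-speed map from ultrasound shot gathers
by full-waveform inversion (FWI) and, at essentially no extra cost,
estimates a per-pixel variance image via stochastic variational
inference (SVI) with a mean-field Gaussian approximating distribution.
This note records the model, the numerical choices, what the synthetic
experiments emulate, and the limits of both.

## Statistical model

The observed data `d` for each source are modelled as the output of the
acoustic wave operator plus Gaussian error, which makes the negative
log-likelihood the familiar least-squares waveform misfit

    Γ(m) = ½ ‖G d − G L(m)‖²,

where `L(m)` simulates receiver traces through the sound-speed image
`m` (one value per pixel, m/s) and `G` is the zero-phase low-pass
filter of the multiscale scheme, applied identically to both sides.

The posterior over `m` is approximated by a mean-field Gaussian with
mean image `µ` and *signed* standard-deviation image `Σ`, through the
reparameterisation `m = µ + Σ ⊙ ε`, `ε ~ N(0, I)`. With the
regularisation weight set to zero the evidence-lower-bound gradient
reduces to pathwise derivatives of `Γ`, giving per iteration (one draw
`ε`, one adjoint-state gradient `Δm = ∂Γ/∂m` evaluated at the sample):

    µ ← µ − α Δm
    Σ ← Σ − α (ε ⊙ Δm)

Both updates recycle the same `Δm`; the `Σ` update is one elementwise
product, which is the no-cost claim (measured here at ~10⁻⁴ of the
cost of the gradient itself on a 100×100 grid). The variance image
reported to users is `Σ²`, taken after the iterations finish, so a
sign-indefinite `Σ` is harmless and is deliberately left unclamped.
Forcing `ε ≡ 0` recovers classical deterministic FWI exactly (the test
suite asserts bit-identity of the `µ` trajectory); the `--deterministic`
CLI flag and `fit(deterministic=True)` expose this mode.

Why the variance behaves as an image-quality monitor: near a convex
basin the gradient at the sample is approximately `H (µ − m* + Σ ε)`,
so the `Σ` update contains a systematic contraction `−α H Σ ε²` that
shrinks `Σ` wherever the data constrain the pixel, balanced against the
random-walk excitation `−α H(µ−m*) ε`. Where the data are inconsistent
with the model class — cycle-skipped traces, wrong physics, corrupted
geometry — the persistent gradient keeps exciting `Σ` and the variance
grows or stays elevated. All four experiments below are expressions of
this mechanism.

## Wave propagation

The forward operator is the constant-density acoustic wave equation
`c⁻² ∂²u/∂t² = ∇²u + s`, discretised second-order in time and
tenth-order in space on a regular grid, with a Courant limit
`c·dt/dx ≤ 2/√(2Σ|w|) ≈ 0.541` for the 10th-order stencil (checked,
with a points-per-wavelength dispersion warning, by
`check_stability`). Boundaries are an absorbing sponge implemented as a
first-order damping term `+2η ∂u/∂t` with a quadratic ramp over a
configurable margin (default 40 cells for the library, 12 at desk
scale). Two choices here matter beyond taste:

- the damping coefficient scales with a *fixed* reference speed
  (1500 m/s), not the model maximum, so the absorber is independent of
  the model being inverted — otherwise the misfit gradient acquires a
  spurious model-wide term;
- the damping is kept in symmetric central-difference form so the
  forward recursion has a clean algebraic transpose.

The adjoint propagator is that exact transpose — damping applied before
the spatial operator, Laplacian of `c²·λ` rather than `c²·(∇²λ)` —
rather than "the same code run backwards", which is only an approximate
transpose when `c` or `η` vary in space. The payoff is the dot-product
identity `⟨Fς, r⟩ = ⟨ς, F†r⟩` holding at ~10⁻¹⁵ relative and the
assembled gradient matching central-difference misfit derivatives to
~10⁻⁷, with no tuning.

The gradient itself is the zero-lag correlation of the stored forward
field's (damped) second time derivative with the adjoint field, with
the `∂H/∂c` weight, which for this scaling reduces to `−2/c`. Snapshots
are stored every step by default; the store supports decimation for
diagnostics, but the exact imaging condition requires the full history
and says so.

The low-pass filter is a zero-phase Butterworth *magnitude* response
(order 8) applied in the frequency domain. A real, even transfer
function makes the filter matrix exactly symmetric, so the adjoint
source of the filtered misfit is just the filter applied once more —
the gradient stays exact under multiscale filtering.

Variable density (used only to generate mismatched-physics observed
data) solves `c⁻²p_tt = ∇²p − ∇(ln ρ)·∇p + s`, i.e. the pressure-form
`∇·(ρ⁻¹∇p)` operator multiplied through by `ρ`, with matching
10th-order first-derivative stencils and replicate-edge boundaries for
`∇ln ρ`. This form was chosen over a flux discretisation because it
degenerates *identically* to the constant-density scheme when `ρ` is
uniform, which pins down the solver-consistency contract to machine
precision.

## Optimisation

The update rules fix what the gradients are, not how large a step to
take. Choices made here, after observing that raw steepest descent
stalls (the raw gradient concentrates at the transducers):

- **Illumination preconditioning.** The summed batch gradient is
  divided by the source illumination `I(x) = Σ_t u_p²(x,t)` (diagonal
  pseudo-Hessian), regularised by `10⁻³` of its peak. Both updates use
  the preconditioned gradient, preserving their common scale.
- **Step size.** `α` is set once so the first mean update's max-norm
  equals `step_fraction` (default 2%) of the prior mean, then held
  fixed. A fixed `α` matters for the variance mechanism: a
  continually renormalised step would prevent the gradient decay that
  lets `Σ` settle.
- **Schedule.** Deterministic round-robin source batches of
  `ceil(n_sources/51)` per iteration; desk-scale default three epochs
  (96 iterations at 32 sources), in line with the ~80–100-iteration
  budgets typical for this configuration at full scale.
- **Sample clipping.** Draws are clipped to a physical band
  (default 1300–1800 m/s) before propagation to protect the solver;
  events are counted in the report. At the default settings a few
  hundred pixel-draws clip over a whole run (of ~10⁶), essentially all
  on the singular transducer pixels.

One `ε` is drawn per iteration and shared by every shot in the batch
and by both updates; `mc_samples > 1` averages several draws.

The absolute scale of the variance image depends on `α` (the
random-walk excitation is `O(α²)`), so variance values are comparable
between runs of the same configuration but not across step sizes. All
image-quality conclusions in the experiments are therefore relative
comparisons at matched settings.

## Synthetic study and what it does (not) show

The desk-scale study rasterises a circular phantom — 50 mm inclusion at
1540 m/s, background 1500 m/s, densities 1.010/1.010 (matched) or
1.220/1.010 g/cm³ (mismatched) — on a 100×100 grid at 1 mm, observed
by 32 co-located single-element transducers on a 70 mm ring, with a
370 kHz Ricker source, 700 kHz low-pass, 80 µs records at dt = 0.1 µs,
and a 12-cell sponge. The inversion starts from the water prior
(mean 1480 m/s, variance 4 (m/s)²).

Observed data are kept out of the inversion's span (no inverse crime)
by rasterising the phantom on a half-cell-shifted grid and simulating
with bilinear transducer stencils at the exact physical positions. The
time step is *shared* between generation and inversion: an earlier
design that refined the generation time step instead was found to
inject a systematic leapfrog time-dispersion mismatch that biased all
recovered speeds several m/s low, because the inversion-side `dt` error
does not cancel. A `time_refinement` option remains for studying
exactly that effect.

Experiments (each a function in `svifwi.experiments`, also reachable as
`svifwi experiment <name>`):

- **progressive_decoding** — matched physics; the mean variance rises
  while the image is wrong, peaks around iteration ~26, and ends near
  half its peak; the final medians recover 1540/1500 to within a few
  m/s.
- **cycle_skip** — same data, started at 1400 m/s: the cross-array
  traveltime error (~3.3 µs) exceeds the 370 kHz half-period (1.35 µs),
  so the inversion locks into a skipped minimum; the variance trends
  upward throughout and ends several times above the matched run.
- **physics_mismatch** — density-contrast data inverted with
  constant-density physics; mean variance is elevated at the end of the
  first epoch relative to a matched run with the same seed, and the
  variance concentrates in a ring at the inclusion boundary.
- **artefact** — a contiguous quarter of the sources displaced 2 mm
  tangentially during data generation only; block-averaged variance
  (11-cell blocks, median + 5·MAD threshold, statistics restricted to
  the imaged interior of the ring) flags a region overlapping the
  corrupted sector, while a clean run at identical thresholds yields an
  empty mask.

What passing these experiments does *not* show: the generator has no
electronic noise, no transducer directivity or bandwidth limits, no
out-of-plane propagation, no attenuation, and its density mismatch is a
single two-valued field — so the tests demonstrate the estimator's
sensitivity mechanisms, not its calibration on real acquisitions. The
mean-field approximation ignores pixel correlations by construction;
correlated structure in real variance images is a known signature of
that missing covariance. The failure-flag and artefact-mask thresholds
are explicit heuristics (configurable, logged), not derived rules.

## Numerical details and edge cases

- Coordinates are (z, x), row-major, metres; grid extent is half-open.
- Nearest-grid-point injection/extraction by default; bilinear stencils
  by configuration (the desk experiments use them throughout).
- Mid-run overflow checks abort propagation with a diagnostic rather
  than returning NaNs; `check_stability` refuses super-Courant steps
  up front.
- The gradient is masked to zero inside the absorbing margin; the
  logged mean variance averages over the imaging region only.
- `run_inversion` is bit-reproducible from its seed, checkpoints
  (images + generator state) resume identically, and the deterministic
  mode consumes the generator identically to the stochastic mode so the
  two stay comparable draw for draw.
- SSIM follows the standard windowed form (uniform 7×7 window,
  `k1=0.01, k2=0.03`, sample covariance, borders cropped); it agrees
  with the scikit-image implementation to ≤10⁻⁶, which the test suite
  uses as an independent cross-check.

## Known limitations

2D constant-density physics in the inversion; no attenuation, elasticity
or 3D; mean-field (diagonal) posterior only; single fixed step size
(no line search); the variance scale is optimiser-dependent as noted;
the desk-scale acquisition (32 elements) under-samples the aperture
relative to the 510-element full-scale design, which is the main reason
recovered inclusion medians sit ~4 m/s below truth rather than ~1.
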