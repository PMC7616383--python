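"""Image-quality metrics and uncertainty-based diagnostics.

The variance image produced by the inference loop is useful as a
reference-free image-quality monitor: its spatial mean falls as the
reconstruction sharpens (progressive decoding), trends upward when the
data are cycle-skipped (reconstruction failure), and develops localised
hot spots over artefacts. This module turns those patterns into
numbers: an SSIM score against a reference image, trend summaries of
the mean-variance trace, a failure flag, and an artefact mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ssim",
    "TrendSummary",
    "variance_trend",
    "flag_failure",
    "artefact_mask",
    "QCReport",
]


def ssim(image: np.ndarray, reference: np.ndarray,
         data_range: float | None = None, win_size: int = 7,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity between two images.

    The standard windowed luminance-contrast-structure product with a
    uniform ``win_size`` x ``win_size`` window, sample (N-1) covariance
    normalisation and constants ``C1 = (k1 L)^2``, ``C2 = (k2 L)^2``
    where L is the dynamic range (reference max - min when not given).
    The local map is averaged after cropping the half-window border.
    Returns a score in [-1, 1]; identical images score exactly 1.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference must share a shape")
    if win_size % 2 == 0 or win_size < 3:
        raise ValueError("win_size must be odd and >= 3")
    if data_range is None:
        data_range = float(reference.max() - reference.min())
        if data_range == 0:
            data_range = 1.0

    def win_mean(a):
        return ndimage.uniform_filter(a, size=win_size, mode="reflect")

    n = win_size ** 2
    cov_norm = n / (n - 1)
    ux, uy = win_mean(image), win_mean(reference)
    uxx, uyy, uxy = win_mean(image**2), win_mean(reference**2), \
        win_mean(image * reference)
    vx = cov_norm * (uxx - ux**2)
    vy = cov_norm * (uyy - uy**2)
    vxy = cov_norm * (uxy - ux * uy)

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)
         / ((ux**2 + uy**2 + c1) * (vx + vy + c2)))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


@dataclass
class TrendSummary:
    """Shape descriptors of a mean-variance trace."""

    peak_iteration: int       # 1-based iteration of the maximum
    peak_value: float
    final_value: float
    final_peak_ratio: float
    tail_slope: float         # least-squares slope on the final third


def variance_trend(report) -> TrendSummary:
    """Summarise the per-iteration mean-variance trace of a report
    (anything with a ``mean_variance`` array attribute, or an array)."""
    trace = np.asarray(getattr(report, "mean_variance", report), dtype=float)
    if trace.size == 0:
        raise ValueError("empty variance trace")
    peak = int(np.argmax(trace))
    tail = trace[-max(2, trace.size // 3):]
    slope = float(np.polyfit(np.arange(tail.size), tail, 1)[0])
    return TrendSummary(
        peak_iteration=peak + 1,
        peak_value=float(trace[peak]),
        final_value=float(trace[-1]),
        final_peak_ratio=float(trace[-1] / trace[peak]) if trace[peak] else 1.0,
        tail_slope=slope)


def flag_failure(report, reference_final: float | None = None,
                 factor: float = 2.0) -> tuple[bool, str]:
    """Heuristic reconstruction-failure flag.

    Fires when the mean-variance tail slope is positive AND the final
    variance exceeds ``factor`` times a reference level — the final
    variance of a known-good (matched) run when provided, otherwise the
    trace's own early plateau (median of iterations 2-10). Returns
    ``(flag, rule description)``.
    """
    trace = np.asarray(getattr(report, "mean_variance", report), dtype=float)
    if trace.size < 10:
        raise ValueError("need at least 10 iterations to judge failure")
    trend = variance_trend(trace)
    if reference_final is not None:
        ref, ref_name = reference_final, "reference run final variance"
    else:
        ref, ref_name = float(np.median(trace[1:10])), "early plateau"
    fired = trend.tail_slope > 0 and trace[-1] > factor * ref
    rule = (f"tail_slope={trend.tail_slope:+.3e} and final="
            f"{trace[-1]:.3f} vs {factor:g} x {ref_name} ({ref:.3f})")
    return bool(fired), rule


def artefact_mask(variance_img: np.ndarray, block: int = 5,
                  k: float = 5.0, margin_cells: int = 0,
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Locate localised variance hot spots.

    The variance image is block-averaged, blocks above
    ``median + k * MAD`` are flagged, and the flags are broadcast back
    to pixel resolution. Median/MAD thresholding makes the mask
    invariant to uniform scaling of the variance image and robust to
    its heavy tail. ``margin_cells`` excludes the absorbing margin —
    where the variance is frozen at the prior and carries no
    information — and ``valid`` restricts the statistics to an
    arbitrary region of interest (e.g. the interior of the transducer
    ring; blocks need at least half their pixels valid to enter the
    statistics). A uniform image returns an empty mask.
    """
    v = np.asarray(variance_img, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("variance image must be finite")
    nz, nx = v.shape
    if valid is None:
        valid = np.ones_like(v, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool).copy()
    m = int(margin_cells)
    if m:
        border = np.zeros_like(valid)
        border[m:nz - m, m:nx - m] = True
        valid &= border

    bz, bx = nz // block, nx // block
    means, coords = [], []
    for i in range(bz):
        for j in range(bx):
            sl = (slice(i * block, (i + 1) * block),
                  slice(j * block, (j + 1) * block))
            ok = valid[sl]
            if ok.sum() >= (block * block) // 2:
                means.append(float(v[sl][ok].mean()))
                coords.append(sl)
    mask = np.zeros_like(v, dtype=bool)
    if not means:
        return mask
    means = np.asarray(means)
    med = np.median(means)
    mad = np.median(np.abs(means - med))
    if mad == 0:
        return mask
    for mu_b, sl in zip(means, coords):
        if mu_b > med + k * mad:
            mask[sl] = True
    return mask & valid


def connected_regions(mask: np.ndarray) -> list[np.ndarray]:
    """Split a boolean mask into connected components (4-connectivity)."""
    labels, n = ndimage.label(mask)
    return [labels == i for i in range(1, n + 1)]


@dataclass
class QCReport:
    """Bundle of quality diagnostics for one inversion run."""

    ssim: float | None
    mean_variance_trace: list = field(default_factory=list)
    failure_flag: bool = False
    failure_rule: str = ""
    peak_iteration: int = 0
    final_peak_ratio: float = 1.0
    tail_slope: float = 0.0
    artefact_fraction: float = 0.0

    @classmethod
    def from_report(cls, report, reference: np.ndarray | None = None,
                    reference_final: float | None = None,
                    mask_kwargs: dict | None = None) -> "QCReport":
        trend = variance_trend(report)
        flag, rule = flag_failure(report, reference_final)
        score = None
        if reference is not None:
            score = ssim(report.mu, np.asarray(reference, dtype=float))
        mask = artefact_mask(report.variance, **(mask_kwargs or {}))
        return cls(ssim=score,
                   mean_variance_trace=list(map(float,
                                                report.mean_variance)),
                   failure_flag=flag, failure_rule=rule,
                   peak_iteration=trend.peak_iteration,
                   final_peak_ratio=trend.final_peak_ratio,
                   tail_slope=trend.tail_slope,
                   artefact_fraction=float(mask.mean()))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
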