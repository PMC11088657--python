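"""Tracker-performance evaluation: precision curves, spatial robustness,
and motion-trace statistics.

The precision metric is the standard object-tracking benchmark quantity:
per-frame Euclidean distance between tracked and reference motion,
sorted into a cumulative distribution ("precision curve"), read off at a
threshold (5 mm, or 2 px via the geometric-mean pixel size for
anisotropic pixels).  Curves are resampled to 100 points before pooling
so series of different lengths contribute equally.  Frames on which a
tracker explicitly reported failure are removed from the precision data
— a reported failure permits re-acquisition and should not count as a
missed measurement.

Spatial robustness repeats the tracking task over a grid of perturbed
initial bounding boxes (5 shifts per axis x 5 symmetric scale changes in
2 px steps = 125 evaluations by default) and summarizes the spread of
the precision values.

Trace statistics: per-axis motion amplitude as the 10th-to-90th
percentile range, and principal motion directions from the SVD of the
mean-centred displacement matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .fusion import BoundingBox
from .simnav import MotionTrace

__all__ = [
    "PrecisionCurve",
    "tracking_error",
    "precision_curve",
    "precision_at",
    "pooled_precision",
    "robustness_grid",
    "robustness_stats",
    "motion_amplitude",
    "principal_motion",
    "mae",
    "px_threshold_mm",
    "plot_precision_curves",
]


@dataclass(frozen=True)
class PrecisionCurve:
    """Cumulative tracking-error distribution resampled to n points.

    ``error_grid[j]`` is the error value below which a ``fraction[j]`` of
    frames fall; fractions are evenly spaced and end at 1.
    """

    error_grid: np.ndarray
    fraction: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.error_grid, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        if e.shape != f.shape or e.ndim != 1:
            raise ValueError("error_grid and fraction must be equal-length 1D")
        if np.any(np.diff(f) < 0) or f[0] < 0 or abs(f[-1] - 1.0) > 1e-12:
            raise ValueError("fraction must be non-decreasing, ending at 1")
        if np.any(np.diff(e) < 0):
            raise ValueError("error_grid must be sorted")
        object.__setattr__(self, "error_grid", e)
        object.__setattr__(self, "fraction", f)


def tracking_error(
    tracked: np.ndarray,
    reference: np.ndarray,
    failures: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame Euclidean error (mm) with failed frames removed.

    ``tracked`` and ``reference`` are (T, 2) displacement series in mm;
    ``failures`` flags frames the tracker reported as failed (NaN
    displacements are treated as failures too).  An empty result means
    no evaluable data — every frame failed.
    """
    a = np.asarray(tracked, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracked and reference series must have equal shape")
    err = np.linalg.norm(a - b, axis=-1)
    keep = np.isfinite(err)
    if failures is not None:
        flags = np.asarray(failures, dtype=bool)
        if flags.shape[0] != err.shape[0]:
            raise ValueError("failures must match the series length")
        keep &= ~flags
    return err[keep]


def precision_curve(errors: np.ndarray, n_points: int = 100) -> PrecisionCurve:
    """Empirical error CDF resampled to ``n_points`` even quantiles.

    Quantiles are taken with the inverted-CDF (order-statistic) rule so
    that reading the curve back at a threshold reproduces the exact
    counting fraction to within 1/len(errors).
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("no evaluable tracking errors (all frames failed?)")
    fractions = np.arange(1, n_points + 1) / n_points
    grid = np.quantile(e, fractions, method="inverted_cdf")
    return PrecisionCurve(error_grid=grid, fraction=fractions)


def precision_at(curve: PrecisionCurve, threshold: float) -> float:
    """Fraction of frames with error <= threshold, read off the curve."""
    idx = np.searchsorted(curve.error_grid, threshold, side="right")
    if idx == 0:
        return 0.0
    return float(curve.fraction[idx - 1])


def pooled_precision(curves: Sequence[PrecisionCurve]) -> PrecisionCurve:
    """Mean of normalized precision curves across datasets.

    All curves must share the resampling length; the pooled curve is the
    pointwise mean of the error quantiles at each common fraction.
    """
    if len(curves) == 0:
        raise ValueError("no curves to pool")
    n = curves[0].fraction.size
    if any(c.fraction.size != n for c in curves):
        raise ValueError("curves must be normalized to the same length")
    grid = np.mean([c.error_grid for c in curves], axis=0)
    return PrecisionCurve(error_grid=grid, fraction=curves[0].fraction.copy())


def px_threshold_mm(pixel_size: Tuple[float, float], n_px: float = 2.0) -> float:
    """Pixel-count threshold in mm via the geometric-mean pixel size."""
    return float(n_px * np.sqrt(pixel_size[0] * pixel_size[1]))


def robustness_grid(
    init: BoundingBox,
    image_dims: Tuple[int, int],
    shift_step_px: float = 2.0,
    n_shifts: int = 5,
    n_scales: int = 5,
) -> List[BoundingBox]:
    """Grid of perturbed initial boxes for the spatial-robustness study.

    ``n_shifts`` symmetric shifts per image axis and ``n_scales``
    symmetric scale changes (applied to both width and height about the
    box centre), all in ``shift_step_px`` steps: the defaults give
    5 x 5 x 5 = 125 boxes including the original.  Boxes are clipped to
    the image bounds (duplicates from clipping are kept and counted).
    ``image_dims`` is (width, height) in px.
    """
    W, H = image_dims
    if init.x < 0 or init.y < 0 or init.x + init.w > W or init.y + init.h > H:
        raise ValueError("initial box lies outside the image")
    offsets = (np.arange(n_shifts) - n_shifts // 2) * shift_step_px
    scales = (np.arange(n_scales) - n_scales // 2) * shift_step_px
    cx, cy = init.center
    boxes = []
    for ds in scales:
        w = max(init.w + ds, 2.0)
        h = max(init.h + ds, 2.0)
        for dy in offsets:
            for dx in offsets:
                x = cx + dx - w / 2.0
                y = cy + dy - h / 2.0
                # clip into the image, preserving size where possible
                x = min(max(x, 0.0), max(W - w, 0.0))
                y = min(max(y, 0.0), max(H - h, 0.0))
                w_c = min(w, float(W))
                h_c = min(h, float(H))
                boxes.append(BoundingBox(x, y, w_c, h_c))
    return boxes


def robustness_stats(values: Iterable[float]) -> Tuple[float, float]:
    """Mean and standard deviation of per-perturbation precision values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def motion_amplitude(trace: MotionTrace) -> np.ndarray:
    """Per-axis motion amplitude: 10th-to-90th percentile range (mm)."""
    return np.quantile(trace.disp, 0.9, axis=0) - np.quantile(trace.disp, 0.1, axis=0)


def principal_motion(trace: MotionTrace) -> Tuple[np.ndarray, np.ndarray]:
    """Principal motion directions and singular values of a 3D trace.

    SVD of the mean-centred (N, 3) displacement matrix; returns
    ``(components, singular_values)`` with components as rows ordered by
    decreasing singular value.  Signs are fixed by making each vector's
    largest-magnitude component positive (principal directions are
    defined up to sign).
    """
    d = trace.disp - trace.disp.mean(axis=0)
    _, s, Vt = np.linalg.svd(d, full_matrices=False)
    comps = Vt.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return comps, s


def mae(
    a: np.ndarray,
    b: np.ndarray,
    pixel_size: Optional[Tuple[float, float]] = None,
) -> float | Tuple[float, float]:
    """Mean absolute (Euclidean) error between two vector series in mm.

    With ``pixel_size`` given, also returns the error in pixels (via the
    geometric-mean pixel size).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal shape")
    err = float(np.mean(np.linalg.norm(x - y, axis=-1)))
    if pixel_size is None:
        return err
    return err, err / float(np.sqrt(pixel_size[0] * pixel_size[1]))


def plot_precision_curves(curves: dict, path, threshold_mm: float = 5.0):
    """Write a precision-curve figure (one line per labelled curve)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        p5 = precision_at(c, threshold_mm)
        ax.plot(c.error_grid, c.fraction, label=f"{label} ({100 * p5:.1f}%)")
    ax.axvline(threshold_mm, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("tracking error [mm]")
    ax.set_ylabel("fraction of frames")
    ax.set_xlim(left=0)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
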