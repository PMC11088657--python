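"""Synthetic 3D motion traces and multi-slice navigator image series.

The generator emulates the appearance of fast low-resolution 2D MR image
navigators of a compact bright target (an organ or phantom sphere) on a
darker background: ~2-3 mm pixels, surface-coil-like intensity falloff
and Rician noise (magnitude of a complex Gaussian, the noise statistics
of magnitude MR images).  It does not model MR contrast physics — no
sequence signal equations, no k-space of the navigator itself — only
geometry, intensity falloff and noise.

Motion is defined as a single 3D ground-truth trace in patient
coordinates shared by all slices.  Two trace families cover the study
conditions: a breathing-like sinusoid with per-cycle amplitude jitter
and slow drift, and the step-wise staircase of the motion-phantom
experiments (4 mm per TR up to 40 mm by default).

Multi-slice acquisition is sequential: within one navigator block each
slice is sampled at its own acquisition mid-time (default 70 ms per
slice), so slices of the same repetition see slightly different
positions — the intra-navigator motion a real interleaved acquisition
experiences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .geometry import AXIS_NAMES, SlicePlane, patient_to_image

__all__ = [
    "MotionTrace",
    "PhantomSpec",
    "NavigatorSeries",
    "make_breathing_trace",
    "make_step_trace",
    "render_navigator",
    "simulate_series",
]

_AXIS_INDEX = {name: i for i, name in enumerate(AXIS_NAMES)}


@dataclass(frozen=True)
class MotionTrace:
    """Time-stamped 3D displacement series in patient coordinates (mm).

    ``disp[0]`` is zero for reference-anchored traces (displacement
    relative to the planning position).
    """

    t: np.ndarray
    disp: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.disp, dtype=float)
        if t.ndim != 1 or d.shape != (t.size, 3):
            raise ValueError("t must be (n,), disp must be (n, 3)")
        if t.size == 0:
            raise ValueError("trace must contain at least one sample")
        if np.any(np.diff(t) <= 0) and t.size > 1:
            raise ValueError("time stamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "disp", d)

    def __len__(self) -> int:
        return self.t.size

    def sample(self, times) -> np.ndarray:
        """Linear interpolation of the trace, clamped at the ends."""
        times = np.asarray(times, dtype=float)
        out = np.stack(
            [np.interp(times, self.t, self.disp[:, k]) for k in range(3)], axis=-1
        )
        return out


def _axis_vector(axis) -> np.ndarray:
    if isinstance(axis, str):
        try:
            v = np.zeros(3)
            v[_AXIS_INDEX[axis]] = 1.0
            return v
        except KeyError:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXIS_NAMES}") from None
    v = np.asarray(axis, dtype=float)
    if v.shape != (3,):
        raise ValueError("axis must be a 3-vector or an axis name")
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis vector must be nonzero")
    return v / n


def make_breathing_trace(
    duration_s: float,
    TR_s: float,
    amplitude_mm: float,
    period_s: float = 4.0,
    axis_weights=(0.2, 0.1, 1.0),
    amp_jitter: float = 0.0,
    drift_mm_per_min: float = 0.0,
    seed: Optional[int] = None,
) -> MotionTrace:
    """Breathing-like sinusoidal trace sampled every TR.

    ``A_c * sin(2 pi t / period)`` along the unit-normalized
    ``axis_weights`` direction; the per-cycle amplitude ``A_c`` is the
    nominal amplitude times a lognormal jitter factor (sigma =
    ``amp_jitter`` in log space, seeded), emulating irregular breathing
    depth.  A linear drift (mm per minute) models slow baseline shift.
    Deterministic for a given seed.
    """
    if TR_s <= 0 or period_s <= 0:
        raise ValueError("TR_s and period_s must be > 0")
    n = int(np.floor(duration_s / TR_s)) + 1
    t = np.arange(n) * TR_s
    axis = _axis_vector(axis_weights)
    cycle = np.floor_divide(t, period_s).astype(int)
    n_cycles = int(cycle.max()) + 1 if n else 0
    rng = np.random.default_rng(seed)
    if amp_jitter > 0:
        factors = rng.lognormal(mean=0.0, sigma=amp_jitter, size=n_cycles)
    else:
        factors = np.ones(n_cycles)
    amp = amplitude_mm * factors[cycle]
    s = amp * np.sin(2.0 * np.pi * t / period_s) + drift_mm_per_min * t / 60.0
    return MotionTrace(t=t, disp=np.outer(s, axis))


def make_step_trace(
    step_mm: float = 4.0,
    steps_per_excursion: int = 10,
    TR_s: float = 2.0,
    n_cycles: int = 1,
    axis="HF",
) -> MotionTrace:
    """Triangular staircase: up ``step_mm`` per TR, then back down.

    With the motion-phantom defaults (4 mm per TR, 10 steps) the
    displacement peaks at 40 mm once per excursion.  All samples are
    integer multiples of ``step_mm``.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    if steps_per_excursion < 1:
        raise ValueError("steps_per_excursion must be >= 1")
    if TR_s <= 0:
        raise ValueError("TR_s must be > 0")
    up = np.arange(1, steps_per_excursion + 1, dtype=float)
    down = np.arange(steps_per_excursion - 1, -1, -1, dtype=float)
    cycle = np.concatenate([up, down]) * step_mm
    s = np.concatenate([[0.0], np.tile(cycle, n_cycles)])
    t = np.arange(s.size) * TR_s
    return MotionTrace(t=t, disp=np.outer(s, _axis_vector(axis)))


@dataclass(frozen=True)
class PhantomSpec:
    """Appearance of the synthetic navigator target.

    ``target_radius`` is in mm (for ``ellipse`` the semi-major axis; the
    axis ratio is fixed at 1.4; for ``ring`` the outer radius, with the
    inner radius at 60%).  ``coil_falloff_scale`` is the exponential
    intensity-decay length from the y=0 image edge in mm (0 =
    homogeneous reception).  ``noise_sigma`` is the Rician noise level as
    a fraction of the target intensity, so SNR = 1/noise_sigma.
    """

    target_shape: str = "disc"
    target_radius: float = 20.0
    target_intensity: float = 1.0
    background_intensity: float = 0.15
    coil_falloff_scale: float = 0.0
    noise_sigma: float = 0.1

    def __post_init__(self):
        if self.target_shape not in ("disc", "ellipse", "ring"):
            raise ValueError("target_shape must be disc, ellipse or ring")
        if self.target_radius <= 0:
            raise ValueError("target_radius must be > 0")
        if self.target_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_sigma < 0 or self.coil_falloff_scale < 0:
            raise ValueError("noise_sigma and coil_falloff_scale must be >= 0")


_ELLIPSE_RATIO = 1.4
_RING_INNER = 0.6


def render_navigator(
    plane: SlicePlane,
    spec: PhantomSpec = PhantomSpec(),
    displacement_3d=(0.0, 0.0, 0.0),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one navigator frame, the target displaced by a 3D vector.

    The target's reference position is the image centre; the in-plane
    projection of ``displacement_3d`` moves it, the through-plane
    component shrinks its apparent radius by chord geometry (the visible
    disc of a displaced sphere) until it vanishes at one radius.  Edges
    are anti-aliased over one pixel.  Returned array is indexed
    ``[y, x]`` (row, column).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    disp = np.asarray(displacement_3d, dtype=float)
    n_x, n_y = plane.dims
    p_x, p_y = plane.pixel_size
    d2 = patient_to_image(disp, plane)
    dz = float(disp @ plane.normal)
    cx = (n_x - 1) / 2.0 + d2[0]
    cy = (n_y - 1) / 2.0 + d2[1]

    r_eff_sq = spec.target_radius**2 - dz**2
    img = np.full((n_y, n_x), spec.background_intensity, dtype=float)
    if r_eff_sq > 0:
        r_eff = np.sqrt(r_eff_sq)
        xs = (np.arange(n_x) - cx) * p_x
        ys = (np.arange(n_y) - cy) * p_y
        X, Y = np.meshgrid(xs, ys)
        aa = 0.5 * (p_x + p_y)  # one-pixel anti-aliasing band
        amp = spec.target_intensity - spec.background_intensity
        if spec.target_shape == "ellipse":
            dist = np.hypot(X / _ELLIPSE_RATIO, Y * _ELLIPSE_RATIO)
        else:
            dist = np.hypot(X, Y)
        cover = np.clip((r_eff - dist) / aa + 0.5, 0.0, 1.0)
        if spec.target_shape == "ring":
            inner = np.clip((_RING_INNER * r_eff - dist) / aa + 0.5, 0.0, 1.0)
            cover = cover - inner
        img += amp * cover

    if spec.coil_falloff_scale > 0:
        depth_mm = np.arange(n_y)[:, None] * p_y
        img *= np.exp(-depth_mm / spec.coil_falloff_scale)

    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * spec.target_intensity
        re = img + rng.normal(0.0, sigma, img.shape)
        im = rng.normal(0.0, sigma, img.shape)
        img = np.hypot(re, im)
    return img


@dataclass
class NavigatorSeries:
    """Multi-slice navigator time series with ground truth.

    ``images[name]`` is a (T, n_y, n_x) stack, ``truth_px[name]`` the
    (T, 2) ground-truth in-plane displacement of the target in px at the
    slice's acquisition mid-time, ``slice_times`` the (T, k) mid-times.
    ``trace`` is the shared 3D ground-truth trace (None for loaded real
    data without truth).
    """

    names: List[str]
    planes: Dict[str, SlicePlane]
    images: Dict[str, np.ndarray]
    truth_px: Optional[Dict[str, np.ndarray]]
    trace: Optional[MotionTrace]
    slice_times: Optional[np.ndarray] = None
    nav_duration_per_slice_s: float = 0.070

    @property
    def n_frames(self) -> int:
        return self.images[self.names[0]].shape[0]

    def truth_mm(self, name: str) -> np.ndarray:
        px = np.asarray(self.planes[name].pixel_size)
        return self.truth_px[name] * px


def simulate_series(
    planes: Union[Dict[str, SlicePlane], Sequence[SlicePlane]],
    trace: MotionTrace,
    spec: PhantomSpec = PhantomSpec(),
    nav_duration_per_slice_s: float = 0.070,
    seed: int = 0,
) -> NavigatorSeries:
    """Render a multi-slice navigator series along a ground-truth trace.

    One navigator block is acquired per trace sample (the trigger).
    Slice ``s`` of block ``j`` is rendered with the trace displacement
    interpolated at ``t_j + (s + 0.5) * nav_duration``, its acquisition
    mid-time, and that same displacement projected through the slice
    geometry is stored as the per-frame 2D ground truth.  Noise streams
    are derived from ``(seed, frame, slice)`` so identical seeds give
    bit-identical series.
    """
    if isinstance(planes, dict):
        plane_map = dict(planes)
    else:
        plane_map = {f"slice{i}": p for i, p in enumerate(planes)}
    names = list(plane_map)
    if not names:
        raise ValueError("at least one plane is required")
    T = len(trace)
    k = len(names)
    images = {n: np.empty((T, plane_map[n].dims[1], plane_map[n].dims[0]))
              for n in names}
    truth = {n: np.empty((T, 2)) for n in names}
    slice_times = np.empty((T, k))
    for j in range(T):
        for s, name in enumerate(names):
            t_mid = trace.t[j] + (s + 0.5) * nav_duration_per_slice_s
            slice_times[j, s] = t_mid
            d3 = trace.sample(t_mid)
            rng = np.random.default_rng([int(seed), j, s])
            images[name][j] = render_navigator(plane_map[name], spec, d3, rng=rng)
            truth[name][j] = patient_to_image(d3, plane_map[name])
    return NavigatorSeries(
        names=names, planes=plane_map, images=images, truth_px=truth,
        trace=trace, slice_times=slice_times,
        nav_duration_per_slice_s=nav_duration_per_slice_s,
    )
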