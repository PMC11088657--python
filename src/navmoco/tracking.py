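"""Frame-to-frame target tracking on grayscale navigator images.

Native implementations of two correlation-filter trackers — MOSSE
(minimum output sum of squared error, adaptive correlation filter with
peak-to-sidelobe-ratio failure detection) and KCF (kernelized
correlation filter on raw grayscale features, Gaussian kernel computed
via circulant/Fourier identities) — plus an exhaustive
normalized-cross-correlation (NCC) baseline that serves as a transparent
oracle in tests.  External tracker libraries can be plugged in through
:func:`register_tracker` without becoming a dependency.

All trackers operate on single-channel 2D arrays of arbitrary intensity
scale; patches are min-max normalized before any filtering, so tracker
output is invariant under positive rescaling of the image (MR magnitude
images carry no absolute scale).

Failure is reported explicitly: MOSSE declares failure when the PSR of
the correlation response drops below a threshold (default 8), KCF when
the detection peak falls below a configurable fraction of its running
mean, NCC when the best correlation is below a floor.  A failed update
leaves the tracker state untouched so tracking can resume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import match_template

from .fusion import BoundingBox

__all__ = [
    "TrackerParams",
    "TrackerResult",
    "TrackingLog",
    "MosseTracker",
    "KcfTracker",
    "NccTracker",
    "FlatPatchError",
    "ncc_track",
    "track_series",
    "make_tracker",
    "register_tracker",
    "TRACKER_KINDS",
]

_EPS = 1e-5


class FlatPatchError(ValueError):
    """Initialization patch has no intensity variation (degenerate input)."""


@dataclass(frozen=True)
class TrackerParams:
    """Tracker hyperparameters.

    ``learning_rate`` defaults to the canonical value of each method
    (0.125 for MOSSE, 0.02 for KCF) when left ``None``.  ``padding`` is
    the search-window size as a multiple of the bounding box.
    ``psr_fail_threshold`` applies to MOSSE, ``kcf_fail_fraction`` (of
    the running mean peak) to KCF and ``ncc_fail_threshold`` to NCC.
    ``subpixel`` enables parabolic refinement of the response peak;
    disable it for integer-pixel oracle comparisons.
    """

    learning_rate: Optional[float] = None
    padding: float = 2.0
    psr_fail_threshold: float = 8.0
    kcf_lambda: float = 1e-4
    kcf_kernel_sigma: float = 0.5
    output_sigma_factor: float = 0.1
    kcf_fail_fraction: float = 0.25
    ncc_fail_threshold: float = 0.2
    search_radius: int = 12
    subpixel: bool = True
    init_perturbations: int = 8
    seed: int = 0

    def __post_init__(self):
        positives = {
            "padding": self.padding,
            "psr_fail_threshold": self.psr_fail_threshold,
            "kcf_lambda": self.kcf_lambda,
            "kcf_kernel_sigma": self.kcf_kernel_sigma,
            "output_sigma_factor": self.output_sigma_factor,
            "kcf_fail_fraction": self.kcf_fail_fraction,
            "ncc_fail_threshold": self.ncc_fail_threshold,
            "search_radius": self.search_radius,
        }
        if self.learning_rate is not None:
            positives["learning_rate"] = self.learning_rate
            if not 0 < self.learning_rate <= 1:
                raise ValueError("learning_rate must lie in (0, 1]")
        for name, v in positives.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        if self.padding < 1:
            raise ValueError("padding must be >= 1")

    def rate(self, default: float) -> float:
        return default if self.learning_rate is None else self.learning_rate


@dataclass(frozen=True)
class TrackerResult:
    """Outcome of one tracker update.

    Exactly one of {``bbox`` present, ``failed``} holds.  ``confidence``
    is the PSR for MOSSE, the detection peak for KCF and the maximum
    correlation for NCC.
    """

    bbox: Optional[BoundingBox]
    failed: bool
    confidence: float

    def __post_init__(self):
        if (self.bbox is None) != self.failed:
            raise ValueError("bbox must be absent exactly when failed")
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")


# ---------------------------------------------------------------------------
# shared helpers


def _check_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a 2D grayscale array")
    return img


def _check_bbox_inside(bbox: BoundingBox, img: np.ndarray, min_area: float = 16.0):
    h, w = img.shape
    if bbox.x < 0 or bbox.y < 0 or bbox.x + bbox.w > w or bbox.y + bbox.h > h:
        raise ValueError("bounding box extends outside the image")
    if bbox.area < min_area:
        raise ValueError(f"bounding box area must be >= {min_area} px^2")


def _extract(img: np.ndarray, x0: int, y0: int, w: int, h: int) -> np.ndarray:
    """Window with edge-replication for out-of-bounds parts."""
    H, W = img.shape
    xs = np.clip(np.arange(x0, x0 + w), 0, W - 1)
    ys = np.clip(np.arange(y0, y0 + h), 0, H - 1)
    return img[np.ix_(ys, xs)]


def _normalize01(patch: np.ndarray) -> np.ndarray:
    lo = patch.min()
    rng = patch.max() - lo
    if rng <= 0:
        return np.zeros_like(patch)
    return (patch - lo) / rng


def _hann2d(h: int, w: int) -> np.ndarray:
    return np.outer(np.hanning(h), np.hanning(w))


def _gaussian_response(h: int, w: int, sigma: float, cy: float, cx: float) -> np.ndarray:
    ys = np.arange(h)[:, None] - cy
    xs = np.arange(w)[None, :] - cx
    return np.exp(-(ys**2 + xs**2) / (2.0 * sigma**2))


def _subpixel_offset(resp: np.ndarray, py: int, px: int) -> Tuple[float, float]:
    """Parabolic peak refinement with wrap-around neighbours."""

    def refine(vm, v0, vp):
        denom = 2.0 * v0 - vm - vp
        if denom <= 0:
            return 0.0
        off = 0.5 * (vp - vm) / denom
        return float(np.clip(off, -0.5, 0.5))

    h, w = resp.shape
    dy = refine(resp[(py - 1) % h, px], resp[py, px], resp[(py + 1) % h, px])
    dx = refine(resp[py, (px - 1) % w], resp[py, px], resp[py, (px + 1) % w])
    return dy, dx


def _window_geometry(bbox: BoundingBox, padding: float) -> Tuple[int, int]:
    win_w = max(int(round(bbox.w * padding)), int(np.ceil(bbox.w)) + 4)
    win_h = max(int(round(bbox.h * padding)), int(np.ceil(bbox.h)) + 4)
    return win_w, win_h


# ---------------------------------------------------------------------------
# MOSSE


class MosseTracker:
    """Minimum-output-sum-of-squared-error adaptive correlation filter.

    The filter is trained in the frequency domain as H* = A/B with
    A = sum G~ conj(F~), B = sum F~ conj(F~), over the initial patch and
    a small set of random small-angle/shift perturbations of it.  The
    desired output G is a narrow Gaussian at the window centre.
    Preprocessing: min-max normalize, log(1 + I), zero-mean/unit-variance,
    Hann window.  Confidence is the peak-to-sidelobe ratio with an 11x11
    exclusion window.
    """

    def __init__(self, image, bbox: BoundingBox, params: TrackerParams = TrackerParams()):
        img = _check_image(image)
        _check_bbox_inside(bbox, img)
        self.params = params
        self.shape = img.shape
        self.size = (bbox.w, bbox.h)
        self.center = list(bbox.center)
        self.win_w, self.win_h = _window_geometry(bbox, params.padding)
        self._hann = _hann2d(self.win_h, self.win_w)
        sigma = params.output_sigma_factor * float(np.sqrt(bbox.w * bbox.h))
        self._G = np.fft.fft2(
            _gaussian_response(self.win_h, self.win_w, sigma,
                               self.win_h // 2, self.win_w // 2)
        )
        patch = self._patch_at(img, self.center)
        if patch.max() - patch.min() <= 0:
            raise FlatPatchError("cannot initialize MOSSE on a constant patch")
        rng = np.random.default_rng(params.seed)
        self._A = np.zeros_like(self._G)
        self._B = np.zeros_like(self._G)
        for f in self._training_patches(patch, rng):
            F = np.fft.fft2(self._preprocess(f))
            self._A += self._G * np.conj(F)
            self._B += F * np.conj(F)

    # -- internals

    def _patch_at(self, img, center) -> np.ndarray:
        x0 = int(round(center[0] - self.win_w / 2.0))
        y0 = int(round(center[1] - self.win_h / 2.0))
        return _extract(img, x0, y0, self.win_w, self.win_h)

    def _training_patches(self, patch, rng):
        yield patch
        for _ in range(self.params.init_perturbations):
            angle = rng.uniform(-5.0, 5.0)
            shift = rng.uniform(-0.5, 0.5, size=2)
            warped = ndi.rotate(patch, angle, reshape=False, mode="nearest")
            yield ndi.shift(warped, shift, mode="nearest")

    def _preprocess(self, patch) -> np.ndarray:
        p = np.log1p(_normalize01(patch))
        p = (p - p.mean()) / (p.std() + _EPS)
        return p * self._hann

    def update(self, image) -> TrackerResult:
        img = _check_image(image)
        if img.shape != self.shape:
            raise ValueError("frame dimensions differ from the init frame")
        x0 = int(round(self.center[0] - self.win_w / 2.0))
        y0 = int(round(self.center[1] - self.win_h / 2.0))
        patch = _extract(img, x0, y0, self.win_w, self.win_h)
        F = np.fft.fft2(self._preprocess(patch))
        H = self._A / (self._B + _EPS)
        resp = np.real(np.fft.ifft2(H * F))
        py, px = np.unravel_index(int(np.argmax(resp)), resp.shape)
        psr = self._psr(resp, py, px)
        if psr < self.params.psr_fail_threshold:
            return TrackerResult(bbox=None, failed=True, confidence=psr)
        dy, dx = (0.0, 0.0)
        if self.params.subpixel:
            dy, dx = _subpixel_offset(resp, py, px)
        self.center[0] = x0 + px + dx
        self.center[1] = y0 + py + dy
        # online filter update on the re-centred patch
        new_patch = self._patch_at(img, self.center)
        Fn = np.fft.fft2(self._preprocess(new_patch))
        lr = self.params.rate(0.125)
        self._A = (1 - lr) * self._A + lr * self._G * np.conj(Fn)
        self._B = (1 - lr) * self._B + lr * Fn * np.conj(Fn)
        return TrackerResult(bbox=self._bbox(), failed=False, confidence=psr)

    def _psr(self, resp, py, px) -> float:
        mask = np.ones_like(resp, dtype=bool)
        half = 5  # 11x11 exclusion window around the peak
        ys = (np.arange(py - half, py + half + 1)) % resp.shape[0]
        xs = (np.arange(px - half, px + half + 1)) % resp.shape[1]
        mask[np.ix_(ys, xs)] = False
        side = resp[mask]
        sd = side.std()
        if sd <= 0:
            return 0.0
        return float((resp[py, px] - side.mean()) / sd)

    def _bbox(self) -> BoundingBox:
        w, h = self.size
        return BoundingBox(self.center[0] - w / 2.0, self.center[1] - h / 2.0, w, h)


# ---------------------------------------------------------------------------
# KCF


class KcfTracker:
    """Kernelized correlation filter on raw grayscale features.

    Training solves alpha~ = y~ / (k~xx + lambda) in the Fourier domain,
    with the Gaussian kernel correlation k computed through circulant
    identities (a handful of FFTs per frame).  Detection evaluates the
    response to the current window against the learned template; target
    and model are updated by linear interpolation.  Failure is declared
    when the detection peak drops below ``kcf_fail_fraction`` times the
    running mean of past successful peaks.
    """

    def __init__(self, image, bbox: BoundingBox, params: TrackerParams = TrackerParams()):
        img = _check_image(image)
        _check_bbox_inside(bbox, img)
        self.params = params
        self.shape = img.shape
        self.size = (bbox.w, bbox.h)
        self.center = list(bbox.center)
        self.win_w, self.win_h = _window_geometry(bbox, params.padding)
        self._hann = _hann2d(self.win_h, self.win_w)
        sigma = params.output_sigma_factor * float(np.sqrt(bbox.w * bbox.h))
        # desired response with its peak wrapped to index (0, 0)
        g = _gaussian_response(self.win_h, self.win_w, sigma,
                               self.win_h // 2, self.win_w // 2)
        self._yf = np.fft.fft2(np.roll(g, (-(self.win_h // 2), -(self.win_w // 2)),
                                       axis=(0, 1)))
        patch = self._patch_at(img, self.center)
        if patch.max() - patch.min() <= 0:
            raise FlatPatchError("cannot initialize KCF on a constant patch")
        self._x = self._features(patch)
        self._alphaf = self._train(self._x)
        self._mean_peak: Optional[float] = None

    def _patch_at(self, img, center) -> np.ndarray:
        x0 = int(round(center[0] - self.win_w / 2.0))
        y0 = int(round(center[1] - self.win_h / 2.0))
        return _extract(img, x0, y0, self.win_w, self.win_h)

    def _features(self, patch) -> np.ndarray:
        p = _normalize01(patch)
        return (p - p.mean()) * self._hann

    def _kernel(self, x1, x2) -> np.ndarray:
        """Gaussian kernel correlation of two windows, all shifts at once."""
        c = np.real(np.fft.ifft2(np.fft.fft2(x1) * np.conj(np.fft.fft2(x2))))
        d = (np.sum(x1**2) + np.sum(x2**2) - 2.0 * c) / x1.size
        return np.exp(-np.maximum(d, 0.0) / self.params.kcf_kernel_sigma**2)

    def _train(self, x) -> np.ndarray:
        kf = np.fft.fft2(self._kernel(x, x))
        return self._yf / (kf + self.params.kcf_lambda)

    def update(self, image) -> TrackerResult:
        img = _check_image(image)
        if img.shape != self.shape:
            raise ValueError("frame dimensions differ from the init frame")
        z = self._features(self._patch_at(img, self.center))
        kf = np.fft.fft2(self._kernel(z, self._x))
        resp = np.real(np.fft.ifft2(kf * self._alphaf))
        py, px = np.unravel_index(int(np.argmax(resp)), resp.shape)
        peak = float(resp[py, px])
        if self._mean_peak is not None and peak < self.params.kcf_fail_fraction * self._mean_peak:
            return TrackerResult(bbox=None, failed=True, confidence=peak)
        dy, dx = (0.0, 0.0)
        if self.params.subpixel:
            dy, dx = _subpixel_offset(resp, py, px)
        sy = py + dy
        sx = px + dx
        if sy > self.win_h / 2.0:
            sy -= self.win_h
        if sx > self.win_w / 2.0:
            sx -= self.win_w
        self.center[0] += sx
        self.center[1] += sy
        # model update by linear interpolation on the re-centred window
        xn = self._features(self._patch_at(img, self.center))
        lr = self.params.rate(0.02)
        self._x = (1 - lr) * self._x + lr * xn
        self._alphaf = (1 - lr) * self._alphaf + lr * self._train(xn)
        if self._mean_peak is None:
            self._mean_peak = peak
        else:
            self._mean_peak = 0.9 * self._mean_peak + 0.1 * peak
        return TrackerResult(bbox=self._bbox(), failed=False, confidence=peak)

    def _bbox(self) -> BoundingBox:
        w, h = self.size
        return BoundingBox(self.center[0] - w / 2.0, self.center[1] - h / 2.0, w, h)


# ---------------------------------------------------------------------------
# NCC baseline


def ncc_track(
    ref_patch,
    image,
    search_center: Tuple[float, float],
    search_radius: int = 12,
    fail_threshold: float = 0.2,
    subpixel: bool = False,
) -> Tuple[Tuple[float, float], float, bool]:
    """Exhaustive normalized cross-correlation over a search window.

    Returns ``(center, max_ncc, failed)`` where ``center`` is the best
    match position of the patch centre in image coordinates.  The search
    window is clipped to the image; confidence is the maximum NCC.
    """
    ref = _check_image(ref_patch)
    img = _check_image(image)
    th, tw = ref.shape
    cx, cy = search_center
    x0 = int(round(cx - tw / 2.0)) - search_radius
    y0 = int(round(cy - th / 2.0)) - search_radius
    x1 = x0 + tw + 2 * search_radius
    y1 = y0 + th + 2 * search_radius
    x0 = max(x0, 0)
    y0 = max(y0, 0)
    x1 = min(x1, img.shape[1])
    y1 = min(y1, img.shape[0])
    window = img[y0:y1, x0:x1]
    if window.shape[0] < th or window.shape[1] < tw:
        raise ValueError("search window smaller than the reference patch")
    corr = match_template(window, ref, pad_input=False)
    py, px = np.unravel_index(int(np.argmax(corr)), corr.shape)
    conf = float(corr[py, px])
    dy = dx = 0.0
    if subpixel and 0 < py < corr.shape[0] - 1 and 0 < px < corr.shape[1] - 1:
        dy, dx = _subpixel_offset(corr, py, px)
    center = (x0 + px + dx + tw / 2.0, y0 + py + dy + th / 2.0)
    return center, conf, conf < fail_threshold


class NccTracker:
    """Template matcher using the initialization patch as fixed reference."""

    def __init__(self, image, bbox: BoundingBox, params: TrackerParams = TrackerParams()):
        img = _check_image(image)
        _check_bbox_inside(bbox, img)
        self.params = params
        self.shape = img.shape
        self.size = (bbox.w, bbox.h)
        self.center = list(bbox.center)
        x0 = int(round(bbox.x))
        y0 = int(round(bbox.y))
        self._ref = img[y0:y0 + int(round(bbox.h)), x0:x0 + int(round(bbox.w))].copy()
        if self._ref.max() - self._ref.min() <= 0:
            raise FlatPatchError("cannot initialize NCC on a constant patch")

    def update(self, image) -> TrackerResult:
        img = _check_image(image)
        if img.shape != self.shape:
            raise ValueError("frame dimensions differ from the init frame")
        center, conf, failed = ncc_track(
            self._ref, img, tuple(self.center),
            search_radius=int(self.params.search_radius),
            fail_threshold=self.params.ncc_fail_threshold,
            subpixel=self.params.subpixel,
        )
        if failed:
            return TrackerResult(bbox=None, failed=True, confidence=conf)
        self.center = list(center)
        w, h = self.size
        bbox = BoundingBox(center[0] - w / 2.0, center[1] - h / 2.0, w, h)
        return TrackerResult(bbox=bbox, failed=False, confidence=conf)


# ---------------------------------------------------------------------------
# registry and series driver

TRACKER_KINDS: Dict[str, Callable] = {
    "mosse": MosseTracker,
    "kcf": KcfTracker,
    "ncc": NccTracker,
}


def register_tracker(name: str, factory: Callable) -> None:
    """Register an external tracker backend.

    ``factory(image, bbox, params)`` must return an object with an
    ``update(image) -> TrackerResult`` method; this is the adapter slot
    for library trackers (e.g. the OpenCV tracking API) which are
    optional and never required.
    """
    TRACKER_KINDS[name] = factory


def make_tracker(kind: str, image, bbox: BoundingBox,
                 params: TrackerParams = TrackerParams()):
    try:
        factory = TRACKER_KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown tracker kind {kind!r}; known: {sorted(TRACKER_KINDS)}"
        ) from None
    return factory(image, bbox, params)


@dataclass
class TrackingLog:
    """Per-frame tracking results for one slice series.

    ``results[0]`` is a pseudo-result for the reference frame itself
    (zero displacement).  Displacements are bounding-box-centre shifts
    relative to the initialization frame, in px and (via the pixel size)
    in mm; failed frames carry NaN displacements and ``failed=True``.
    """

    results: List[TrackerResult]
    init_bbox: BoundingBox
    pixel_size: Tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        cx0, cy0 = self.init_bbox.center
        px, py = self.pixel_size
        rows = []
        for i, r in enumerate(self.results):
            if r.failed:
                rows.append(dict(frame=i, x=np.nan, y=np.nan,
                                 w=self.init_bbox.w, h=self.init_bbox.h,
                                 dx_px=np.nan, dy_px=np.nan,
                                 dx_mm=np.nan, dy_mm=np.nan,
                                 confidence=r.confidence, failed=True))
            else:
                cx, cy = r.bbox.center
                rows.append(dict(frame=i, x=r.bbox.x, y=r.bbox.y,
                                 w=r.bbox.w, h=r.bbox.h,
                                 dx_px=cx - cx0, dy_px=cy - cy0,
                                 dx_mm=(cx - cx0) * px, dy_mm=(cy - cy0) * py,
                                 confidence=r.confidence, failed=False))
        return pd.DataFrame(rows)

    @property
    def displacements_px(self) -> np.ndarray:
        """(T, 2) centre shifts in px; NaN where tracking failed."""
        cx0, cy0 = self.init_bbox.center
        out = np.full((len(self.results), 2), np.nan)
        for i, r in enumerate(self.results):
            if not r.failed:
                cx, cy = r.bbox.center
                out[i] = (cx - cx0, cy - cy0)
        return out

    @property
    def displacements_mm(self) -> np.ndarray:
        return self.displacements_px * np.asarray(self.pixel_size)

    @property
    def failed_flags(self) -> np.ndarray:
        return np.array([r.failed for r in self.results], dtype=bool)


def track_series(
    frames: Sequence[np.ndarray],
    init_bbox: BoundingBox,
    tracker_kind: str = "kcf",
    params: TrackerParams = TrackerParams(),
    pixel_size: Tuple[float, float] = (1.0, 1.0),
) -> TrackingLog:
    """Track a target through an image series.

    ``frames[0]`` is the reference frame on which the tracker is
    initialized with ``init_bbox``; one :class:`TrackerResult` is
    produced per subsequent frame.  The returned log also contains a
    pseudo-result for the reference frame (zero displacement, infinite
    confidence is not used — the init box with NaN-free zero shift).
    """
    if len(frames) < 2:
        raise ValueError("a series needs at least 2 frames (reference + 1)")
    tracker = make_tracker(tracker_kind, frames[0], init_bbox, params)
    results = [TrackerResult(bbox=init_bbox, failed=False, confidence=0.0)]
    for frame in frames[1:]:
        results.append(tracker.update(frame))
    return TrackingLog(results=results, init_bbox=init_bbox, pixel_size=pixel_size)
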