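"""Displacement features and regularized-SVD fusion into one 3D translation.

Each tracked bounding box on a navigator slice contributes four scalar
displacement observations ("features"), one per box edge.  A feature is
a triple (a_i, b_i, w_i): a 3D unit direction in patient coordinates, a
signed length in mm, and a nonnegative weight.  Stacking m features gives
the weighted linear system

    W A x = W b,     A in R^{m x 3},  W = diag(w_i),

whose minimum-norm solution is computed from the SVD of the weighted
matrix, with Tikhonov-filtered inverse singular values

    x = sum_i  (u_i^T b~) v_i  *  sigma_i / (sigma_i^2 + tau^2),

tau = 0.05 by default.  Components of x lying in the null space of the
weighted system come out exactly zero: a single coronal slice, for
example, says nothing about AP motion and leaves that component at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .geometry import SlicePlane

__all__ = [
    "BoundingBox",
    "Feature",
    "FusionConfig",
    "AllSlicesFailed",
    "features_from_bbox",
    "combine_features",
    "fuse_frame",
]

# Singular values below this fraction of sigma_max are treated as exact
# rank deficiency and dropped before the Tikhonov filter is applied.
_RANK_TOL = 1e-12


class AllSlicesFailed(RuntimeError):
    """Raised when no slice delivered a usable tracking update this frame."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner (x, y), width and height in px.

    0-based, half-open: the box covers columns [x, x+w) and rows [y, y+h).
    Coordinates may be fractional (sub-pixel tracking).
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        vals = (self.x, self.y, self.w, self.h)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("bounding box fields must be finite")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bounding box width and height must be > 0")

    @property
    def center(self) -> Tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.w, self.h)


@dataclass(frozen=True)
class Feature:
    """One scalar displacement observation.

    ``direction_a`` is a 3D unit vector in patient coordinates,
    ``length_b`` the signed displacement along it in mm, ``weight_w`` a
    nonnegative confidence weight.
    """

    direction_a: np.ndarray
    length_b: float
    weight_w: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.direction_a, dtype=float)
        if a.shape != (3,):
            raise ValueError("direction_a must be a 3-vector")
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError("direction_a must be a unit vector")
        if not np.isfinite(self.length_b):
            raise ValueError("length_b must be finite")
        if not (np.isfinite(self.weight_w) and self.weight_w >= 0):
            raise ValueError("weight_w must be finite and >= 0")
        object.__setattr__(self, "direction_a", a)


@dataclass(frozen=True)
class FusionConfig:
    """Fusion parameters: Tikhonov scale ``tau`` and the default weight."""

    tau: float = 0.05
    default_weight: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise ValueError("tau must be finite and >= 0")
        if not (np.isfinite(self.default_weight) and self.default_weight >= 0):
            raise ValueError("default_weight must be finite and >= 0")


#: Edge labels in the order features are emitted.
EDGE_ORDER = ("left", "right", "top", "bottom")


def features_from_bbox(
    ref: BoundingBox,
    cur: BoundingBox,
    plane: SlicePlane,
    weight: float = 1.0,
) -> list[Feature]:
    """Four edge features from a reference and a current bounding box.

    Left/right edges move along the plane's e1 direction, top/bottom
    along e2; lengths are the signed per-edge displacements converted to
    mm with the in-plane pixel sizes.  For a rigid box the two features
    per direction are redundant by construction and deliberately kept
    (m = 4 per slice); boxes that change size yield distinct per-edge
    lengths.
    """
    p_x, p_y = plane.pixel_size
    a_x = plane.e1
    a_y = plane.e2
    left = (cur.x - ref.x) * p_x
    right = ((cur.x + cur.w) - (ref.x + ref.w)) * p_x
    top = (cur.y - ref.y) * p_y
    bottom = ((cur.y + cur.h) - (ref.y + ref.h)) * p_y
    return [
        Feature(a_x, left, weight),
        Feature(a_x, right, weight),
        Feature(a_y, top, weight),
        Feature(a_y, bottom, weight),
    ]


def combine_features(
    features: Sequence[Feature],
    cfg: FusionConfig = FusionConfig(),
) -> np.ndarray:
    """Solve the weighted feature system for the 3D translation (mm).

    Builds the weighted matrix and right-hand side, takes its SVD, and
    applies the Tikhonov-filtered pseudo-inverse.  With tau = 0 and a
    full-rank system this is the ordinary weighted least-squares
    solution; rank-deficient directions contribute exactly zero.
    """
    if len(features) == 0:
        raise ValueError("at least one feature is required")
    A = np.stack([f.direction_a for f in features])
    b = np.array([f.length_b for f in features], dtype=float)
    w = np.array([f.weight_w for f in features], dtype=float)
    if not np.any(w > 0):
        raise ValueError("at least one feature must carry positive weight")
    Aw = A * w[:, None]
    bw = b * w
    U, s, Vt = np.linalg.svd(Aw, full_matrices=False)
    keep = s > _RANK_TOL * s[0]
    if not np.any(keep):
        return np.zeros(3)
    s = s[keep]
    coef = (U.T @ bw)[keep] * s / (s**2 + cfg.tau**2)
    return Vt[keep].T @ coef


def fuse_frame(
    per_slice_boxes: Mapping[str, Optional[Tuple[BoundingBox, BoundingBox]]],
    planes: Mapping[str, SlicePlane],
    cfg: FusionConfig = FusionConfig(),
) -> Tuple[np.ndarray, int]:
    """Pool edge features from all non-failed slices and fuse them.

    ``per_slice_boxes`` maps slice name to ``(ref_box, cur_box)`` or
    ``None`` for a slice whose tracker reported failure.  Failed slices
    are dropped; only a frame with no valid slice at all raises
    :class:`AllSlicesFailed` ("no update possible" — the prospective loop
    then holds the last applied position).

    Returns ``(x, n_valid_slices)``.
    """
    features: list[Feature] = []
    n_valid = 0
    for name, boxes in per_slice_boxes.items():
        if boxes is None:
            continue
        ref, cur = boxes
        features.extend(
            features_from_bbox(ref, cur, planes[name], weight=cfg.default_weight)
        )
        n_valid += 1
    if n_valid == 0:
        raise AllSlicesFailed("all slices failed; no position update possible")
    return combine_features(features, cfg), n_valid
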