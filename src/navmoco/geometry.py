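"""Slice-plane geometry and 2D image <-> 3D patient coordinate transforms.

Patient coordinates throughout this package are the (LR, AP, HF) axes in
millimetres: left-right, anterior-posterior and head-foot, fixed to the
subject.  Sign conventions are +LR = patient-left, +AP = posterior,
+HF = head-ward, which makes the numeric triple identical to DICOM LPS
(axis 3 = Superior).  Conversions to/from LPS and RAS live in
:mod:`navmoco.io_cli`.

A navigator slice is described by a :class:`SlicePlane`: two orthonormal
3D unit vectors ``e1`` (direction of increasing image x / column index)
and ``e2`` (direction of increasing image y / row index), the patient
position of the centre of pixel (0, 0), the pixel sizes and the matrix
size.  A 2D in-plane vector ``d`` (pixels) maps to patient space as

    x = R P d (+ q)

with R = (e1, e2) the 3x2 basis matrix, P = diag(p_x, p_y) the pixel
scaling and q the origin shift (applied in position mode only; pure
displacements do not see q because it cancels in differences).

Image coordinates are 0-based with x = column index (first image axis)
and y = row index; pixel centres sit at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "SlicePlane",
    "Displacement2D",
    "named_plane",
    "image_to_patient",
    "patient_to_image",
    "AXIS_NAMES",
]

#: Index of each patient axis in 3-vectors used across the package.
AXIS_NAMES: Tuple[str, str, str] = ("LR", "AP", "HF")

_UNIT_TOL = 1e-9


def _as_vec(v, n, name):
    a = np.asarray(v, dtype=float)
    if a.shape != (n,):
        raise ValueError(f"{name} must be a length-{n} vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


@dataclass(frozen=True)
class SlicePlane:
    """Geometry of one navigator slice in patient coordinates.

    Parameters
    ----------
    e1, e2
        Orthonormal 3D unit vectors spanning the image plane; ``e1`` points
        along increasing column index, ``e2`` along increasing row index.
    origin_q
        Patient position (mm) of the centre of pixel (0, 0).
    pixel_size
        (p_x, p_y) in mm/px, both > 0.
    dims
        (n_x, n_y) matrix size in pixels, both >= 8.
    """

    e1: np.ndarray
    e2: np.ndarray
    origin_q: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pixel_size: Tuple[float, float] = (2.7, 2.7)
    dims: Tuple[int, int] = (64, 64)

    def __post_init__(self):
        e1 = _as_vec(self.e1, 3, "e1")
        e2 = _as_vec(self.e2, 3, "e2")
        q = _as_vec(self.origin_q, 3, "origin_q")
        if abs(np.linalg.norm(e1) - 1.0) > _UNIT_TOL:
            raise ValueError("e1 must be a unit vector")
        if abs(np.linalg.norm(e2) - 1.0) > _UNIT_TOL:
            raise ValueError("e2 must be a unit vector")
        if abs(float(e1 @ e2)) > _UNIT_TOL:
            raise ValueError("e1 and e2 must be orthogonal")
        p = tuple(float(v) for v in self.pixel_size)
        if len(p) != 2 or any(v <= 0 for v in p):
            raise ValueError("pixel_size components must be > 0")
        d = tuple(int(v) for v in self.dims)
        if len(d) != 2 or any(v < 8 for v in d):
            raise ValueError("dims components must be >= 8")
        object.__setattr__(self, "e1", e1)
        object.__setattr__(self, "e2", e2)
        object.__setattr__(self, "origin_q", q)
        object.__setattr__(self, "pixel_size", p)
        object.__setattr__(self, "dims", d)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal e1 x e2 (through-plane direction)."""
        return np.cross(self.e1, self.e2)

    @property
    def basis(self) -> np.ndarray:
        """3x2 matrix R = (e1, e2)."""
        return np.stack([self.e1, self.e2], axis=1)

    @property
    def fov_mm(self) -> Tuple[float, float]:
        return (self.dims[0] * self.pixel_size[0], self.dims[1] * self.pixel_size[1])

    def to_dict(self) -> dict:
        return {
            "e1": self.e1.tolist(),
            "e2": self.e2.tolist(),
            "origin_q": self.origin_q.tolist(),
            "pixel_size": list(self.pixel_size),
            "dims": list(self.dims),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlicePlane":
        return cls(
            e1=np.asarray(d["e1"], dtype=float),
            e2=np.asarray(d["e2"], dtype=float),
            origin_q=np.asarray(d.get("origin_q", (0.0, 0.0, 0.0)), dtype=float),
            pixel_size=tuple(d.get("pixel_size", (2.7, 2.7))),
            dims=tuple(d.get("dims", (64, 64))),
        )


@dataclass(frozen=True)
class Displacement2D:
    """Signed in-plane displacement in pixels (image coordinates)."""

    dx: float
    dy: float

    def __post_init__(self):
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValueError("displacement components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)


# Named-plane conventions, standard radiological display:
#   coronal:     image x -> +LR (patient-left), image y -> -HF (foot-ward down)
#   sagittal:    image x -> +AP (posterior),    image y -> -HF
#   transversal: image x -> +LR,                image y -> +AP
_NAMED_BASES = {
    "coronal": ((1.0, 0.0, 0.0), (0.0, 0.0, -1.0)),
    "sagittal": ((0.0, 1.0, 0.0), (0.0, 0.0, -1.0)),
    "transversal": ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
}


def named_plane(
    orientation: str,
    pixel_size: Tuple[float, float] = (2.7, 2.7),
    dims: Tuple[int, int] = (64, 64),
    origin_q=(0.0, 0.0, 0.0),
) -> SlicePlane:
    """Build a :class:`SlicePlane` for one of the anatomical orientations.

    ``orientation`` must be one of ``sagittal``, ``coronal``,
    ``transversal``.  Any other plane must be supplied explicitly through
    the :class:`SlicePlane` constructor.
    """
    try:
        e1, e2 = _NAMED_BASES[orientation]
    except KeyError:
        raise ValueError(
            f"unknown orientation {orientation!r}; expected one of "
            f"{sorted(_NAMED_BASES)}"
        ) from None
    return SlicePlane(
        e1=np.array(e1), e2=np.array(e2), origin_q=np.asarray(origin_q, dtype=float),
        pixel_size=pixel_size, dims=dims,
    )


def _d2_array(d) -> np.ndarray:
    if isinstance(d, Displacement2D):
        return d.as_array()
    a = np.asarray(d, dtype=float)
    if a.shape[-1] != 2:
        raise ValueError("2D displacement must have last dimension 2")
    return a


def image_to_patient(d, plane: SlicePlane, as_position: bool = False) -> np.ndarray:
    """Map a 2D image-space vector (px) to patient coordinates (mm).

    Returns ``R P d`` — the pure linear map used for displacements — or
    ``R P d + q`` when ``as_position`` is set (pixel (0,0) maps to the
    plane origin).  Accepts a :class:`Displacement2D`, a length-2 array,
    or an (..., 2) stack of vectors.
    """
    a = _d2_array(d)
    p = np.asarray(plane.pixel_size)
    out = (a * p) @ plane.basis.T
    if as_position:
        out = out + plane.origin_q
    return out


def patient_to_image(x, plane: SlicePlane, as_position: bool = False) -> np.ndarray:
    """Project a patient-space vector (mm) onto the plane, in pixels.

    The orthogonal projection onto (e1, e2) divided by the pixel sizes;
    inverse of :func:`image_to_patient` for in-plane vectors.  With
    ``as_position`` the plane origin is subtracted first.
    """
    a = np.asarray(x, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError("patient-space vector must have last dimension 3")
    if as_position:
        a = a - plane.origin_q
    p = np.asarray(plane.pixel_size)
    return (a @ plane.basis) / p
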