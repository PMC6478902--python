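"""Homogeneous similarity transforms and warping helpers.

Every geometric relation between views (frame-to-frame, frame-to-scene,
frame-to-canvas) is stored as a 3x3 homogeneous matrix acting on column
vectors ``[x, y, 1]^T`` with x = column index and y = row index, origin at
the top-left pixel centre.  The transform model is a similarity (uniform
scale * rotation + translation, 4 degrees of freedom), which captures the
three distortion classes of flexible endoscopy: translation, rotation and
magnification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GeometricTransform:
    """A 3x3 homogeneous similarity transform.

    Attributes
    ----------
    matrix : (3, 3) ndarray
        Homogeneous matrix with last row ``[0, 0, 1]`` and upper-left 2x2
        block equal to ``s * R`` for a scale ``s > 0`` and rotation ``R``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"transform matrix must be 3x3, got {m.shape}")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of a homogeneous transform must be [0, 0, 1]")
        if np.linalg.det(m[:2, :2]) <= 0:
            raise ValueError("transform must be orientation-preserving with positive scale")
        object.__setattr__(self, "matrix", m)

    # -- constructors ---------------------------------------------------

    @classmethod
    def identity(cls) -> "GeometricTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(
        cls,
        translation: tuple[float, float] = (0.0, 0.0),
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "GeometricTransform":
        """Build ``p' = t + c + s R (p - c)`` from explicit parameters.

        ``translation`` is applied on top of the rotation/scale about
        ``center`` (both in (x, y) order), so a frame whose centre sits at
        ``center`` maps that centre to ``center + translation``.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        sr = scale * np.array([[c, -s], [s, c]])
        cx, cy = center
        tx, ty = translation
        m = np.eye(3)
        m[:2, :2] = sr
        m[:2, 2] = np.array([tx + cx, ty + cy]) - sr @ np.array([cx, cy])
        return cls(m)

    # -- algebra --------------------------------------------------------

    def __matmul__(self, other: "GeometricTransform") -> "GeometricTransform":
        """Composition: ``(A @ B)(p) == A(B(p))``."""
        return GeometricTransform(self.matrix @ other.matrix)

    def inverse(self) -> "GeometricTransform":
        return GeometricTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    # -- similarity parameters ------------------------------------------

    @property
    def scale(self) -> float:
        return float(np.sqrt(np.linalg.det(self.matrix[:2, :2])))

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    @property
    def translation(self) -> np.ndarray:
        """Translation component (x, y) of the matrix."""
        return self.matrix[:2, 2].copy()

    def is_similarity(self, rtol: float = 1e-6) -> bool:
        sv = np.linalg.svd(self.matrix[:2, :2], compute_uv=False)
        return bool(np.abs(sv[0] - sv[1]) <= rtol * sv[0])

    def compare(self, other: "GeometricTransform", extent: float = 0.0):
        """Parameter-space difference to another similarity transform.

        Returns ``(translation_err_px, rotation_err_deg, scale_err)`` where
        the translation error is the displacement of the point at the centre
        of a square of side ``extent`` (the frame centre when ``extent`` is
        the frame size), rotation error is in degrees and scale error is the
        relative scale difference.
        """
        c = np.array([(extent - 1) / 2.0, (extent - 1) / 2.0])
        d = np.linalg.norm(self.apply(c) - other.apply(c))
        dr = abs(self.rotation_deg - other.rotation_deg)
        ds = abs(self.scale - other.scale) / other.scale
        return float(d), float(dr), float(ds)


def warp_image(
    image: np.ndarray,
    transform: GeometricTransform,
    output_shape: tuple[int, int],
    offset: tuple[float, float] = (0.0, 0.0),
    order: int = 1,
    cval: float = np.nan,
) -> np.ndarray:
    """Warp ``image`` so that output pixel ``p`` holds ``image(T^-1(p + offset))``.

    ``transform`` maps image (source) coordinates to output (destination)
    coordinates; ``offset`` is the (y, x) origin of the output grid in
    destination coordinates.  Bilinear by default, constant fill outside.
    """
    h, w = output_shape
    inv = transform.inverse().matrix
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    xx += offset[1]
    yy += offset[0]
    xs = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
    ys = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
    return ndimage.map_coordinates(
        np.asarray(image, dtype=float), [ys, xs], order=order, cval=cval, mode="constant"
    )


def footprint_bbox(
    shape: tuple[int, int], transform: GeometricTransform
) -> tuple[float, float, float, float]:
    """Bounding box (ymin, xmin, ymax, xmax) of a warped image footprint."""
    h, w = shape
    corners = np.array(
        [[-0.5, -0.5], [w - 0.5, -0.5], [-0.5, h - 0.5], [w - 0.5, h - 0.5]]
    )
    warped = transform.apply(corners)
    return (
        float(warped[:, 1].min()),
        float(warped[:, 0].min()),
        float(warped[:, 1].max()),
        float(warped[:, 0].max()),
    )
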