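"""Wide-field frame conditioning ahead of registration.

Raw monochrome endoscope frames carry several instrument signatures that
defeat feature matching if left in place: sensor dark counts and
illumination non-uniformity, radial (barrel) lens distortion, the
honeycomb lattice imprinted by the cores of the imaging fibre bundle, and
the dark border outside the bundle's circular field.  The fixed pipeline is

    normalise -> lens-correct -> honeycomb removal -> crop to field

implemented by :func:`preprocess_frame`; each stage is also exposed on its
own.  All stages propagate the frame's acquisition index, validity mask and
coordinate origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image


class FieldDetectionError(ValueError):
    """No bright circular field could be detected in a frame."""


@dataclass
class WidefieldFrame:
    """One monochrome wide-field endoscopic frame.

    Attributes
    ----------
    data : 2D ndarray
        Intensities (raw counts or normalised reflectance).
    index : int
        Acquisition order within the stream.
    valid_mask : 2D bool ndarray
        True where the pixel carries usable signal (inside the fibre-bundle
        field, positive calibration denominator, inside warp support).
    origin : (float, float)
        (row, col) of ``data[0, 0]`` in the acquisition coordinate system;
        cropping moves the origin so keypoint coordinates stay comparable
        across frames.
    """

    data: np.ndarray
    index: int = 0
    valid_mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2D")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape:
                raise ValueError("valid_mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class CalibrationPair:
    """White-reference and dark (shutter-closed) calibration frames."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark calibration frames must share a shape")


@dataclass
class LensModel:
    """Radial magnification model about an optical centre.

    A point at polar radius ``r`` from ``center`` maps to radius
    ``alpha * r`` (uniform radial rescale).  ``alpha_poly``, when given,
    replaces the scalar with ``alpha(r) = c0 + c1*r + c2*r**2 + ...`` to
    express magnification that varies along the radial axis.
    """

    alpha: float = 1.0
    center: tuple[float, float] | None = None  # (x0, y0); frame centre if None
    alpha_poly: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.alpha_poly is None and self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def radial_scale(self, r: np.ndarray) -> np.ndarray:
        if self.alpha_poly is None:
            return np.full_like(np.asarray(r, dtype=float), self.alpha)
        return np.polyval(self.alpha_poly[::-1], np.asarray(r, dtype=float))


def normalize_reflectance(
    frame: WidefieldFrame, cal: CalibrationPair, eps: float = 1e-6
) -> WidefieldFrame:
    """Flat-field the frame: ``(I - I_dark) / (I_white - I_dark)``.

    Pixels whose white/dark difference is not positive carry no calibration
    information and are marked invalid rather than filled.
    """
    if cal.white.shape != frame.data.shape:
        raise ValueError("calibration frames must match the frame shape")
    denom = cal.white - cal.dark
    good = denom > eps
    out = (frame.data - cal.dark) / np.where(good, denom, eps)
    return replace(frame, data=out, valid_mask=frame.valid_mask & good)


def _radial_map(shape, center, scale_fn, invert):
    """Sampling coordinates implementing the radial rescale (inverse map)."""
    h, w = shape
    x0, y0 = center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - x0, yy - y0
    r = np.hypot(dx, dy)
    alpha = scale_fn(r)
    # forward map sends r -> alpha(r) * r; resampling needs the inverse
    if invert:
        rs = np.where(r > 0, alpha, 1.0)  # sampling radius = alpha * r
    else:
        rs = np.where(r > 0, 1.0 / np.where(alpha > 0, alpha, 1.0), 1.0)
    return y0 + dy * rs, x0 + dx * rs


def correct_lens_distortion(
    frame: WidefieldFrame, model: LensModel, invert: bool = False
) -> WidefieldFrame:
    """Rescale every pixel's radial coordinate by ``alpha`` about the centre.

    With ``invert=True`` the reciprocal rescale is applied, so correcting and
    inverting with the same model round-trips to interpolation tolerance.
    Bilinear resampling; pixels sampled outside the source are invalidated.
    """
    h, w = frame.shape
    center = model.center
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if not (0 <= center[0] < w and 0 <= center[1] < h):
        raise ValueError("lens centre must lie inside the frame")
    if model.alpha_poly is not None and model.alpha_poly[0] <= 0:
        raise ValueError("alpha(r) must be positive at r=0")
    ys, xs = _radial_map(frame.shape, center, model.radial_scale, invert)
    data = ndimage.map_coordinates(frame.data, [ys, xs], order=1, cval=np.nan)
    mask = (
        ndimage.map_coordinates(
            frame.valid_mask.astype(float), [ys, xs], order=1, cval=0.0
        )
        > 0.99
    )
    mask &= np.isfinite(data)
    return replace(frame, data=np.nan_to_num(data), valid_mask=mask)


def estimate_lattice_frequency(
    data: np.ndarray, min_freq: float = 0.06
) -> float | None:
    """Locate the fibre-bundle lattice fundamental in the power spectrum.

    Radially binned 2D power spectrum, detrended by a wide median filter;
    the strongest ratio peak at frequency >= ``min_freq`` cycles/px is taken
    as the lattice fundamental.  Returns None when no prominent peak exists
    (e.g. frames without a honeycomb pattern).
    """
    f = np.fft.fft2(data - data.mean())
    p = np.abs(f) ** 2
    fy = np.fft.fftfreq(data.shape[0])[:, None]
    fx = np.fft.fftfreq(data.shape[1])[None, :]
    fr = np.hypot(fy, fx)
    nbins = 200
    idx = np.minimum((fr * 2 * nbins).astype(int), nbins - 1)  # fr in [0, ~0.707]
    prof = np.bincount(idx.ravel(), weights=p.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    prof = prof / np.maximum(counts, 1)
    smooth = ndimage.median_filter(prof, size=31)
    ratio = prof / np.maximum(smooth, 1e-30)
    freqs = (np.arange(nbins) + 0.5) / (2 * nbins)
    sel = freqs >= min_freq
    if not sel.any() or ratio[sel].max() < 3.0:
        return None
    return float(freqs[sel][np.argmax(ratio[sel])])


def remove_honeycomb(
    frame: WidefieldFrame, cutoff: float | str = "auto"
) -> WidefieldFrame:
    """Suppress the fibre-core lattice with a radial Fourier low-pass.

    ``cutoff`` is in cycles/pixel in ``(0, 0.5]``; ``"auto"`` places it at
    0.6x the estimated lattice fundamental (falling back to 0.25 when no
    lattice is detected).  A hard radial mask is used, so the filter is
    exactly idempotent and preserves the mean (DC) intensity.
    """
    if cutoff == "auto":
        f0 = estimate_lattice_frequency(frame.data)
        cutoff = 0.6 * f0 if f0 is not None else 0.25
    cutoff = float(cutoff)
    if not 0.0 < cutoff <= 0.5:
        raise ValueError("cutoff must lie in (0, 0.5] cycles/pixel")
    f = np.fft.fft2(frame.data)
    fy = np.fft.fftfreq(frame.data.shape[0])[:, None]
    fx = np.fft.fftfreq(frame.data.shape[1])[None, :]
    keep = np.hypot(fy, fx) < cutoff
    out = np.fft.ifft2(f * keep).real
    return replace(frame, data=out)


def crop_to_field(
    frame: WidefieldFrame,
    rel_threshold: float = 0.1,
    mask_erosion: int = 0,
    inscribed: bool = False,
) -> WidefieldFrame:
    """Crop to the bright fibre-bundle field.

    The field is found as the convex hull of pixels brighter than
    ``rel_threshold`` times the robust (99.5th percentile) maximum, which
    bridges dark scene regions inside the field.  By default the crop is
    the axis-aligned bounding box of the field; with ``inscribed=True`` it
    is the largest axis-aligned square guaranteed inside the field (centred
    at the deepest interior point), which removes the static field boundary
    entirely — the boundary is identical in every frame and otherwise
    biases feature-based motion estimation toward zero motion.  The frame
    origin is shifted so coordinates remain expressed in the uncropped
    system, and ``valid_mask`` is restricted accordingly.
    """
    data = frame.data
    thr = rel_threshold * np.percentile(data, 99.5)
    bright = data > thr
    if not bright.any() or thr <= 0:
        raise FieldDetectionError("no bright field detected (all-dark frame)")
    hull = convex_hull_image(bright)
    if mask_erosion > 0:
        hull = ndimage.binary_erosion(hull, iterations=mask_erosion)
    if inscribed:
        dist = ndimage.distance_transform_edt(hull)
        cy, cx = np.unravel_index(np.argmax(dist), dist.shape)
        half = int((dist[cy, cx] - 1) / np.sqrt(2.0))
        if half < 1:
            raise FieldDetectionError("field too small for an inscribed crop")
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
    else:
        rows = np.flatnonzero(hull.any(axis=1))
        cols = np.flatnonzero(hull.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
    return replace(
        frame,
        data=data[r0:r1, c0:c1],
        valid_mask=(frame.valid_mask & hull)[r0:r1, c0:c1],
        origin=(frame.origin[0] + r0, frame.origin[1] + c0),
    )


def preprocess_frame(
    frame: WidefieldFrame,
    cal: CalibrationPair | None = None,
    lens: LensModel | None = None,
    cutoff: float | str | None = "auto",
    crop: bool = True,
    rel_threshold: float = 0.1,
    mask_erosion: int = 0,
) -> WidefieldFrame:
    """Run the fixed conditioning pipeline on one frame.

    Stages with a None argument are skipped; the order is always
    normalise -> lens-correct -> honeycomb -> crop.
    """
    if cal is not None:
        frame = normalize_reflectance(frame, cal)
    if lens is not None:
        frame = correct_lens_distortion(frame, lens)
    if cutoff is not None:
        frame = remove_honeycomb(frame, cutoff)
    if crop:
        frame = crop_to_field(frame, rel_threshold, mask_erosion)
    return frame
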