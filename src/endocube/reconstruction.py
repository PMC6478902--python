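"""Hypercube assembly from registered line-scan spectral slices.

Each spectral slice is a (y, lambda) image recorded through the
spectrograph entrance slit, intrinsically co-registered with one wide-field
frame.  For every wavelength, the slice column is replicated horizontally
to the physical slit width, placed at the slit's position in frame
coordinates (the central columns), warped by the frame's global transform
and accumulated on the canvas; averaging the overlapping contributions per
wavelength yields the (y, x, lambda) hypercube.  Geometry is wavelength
independent, so a single coverage map describes the whole cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometricTransform


@dataclass
class SpectralSlice:
    """One line-scan spectral image: rows are spatial (y), columns spectral."""

    data: np.ndarray  # (y, lambda)
    wavelengths: np.ndarray
    frame_index: int = 0
    slit_width_px: float = 1.0  # slit width in wide-field pixel units
    slit_center_x: float | None = None  # slit centre column in frame coords
    frame_height: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("slice data must be 2D (y, lambda)")
        if len(self.wavelengths) != self.data.shape[1]:
            raise ValueError("wavelength axis must match the spectral dimension")
        if len(self.wavelengths) > 1 and not (
            np.all(np.diff(self.wavelengths) > 0) or np.all(np.diff(self.wavelengths) < 0)
        ):
            raise ValueError("wavelengths must be strictly monotone")
        if self.frame_height is None:
            self.frame_height = self.data.shape[0]
        if self.slit_center_x is None:
            self.slit_center_x = (self.frame_height - 1) / 2.0


@dataclass
class Hypercube:
    """Reconstructed (y, x, lambda) cube on the global canvas.

    Pixels never covered by a slice are NaN with ``coverage == 0``;
    ``offset`` is the (y, x) position of ``data[0, 0]`` in the reference
    frame's coordinate system, shared with the wide-field panorama so the
    two overlay consistently.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    coverage: np.ndarray
    offset: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self):
        return self.data.shape

    def channel(self, i: int) -> np.ndarray:
        return self.data[:, :, i]


def slice_to_strip(sl: SpectralSlice, wavelength_index: int) -> tuple[np.ndarray, float]:
    """Replicate one wavelength column to the physical slit width.

    Returns the (y, slit_width) strip and the x coordinate of its leftmost
    column centre in frame coordinates (the strip is centred on the slit's
    central column).
    """
    n_ch = sl.data.shape[1]
    if not 0 <= wavelength_index < n_ch:
        raise IndexError(f"wavelength index {wavelength_index} out of range [0, {n_ch})")
    w = int(round(sl.slit_width_px))
    strip = np.repeat(sl.data[:, wavelength_index : wavelength_index + 1], w, axis=1)
    x_left = sl.slit_center_x - (w - 1) / 2.0
    return strip, x_left


def strips_extent(slices, chain) -> tuple[tuple[float, float], tuple[int, int]]:
    """Union bounding box of all warped strip footprints."""
    boxes = []
    for sl in slices:
        t = chain.transforms[sl.frame_index]
        if t is None:
            continue
        h = sl.data.shape[0]
        half = sl.slit_width_px / 2.0
        corners = np.array(
            [
                [sl.slit_center_x - half, -0.5],
                [sl.slit_center_x + half, -0.5],
                [sl.slit_center_x - half, h - 0.5],
                [sl.slit_center_x + half, h - 0.5],
            ]
        )
        w = t.apply(corners)
        boxes.append([w[:, 1].min(), w[:, 0].min(), w[:, 1].max(), w[:, 0].max()])
    if not boxes:
        raise ValueError("no slices with a registered transform")
    boxes = np.array(boxes)
    # canvas pixels are those whose centres fall inside the union bbox
    y0, x0 = np.ceil(boxes[:, 0].min()), np.ceil(boxes[:, 1].min())
    y1, x1 = np.floor(boxes[:, 2].max()), np.floor(boxes[:, 3].max())
    return (float(y0), float(x0)), (int(y1 - y0) + 1, int(x1 - x0) + 1)


def reconstruct_hypercube(
    slices: list,
    chain,
    canvas: tuple[tuple[float, float], tuple[int, int]] | None = None,
) -> Hypercube:
    """Place every slice's replicated strips on the canvas and average overlaps.

    All slices must share a wavelength axis and have a registered (or
    fallback) frame transform; slices of failed frames are skipped.  The
    accumulation is linear and order-independent (sums + counts).  The
    strip interior is sampled bilinearly along y; across the slit width the
    profile is constant by construction, and a canvas pixel contributes
    when its pre-image falls within the slit's half-open support.
    """
    used = [sl for sl in slices if chain.transforms[sl.frame_index] is not None]
    if not used:
        raise ValueError("no slices with a registered transform")
    wl = used[0].wavelengths
    for sl in used[1:]:
        if len(sl.wavelengths) != len(wl) or not np.allclose(sl.wavelengths, wl):
            raise ValueError("all slices must share a common wavelength axis")
    if canvas is None:
        canvas = strips_extent(used, chain)
    (oy, ox), (ch, cw) = canvas
    n_ch = len(wl)
    acc = np.zeros((ch, cw, n_ch), dtype=np.float64)
    cnt = np.zeros((ch, cw), dtype=np.int32)

    for sl in used:
        t = chain.transforms[sl.frame_index]
        h = sl.data.shape[0]
        half = sl.slit_width_px / 2.0
        cx = sl.slit_center_x
        corners = np.array(
            [[cx - half, -0.5], [cx + half, -0.5], [cx - half, h - 0.5], [cx + half, h - 0.5]]
        )
        wc = t.apply(corners)
        r0 = max(0, int(np.floor(wc[:, 1].min() - oy)))
        c0 = max(0, int(np.floor(wc[:, 0].min() - ox)))
        r1 = min(ch, int(np.ceil(wc[:, 1].max() - oy)) + 1)
        c1 = min(cw, int(np.ceil(wc[:, 0].max() - ox)) + 1)
        if r1 <= r0 or c1 <= c0:
            continue
        inv = t.inverse().matrix
        yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
        xx += ox
        yy += oy
        xf = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
        yf = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
        inside = (np.abs(xf - cx) <= half) & (yf >= -0.5) & (yf <= h - 0.5)
        if not inside.any():
            continue
        yv = np.clip(yf[inside], 0.0, h - 1.0)
        y0i = np.floor(yv).astype(int)
        y1i = np.minimum(y0i + 1, h - 1)
        fy = (yv - y0i)[:, None]
        vals = (1.0 - fy) * sl.data[y0i, :] + fy * sl.data[y1i, :]
        rr, cc = np.nonzero(inside)
        acc[r0 + rr, c0 + cc, :] += vals
        cnt[r0 + rr, c0 + cc] += 1

    with np.errstate(invalid="ignore"):
        data = np.where(cnt[:, :, None] > 0, acc / np.maximum(cnt, 1)[:, :, None], np.nan)
    return Hypercube(data.astype(np.float32), wl.copy(), cnt, (oy, ox))


def extract_spectrum(
    cube: Hypercube, region: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation spectrum over a pixel region.

    ``region`` is a boolean mask on the canvas (or an integer index pair
    array); only covered pixels contribute.  Raises when the region misses
    coverage entirely.
    """
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != cube.coverage.shape:
            raise ValueError("region mask must match the canvas shape")
        sel = region & (cube.coverage > 0)
    else:
        mask = np.zeros(cube.coverage.shape, dtype=bool)
        mask[tuple(region.T)] = True
        sel = mask & (cube.coverage > 0)
    if not sel.any():
        raise ValueError("region has no covered pixels")
    spectra = cube.data[sel]
    return spectra.mean(axis=0), spectra.std(axis=0)
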