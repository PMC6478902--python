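"""In-silico acquisition model for line-scan hyperspectral endoscopy.

The emulator reproduces, at the pixel level, how the instrument sees a
scene: a ground-truth reflectance cube (a procedurally rendered USAF-1951
style bar target whose elements each carry one of a small library of smooth
reflectance spectra) is viewed through a moving window.  Each view yields

* a wide-field frame: the spectrally integrated, similarity-warped crop,
  multiplied by the fibre bundle's circular field mask and honeycomb core
  lattice, with additive dark noise; and
* a spectral slice: the per-wavelength mean over the central columns of the
  warped crop, i.e. what a spectrograph with a finite entrance slit records.

The view of frame k advances a fixed number of pixels along x (the scan
axis) and draws its y-shift, rotation and magnification independently from
configurable ranges, emulating freehand endoscope motion.  Every stage of
the downstream pipeline can therefore be tested against known ground truth
without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import GeometricTransform
from .preprocess import WidefieldFrame
from .reconstruction import SpectralSlice


@dataclass
class GroundTruthCube:
    """Ground-truth reflectance scene (rows y, cols x, channels lambda).

    ``profile_map`` holds the per-pixel spectral profile label (-1 for
    background); every foreground pixel's spectrum is exactly
    ``profiles[profile_map]``, background pixels are all-zero.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    profile_map: np.ndarray
    profiles: np.ndarray  # (n_profiles, n_channels)
    _intensity: np.ndarray | None = field(default=None, repr=False)

    @property
    def shape(self):
        return self.data.shape

    @property
    def intensity(self) -> np.ndarray:
        """Spectrally integrated scene (cached); what a panchromatic camera sees."""
        if self._intensity is None:
            self._intensity = self.data.sum(axis=2, dtype=np.float64)
        return self._intensity


@dataclass
class DistortionParams:
    """Per-frame view distortion ranges for the emulated freehand scan.

    Defaults are the in-silico validation conditions: 8 px scan step,
    y-shift 2-7 px, rotation 0.54-0.71 deg, magnification -0.15 to +1.36
    percent, dark noise ~2 percent of maximum intensity.  Each frame draws
    its y-shift, rotation and magnification independently and uniformly
    from the closed ranges.
    """

    x_step: float = 8.0
    y_shift_range: tuple[float, float] = (2.0, 7.0)
    rotation_range: tuple[float, float] = (0.54, 0.71)
    magnification_range: tuple[float, float] = (-0.15, 1.36)  # percent
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("y_shift_range", "rotation_range", "magnification_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (min <= max), got {(lo, hi)}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


@dataclass
class ViewSpec:
    """One emulated camera view of the ground-truth scene."""

    transform: GeometricTransform = field(default_factory=GeometricTransform.identity)
    crop_size: int = 512
    mask_radius: float = 250.0
    honeycomb_pitch: float = 6.0
    honeycomb_depth: float = 0.5

    def __post_init__(self) -> None:
        if self.crop_size <= 0:
            raise ValueError("crop_size must be positive")
        if self.mask_radius > self.crop_size / 2:
            raise ValueError("mask radius must not exceed half the crop size")
        if self.honeycomb_pitch <= 0:
            raise ValueError("honeycomb pitch must be positive")


# ---------------------------------------------------------------------------
# ground-truth target


def spectral_profile_library(
    n_profiles: int, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random reflectance profiles: 2-3 Gaussians each, clipped to [0, 1]."""
    c = np.arange(n_channels)
    profiles = np.zeros((n_profiles, n_channels))
    for i in range(n_profiles):
        n_gauss = rng.integers(2, 4)
        p = np.zeros(n_channels)
        for _ in range(n_gauss):
            centre = rng.uniform(0.05, 0.95) * (n_channels - 1)
            width = rng.uniform(0.05, 0.25) * n_channels
            amp = rng.uniform(0.3, 1.0)
            p += amp * np.exp(-0.5 * ((c - centre) / width) ** 2)
        p *= 0.95 / p.max()
        profiles[i] = np.clip(p, 0.0, 1.0)
    return profiles


def _render_bar_layout(
    width: int, height: int, rng: np.random.Generator,
    bar_widths=(10, 13, 16, 20, 25, 31),
    pad: int = 6,
) -> tuple[np.ndarray, int]:
    """Procedural USAF-1951 style layout: rows of graded three-bar elements.

    Returns an element-label map (-1 background, elements numbered from 0)
    and the element count.  Each row carries one bar width from the graded
    series (cycling row to row, as in the graded groups of a resolution
    chart); elements alternate horizontal/vertical orientation and receive
    a small position jitter.  A three-bar element spans 5w x 5w pixels for
    bar width w, so foreground covers roughly half the scene.
    """
    labels = np.full((height, width), -1, dtype=np.int32)
    element = 0
    y = pad
    row = 0
    while True:
        w = int(bar_widths[row % len(bar_widths)])
        size = 5 * w
        if y + size + pad > height:
            break
        x = pad
        while x + size + pad <= width:
            jy = int(rng.integers(0, pad + 1)) - pad // 2
            jx = int(rng.integers(0, pad + 1)) - pad // 2
            y0 = int(np.clip(y + jy, 0, height - size))
            x0 = int(np.clip(x + jx, 0, width - size))
            horizontal = (element % 2) == 0
            for k in range(3):
                if horizontal:
                    labels[y0 + 2 * k * w : y0 + (2 * k + 1) * w, x0 : x0 + size] = element
                else:
                    labels[y0 : y0 + size, x0 + 2 * k * w : x0 + (2 * k + 1) * w] = element
            element += 1
            x += size + pad
        y += size + pad
        row += 1
    return labels, element


def make_insilico_target(
    width: int = 1120,
    height: int = 560,
    n_profiles: int = 6,
    n_channels: int = 100,
    seed: int = 0,
) -> GroundTruthCube:
    """Render the in-silico resolution target with per-element spectra.

    Every three-bar element is randomly assigned one of ``n_profiles``
    smooth reflectance spectra sampled over ``n_channels`` channels; the
    default scene is sized so that a default scan (512 px crops stepping
    8 px between small margins) holds exactly 74 frames.  Deterministic for
    a given seed.
    """
    if width <= 0 or height <= 0:
        raise ValueError("target dimensions must be positive")
    if n_profiles < 1 or n_channels < 1:
        raise ValueError("n_profiles and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = spectral_profile_library(n_profiles, n_channels, rng)
    elements, n_elements = _render_bar_layout(width, height, rng)
    if n_elements == 0:
        raise ValueError("target too small to hold any chart element")
    # assign profiles so that every profile occurs when possible
    assign = np.concatenate(
        [np.arange(n_profiles)] * (n_elements // n_profiles + 1)
    )[:n_elements]
    rng.shuffle(assign)
    profile_map = np.where(elements >= 0, assign[np.maximum(elements, 0)], -1).astype(
        np.int32
    )
    data = np.zeros((height, width, n_channels), dtype=np.float32)
    fg = profile_map >= 0
    data[fg] = profiles[profile_map[fg]].astype(np.float32)
    wavelengths = np.arange(n_channels, dtype=float)
    return GroundTruthCube(data, wavelengths, profile_map, profiles)


# ---------------------------------------------------------------------------
# distortions and views


def sample_distortions(
    params: DistortionParams,
    n_frames: int,
    origin: tuple[float, float] = (0.0, 0.0),
    crop_size: int = 512,
) -> list[GeometricTransform]:
    """Draw the frame-to-scene transform of every frame in a scan.

    Frame k translates by ``k * x_step`` along x (plus the scan origin) and
    receives independent uniform draws of y-shift, rotation and
    magnification; rotation and magnification act about the frame centre.
    Reproducible for a given ``params.seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    centre = ((crop_size - 1) / 2.0, (crop_size - 1) / 2.0)
    out = []
    for k in range(n_frames):
        dy = rng.uniform(*params.y_shift_range)
        rot = rng.uniform(*params.rotation_range)
        mag = rng.uniform(*params.magnification_range)
        out.append(
            GeometricTransform.from_params(
                translation=(origin[1] + k * params.x_step, origin[0] + dy),
                rotation_deg=rot,
                scale=1.0 + mag / 100.0,
                center=centre,
            )
        )
    return out


def honeycomb_texture(
    shape: tuple[int, int], pitch: float = 6.0, depth: float = 0.5
) -> np.ndarray:
    """Multiplicative fibre-core lattice: a hexagonal three-cosine pattern.

    Three plane waves at 60 degree spacing with period ``pitch`` pixels;
    values span [1 - depth, 1] with bright cores at lattice sites.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    k = 2 * np.pi / pitch
    s = np.zeros((h, w))
    for ang in (0.0, np.pi / 3, 2 * np.pi / 3):
        s += np.cos(k * (np.cos(ang) * xx + np.sin(ang) * yy))
    s /= 3.0  # in [-0.5, 1]
    return 1.0 - depth * (1.0 - s) / 1.5


def _check_view_inside(cube: GroundTruthCube, view: ViewSpec) -> None:
    h, w, _ = cube.shape
    n = view.crop_size
    corners = np.array(
        [[-0.5, -0.5], [n - 0.5, -0.5], [-0.5, n - 0.5], [n - 0.5, n - 0.5]]
    )
    warped = view.transform.apply(corners)
    if (
        warped[:, 0].min() < -0.5
        or warped[:, 1].min() < -0.5
        or warped[:, 0].max() > w - 0.5
        or warped[:, 1].max() > h - 0.5
    ):
        raise ValueError("view window falls outside the ground-truth scene")


def _view_coords(view: ViewSpec, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scene sampling coordinates (ys, xs) for given frame columns."""
    rows = np.arange(view.crop_size, dtype=float)
    xx, yy = np.meshgrid(cols, rows)
    pts = view.transform.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    return pts[:, 1].reshape(xx.shape), pts[:, 0].reshape(xx.shape)


def emulate_widefield_frame(
    cube: GroundTruthCube,
    view: ViewSpec,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
    index: int = 0,
) -> WidefieldFrame:
    """Emulate the wide-field camera: warped spectral sum x mask x honeycomb + noise.

    Noise is additive uniform in ``[0, noise_level * max_intensity]`` (dark
    noise), added across the whole sensor including outside the field mask.
    """
    _check_view_inside(cube, view)
    n = view.crop_size
    ys, xs = _view_coords(view, np.arange(n, dtype=float))
    img = ndimage.map_coordinates(cube.intensity, [ys, xs], order=1, cval=0.0)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    mask = np.hypot(xx - c, yy - c) <= view.mask_radius
    img *= mask
    if view.honeycomb_depth > 0:
        img *= honeycomb_texture((n, n), view.honeycomb_pitch, view.honeycomb_depth)
    if noise_level > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = img + rng.uniform(0.0, noise_level * img.max(), size=img.shape)
    return WidefieldFrame(data=img, index=index, valid_mask=mask)


def emulate_spectral_slice(
    cube: GroundTruthCube,
    view: ViewSpec,
    slit_width: int = 10,
    index: int = 0,
) -> SpectralSlice:
    """Emulate the spectrograph: per-wavelength mean over the central slit columns.

    The slit is centred on the frame's central column (the optical axis);
    the returned (y, lambda) slice is the mean over ``slit_width`` columns
    of the similarity-warped crop at every wavelength.
    """
    if slit_width < 1:
        raise ValueError("slit_width must be >= 1")
    if slit_width > view.crop_size:
        raise ValueError("slit_width cannot exceed the crop width")
    _check_view_inside(cube, view)
    n = view.crop_size
    c = (n - 1) / 2.0
    cols = c + (np.arange(slit_width) - (slit_width - 1) / 2.0)
    ys, xs = _view_coords(view, cols)
    n_ch = cube.data.shape[2]
    out = np.empty((n, n_ch), dtype=float)
    for ch in range(n_ch):
        vals = ndimage.map_coordinates(
            cube.data[:, :, ch].astype(float), [ys, xs], order=1, cval=0.0
        )
        out[:, ch] = vals.mean(axis=1)
    return SpectralSlice(
        data=out,
        wavelengths=cube.wavelengths,
        frame_index=index,
        slit_width_px=float(slit_width),
        slit_center_x=c,
        frame_height=n,
    )


# ---------------------------------------------------------------------------
# full acquisition sequences


@dataclass
class Acquisition:
    """A full emulated scan: frames, slices and their ground-truth transforms."""

    frames: list
    slices: list
    true_transforms: list  # frame -> scene, one per frame
    params: DistortionParams
    crop_size: int

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def true_globals(self, reference: int = 0) -> list:
        """Ground-truth frame-to-reference-frame transforms."""
        inv_ref = self.true_transforms[reference].inverse()
        return [inv_ref @ t for t in self.true_transforms]


def emulate_sequence(
    cube: GroundTruthCube,
    params: DistortionParams | None = None,
    n_frames: int | None = None,
    crop_size: int = 512,
    mask_radius: float = 250.0,
    honeycomb_pitch: float = 6.0,
    honeycomb_depth: float = 0.5,
    slit_width: int = 10,
    origin: tuple[float, float] | None = None,
) -> Acquisition:
    """Emulate a complete scan across the target.

    ``n_frames`` defaults to the number of x-steps that keep the crop inside
    the scene; ``origin`` (row, col) defaults to a small symmetric margin.
    All randomness (distortion draws and dark noise) derives from
    ``params.seed``.
    """
    if params is None:
        params = DistortionParams()
    h, w, _ = cube.shape
    if origin is None:
        oy = (h - crop_size - max(0.0, params.y_shift_range[1])) / 2.0
        origin = (max(2.0, oy), 12.0)
    if n_frames is None:
        n_frames = int((w - crop_size - 2 * origin[1]) // params.x_step) + 1
    transforms = sample_distortions(params, n_frames, origin=origin, crop_size=crop_size)
    rng = np.random.default_rng(params.seed + 1)
    frames, slices = [], []
    for k, t in enumerate(transforms):
        view = ViewSpec(
            transform=t,
            crop_size=crop_size,
            mask_radius=mask_radius,
            honeycomb_pitch=honeycomb_pitch,
            honeycomb_depth=honeycomb_depth,
        )
        frames.append(
            emulate_widefield_frame(
                cube, view, noise_level=params.noise_level, rng=rng, index=k
            )
        )
        slices.append(emulate_spectral_slice(cube, view, slit_width=slit_width, index=k))
    return Acquisition(frames, slices, transforms, params, crop_size)
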