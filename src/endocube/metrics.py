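"""Quantitative performance evaluation of the imaging pipeline.

Michelson contrast of bar-target modulations (via a sinusoid fit), spatial
resolution from the contrast-versus-frequency regression with a 1% contrast
cut-off, spectral resolution as the Gaussian FWHM of an emission peak, and
reconstruction-fidelity scoring of a hypercube against the simulation's
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .geometry import GeometricTransform
from .reconstruction import Hypercube
from .simulation import GroundTruthCube
from .spectral_analysis import spectral_angle


class PeakNotFoundError(ValueError):
    """The spectrum holds no peak clearly above background."""


class ResolutionFitError(ValueError):
    """The contrast-frequency regression cannot yield a cut-off crossing."""


@dataclass
class ContrastMeasurement:
    """Michelson contrast of one chart element at a known spatial frequency."""

    frequency: float  # line pairs per unit length (e.g. lp/px)
    contrast: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


@dataclass
class FidelityReport:
    """Agreement between a reconstructed cube and the ground-truth scene."""

    channel_pearson: np.ndarray  # per-channel correlation on covered pixels
    channel_rmse: np.ndarray
    mean_spectral_angle: float  # mean per-pixel angle, radians
    coverage_fraction: float

    @property
    def mean_pearson(self) -> float:
        return float(np.nanmean(self.channel_pearson))


def fit_sinusoid(profile: np.ndarray, period: float | None = None):
    """Least-squares sinusoid fit; returns (amplitude, offset, period).

    With ``period`` given (the known element spacing), only amplitude,
    offset and phase are free and the fit is a linear regression on a
    sin/cos basis.  Otherwise the dominant non-DC Fourier component sets
    the period first.
    """
    y = np.asarray(profile, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("profile too short for a sinusoid fit")
    if period is None:
        spec = np.abs(np.fft.rfft(y - y.mean()))
        if spec[1:].max() <= 0:
            return 0.0, float(y.mean()), float(n)
        k = int(np.argmax(spec[1:]) + 1)
        period = n / k
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.arange(n)
    w = 2 * np.pi / period
    basis = np.column_stack([np.ones(n), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    amp = float(np.hypot(coef[1], coef[2]))
    return amp, float(coef[0]), float(period)


def michelson_contrast(profile: np.ndarray, period: float | None = None) -> float:
    """Michelson contrast ``(I_max - I_min) / (I_max + I_min)`` of a modulation.

    The intensity extremes come from a fitted sinusoid (amplitude/offset),
    making the estimate robust to pixel noise.  Raises when the modulation
    mean is not positive.
    """
    amp, offset, _ = fit_sinusoid(profile, period)
    amp = min(amp, offset)  # physical intensities are non-negative
    i_max, i_min = offset + amp, offset - amp
    if i_max + i_min <= 0:
        raise ValueError("contrast undefined for non-positive mean intensity")
    return float((i_max - i_min) / (i_max + i_min))


def estimate_spatial_resolution(
    measurements: list, cutoff: float = 0.01
) -> float:
    """Spatial resolution from the contrast-frequency linear regression.

    Contrast is regressed linearly on spatial frequency; the resolution is
    the half-period ``1 / (2 f_c)`` at the frequency ``f_c`` where the
    fitted line falls to the contrast cut-off (default 0.01, i.e. 1%
    contrast).  Requires a negative slope (contrast decreasing with
    frequency).
    """
    if len(measurements) < 2:
        raise ValueError("at least two contrast measurements are required")
    f = np.array([m.frequency for m in measurements], dtype=float)
    c = np.array([m.contrast for m in measurements], dtype=float)
    if len(np.unique(f)) < 2:
        raise ValueError("measurements must span at least two distinct frequencies")
    slope, intercept = np.polyfit(f, c, 1)
    if slope >= -1e-9 * max(1.0, c.max()):
        raise ResolutionFitError("contrast does not decrease with frequency")
    f_c = (cutoff - intercept) / slope
    if f_c <= 0:
        raise ResolutionFitError("fitted line never crosses the contrast cut-off")
    return float(1.0 / (2.0 * f_c))


def spectral_fwhm(
    spectrum: np.ndarray, wavelengths: np.ndarray, noise_sigma_factor: float = 3.0
) -> float:
    """Full width at half maximum of the dominant spectral peak.

    A Gaussian with constant background is fitted around the highest
    sample; the FWHM is ``2 sqrt(2 ln 2) sigma`` in wavelength units.  The
    background is the median outside the peak's +-3 sigma window, and a
    peak is required to rise above background by at least
    ``noise_sigma_factor`` times the off-peak noise SD.
    """
    y = np.asarray(spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if y.shape != wl.shape or y.ndim != 1 or len(y) < 5:
        raise ValueError("spectrum and wavelengths must be matching 1D arrays (n >= 5)")
    i0 = int(np.argmax(y))
    # initial width guess from half-maximum crossings
    half = (y[i0] + np.median(y)) / 2.0
    above = y >= half
    left = i0
    while left > 0 and above[left - 1]:
        left -= 1
    right = i0
    while right < len(y) - 1 and above[right + 1]:
        right += 1
    sigma0 = max((wl[right] - wl[left]) / 2.355, (wl[1] - wl[0]) / 2.0)

    def model(x, amp, mu, sig, bg):
        return bg + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            model,
            wl,
            y,
            p0=[y[i0] - np.median(y), wl[i0], sigma0, np.median(y)],
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise PeakNotFoundError("Gaussian peak fit did not converge") from exc
    amp, mu, sig, bg = popt
    sig = abs(sig)
    outside = np.abs(wl - mu) > 3 * sig
    if outside.sum() >= 4:
        bg_ref = np.median(y[outside])
        noise = y[outside].std()
    else:
        bg_ref, noise = bg, 0.0
    floor = 1e-6 * max(np.abs(y).max(), 1e-30)
    if amp <= floor or y[i0] < bg_ref + noise_sigma_factor * noise:
        raise PeakNotFoundError("no spectral peak above background")
    return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * sig)


def warp_truth_to_canvas(
    truth: GroundTruthCube,
    recon: Hypercube,
    frame_to_scene: GeometricTransform | None = None,
) -> np.ndarray:
    """Sample the ground-truth cube on the reconstruction canvas.

    ``frame_to_scene`` maps the reference frame's coordinates into the
    ground-truth scene (identity when the canvas already lives in scene
    coordinates); the canvas offset of ``recon`` is applied on top.
    """
    if frame_to_scene is None:
        frame_to_scene = GeometricTransform.identity()
    h, w, n_ch = recon.data.shape
    oy, ox = recon.offset
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = frame_to_scene.apply(
        np.column_stack([(xx + ox).ravel(), (yy + oy).ravel()])
    )
    ys, xs = pts[:, 1].reshape(h, w), pts[:, 0].reshape(h, w)
    out = np.empty((h, w, n_ch), dtype=np.float32)
    for ch in range(n_ch):
        out[:, :, ch] = ndimage.map_coordinates(
            truth.data[:, :, ch].astype(float), [ys, xs], order=1, cval=np.nan
        )
    return out


def cube_fidelity(
    recon: Hypercube,
    truth: GroundTruthCube,
    frame_to_scene: GeometricTransform | None = None,
) -> FidelityReport:
    """Score a reconstruction against the ground-truth scene.

    Per-channel Pearson correlation and RMSE plus the mean per-pixel
    spectral angle, all restricted to covered canvas pixels that fall
    inside the scene.
    """
    ref = warp_truth_to_canvas(truth, recon, frame_to_scene)
    covered = (recon.coverage > 0) & np.isfinite(ref).all(axis=-1)
    covered &= np.isfinite(recon.data).all(axis=-1)
    if not covered.any():
        raise ValueError("no covered overlap between reconstruction and truth")
    a = recon.data[covered]
    b = ref[covered]
    n_ch = a.shape[1]
    pear = np.empty(n_ch)
    rmse = np.empty(n_ch)
    for ch in range(n_ch):
        x, y = a[:, ch], b[:, ch]
        sx, sy = x.std(), y.std()
        pear[ch] = (
            np.nan if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1])
        )
        rmse[ch] = float(np.sqrt(np.mean((x - y) ** 2)))
    norms_a = np.linalg.norm(a, axis=1)
    norms_b = np.linalg.norm(b, axis=1)
    nz = (norms_a > 0) & (norms_b > 0)
    cos = np.einsum("ij,ij->i", a[nz], b[nz]) / (norms_a[nz] * norms_b[nz])
    mean_angle = float(np.mean(np.arccos(np.clip(cos, -1.0, 1.0)))) if nz.any() else 0.0
    return FidelityReport(
        pear, rmse, mean_angle, float(covered.mean())
    )


def profile_recovery_angles(
    recon: Hypercube,
    truth: GroundTruthCube,
    frame_to_scene: GeometricTransform | None = None,
) -> dict:
    """Spectral angle between each profile's mean reconstructed spectrum and truth.

    The ground-truth profile label map is resampled (nearest neighbour) to
    the canvas; for every profile the mean reconstructed spectrum over its
    covered pixels is compared with the assigned library profile.
    """
    if frame_to_scene is None:
        frame_to_scene = GeometricTransform.identity()
    h, w, _ = recon.data.shape
    oy, ox = recon.offset
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = frame_to_scene.apply(np.column_stack([(xx + ox).ravel(), (yy + oy).ravel()]))
    ys, xs = pts[:, 1].reshape(h, w), pts[:, 0].reshape(h, w)
    labels = ndimage.map_coordinates(
        truth.profile_map.astype(float), [ys, xs], order=0, cval=-1.0
    ).astype(int)
    covered = (recon.coverage > 0) & np.isfinite(recon.data).all(axis=-1)
    out = {}
    for lab in range(truth.profiles.shape[0]):
        sel = (labels == lab) & covered
        if not sel.any():
            continue
        mean_spec = recon.data[sel].mean(axis=0)
        out[lab] = spectral_angle(mean_spec, truth.profiles[lab])
    return out
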