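"""Physiological and classification endpoints derived from the hypercube.

* absorbance via the Beer-Lambert law, ``A = -log10(I / I0)``;
* synthetic RGB rendering through Rayleigh-shaped colour filters
  (centre wavelengths 442, 518 and 579 nm);
* non-negative least-squares (NNLS) linear unmixing against endmember
  spectra, giving oxygen saturation ``sO2 = alpha / (alpha + beta)`` for an
  oxy/deoxy-haemoglobin pair;
* the spectral angle mapper (SAM), a scale-invariant spectral similarity,
  with per-region statistics and a one-way ANOVA + Tukey HSD group test;
* unsupervised tissue segmentation by spatial binning, PCA and k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .reconstruction import Hypercube

OXY = "oxy"
DEOXY = "deoxy"


@dataclass
class AbsorbanceCube:
    """Dimensionless absorbance cube; NaN where reflectance was invalid."""

    data: np.ndarray  # (y, x, lambda)
    wavelengths: np.ndarray
    valid: np.ndarray  # (y, x) bool: finite full spectrum

    @property
    def shape(self):
        return self.data.shape


@dataclass
class EndmemberLibrary:
    """Named reference spectra on a common wavelength grid."""

    names: list
    spectra: np.ndarray  # (k, n_wavelengths)
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.names) != self.spectra.shape[0]:
            raise ValueError("one name per endmember spectrum required")
        if self.spectra.shape[1] != len(self.wavelengths):
            raise ValueError("endmember spectra must match the wavelength grid")
        if np.any(np.all(self.spectra == 0, axis=1)):
            raise ValueError("endmember spectra must not be all-zero")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.spectra[self.names.index(name)]

    @classmethod
    def from_csv(cls, path) -> "EndmemberLibrary":
        """Read a CSV whose first column is wavelength, remaining columns endmembers."""
        df = pd.read_csv(path)
        return cls(list(df.columns[1:]), df.iloc[:, 1:].to_numpy().T, df.iloc[:, 0].to_numpy())

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"wavelength": self.wavelengths})
        for name, s in zip(self.names, self.spectra):
            df[name] = s
        df.to_csv(path, index=False)


@dataclass
class RGBFilterBank:
    """Three Rayleigh-shaped spectral response curves for RGB synthesis."""

    responses: np.ndarray  # (3, n_wavelengths), unit integral each
    centers: tuple[float, float, float]
    wavelengths: np.ndarray

    @classmethod
    def rayleigh(
        cls,
        wavelengths: np.ndarray,
        centers: tuple[float, float, float] = (442.0, 518.0, 579.0),
        scale: float = 45.0,
    ) -> "RGBFilterBank":
        """Rayleigh-pdf filters with the mode at each centre wavelength.

        ``centers`` lists the blue, green and red centre wavelengths in
        ascending order (blue is the shortest).  The Rayleigh density peaks
        at its scale parameter, so each filter is shifted to put the mode at
        the requested centre.  Responses are normalised to unit integral on
        the given grid (a spectrally flat cube renders as grey) and returned
        as (R, G, B) rows.
        """
        wl = np.asarray(wavelengths, dtype=float)
        lo, hi = wl.min(), wl.max()
        resp = []
        for c in centers:
            if not lo <= c <= hi:
                raise ValueError(f"filter centre {c} outside the wavelength range")
            r = stats.rayleigh.pdf(wl, loc=c - scale, scale=scale)
            area = np.trapezoid(r, wl)
            if area <= 0:
                raise ValueError("degenerate filter response on this grid")
            resp.append(r / area)
        return cls(np.array(resp[::-1]), tuple(centers), wl)


@dataclass
class UnmixResult:
    """Per-pixel non-negative endmember coefficients and derived maps."""

    coefficients: np.ndarray  # (y, x, k), NaN where undefined
    residual: np.ndarray  # (y, x) L2 norm of the fit error
    names: list
    so2: np.ndarray | None = None  # alpha/(alpha+beta); NaN where undefined


@dataclass
class SamRegionStats:
    """Per-region spectral-angle statistics with the ANOVA group comparison."""

    per_region: pd.DataFrame  # region, n, mean, sd
    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame | None  # pairwise Tukey HSD p-values
    angle_map: np.ndarray


def synthetic_hemoglobin_library(
    wavelengths: np.ndarray | None = None,
) -> EndmemberLibrary:
    """Synthetic oxy/deoxy absorbance endmembers for tests and simulations.

    Smooth Gaussian-mixture stand-ins that echo the qualitative features of
    haemoglobin absorbance in the visible range (the oxygenated form's
    double peak near 542/577 nm and low red absorbance; the deoxygenated
    form's single broad peak near 556 nm with elevated red absorbance).
    They are not measured spectra and carry no quantitative meaning beyond
    being two distinct, realistic endmembers.
    """
    wl = (
        np.linspace(450, 700, 100)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    oxy = (
        0.60 * np.exp(-0.5 * ((wl - 542) / 12.0) ** 2)
        + 0.55 * np.exp(-0.5 * ((wl - 577) / 10.0) ** 2)
        + 0.35 * np.exp(-0.5 * ((wl - 415) / 25.0) ** 2)
        + 0.03
    )
    deoxy = (
        0.80 * np.exp(-0.5 * ((wl - 556) / 22.0) ** 2)
        + 0.30 * np.exp(-0.5 * ((wl - 430) / 25.0) ** 2)
        + 0.18 * np.exp(-0.5 * ((wl - 650) / 40.0) ** 2)
        + 0.03
    )
    return EndmemberLibrary([OXY, DEOXY], np.vstack([oxy, deoxy]), wl)


# ---------------------------------------------------------------------------
# absorbance


def absorbance(
    sample: Hypercube | np.ndarray,
    background: Hypercube | np.ndarray,
    eps: float = 1e-6,
) -> AbsorbanceCube:
    """Beer-Lambert absorbance ``A(x, y, lambda) = -log10(I / I0)``.

    ``background`` may be a matching hypercube or a single reference
    spectrum applied to every pixel.  Reflectance at or below zero carries
    no absorbance information: it is clipped at ``eps`` and the affected
    pixels flagged invalid.
    """
    data = sample.data if isinstance(sample, Hypercube) else np.asarray(sample, float)
    wl = (
        sample.wavelengths
        if isinstance(sample, Hypercube)
        else np.arange(data.shape[-1], dtype=float)
    )
    if isinstance(background, Hypercube):
        bg = background.data
        if len(background.wavelengths) != len(wl) or not np.allclose(
            background.wavelengths, wl
        ):
            raise ValueError("sample and background wavelength grids differ")
    else:
        bg = np.asarray(background, dtype=float)
        if bg.ndim == 1:
            if len(bg) != data.shape[-1]:
                raise ValueError("background spectrum length must match the cube")
            bg = np.broadcast_to(bg, data.shape)
    good = np.isfinite(data) & np.isfinite(bg) & (data > 0) & (bg > 0)
    a = -np.log10(np.clip(data, eps, None) / np.clip(bg, eps, None))
    a = np.where(good, a, np.nan)
    return AbsorbanceCube(a, np.asarray(wl, float), np.all(np.isfinite(a), axis=-1))


# ---------------------------------------------------------------------------
# synthetic RGB


def synthesize_rgb(
    cube: Hypercube | AbsorbanceCube | np.ndarray,
    filters: RGBFilterBank | None = None,
    percentile: float = 99.0,
) -> np.ndarray:
    """Render the cube as an RGB image through the colour filter bank.

    Each channel is the per-pixel inner product of the spectrum with the
    filter response; the image is globally scaled so the ``percentile``-th
    percentile maps to 1.0 (then clipped), avoiding saturation.
    """
    data = cube.data if hasattr(cube, "data") else np.asarray(cube, float)
    wl = cube.wavelengths if hasattr(cube, "wavelengths") else np.arange(data.shape[-1])
    if filters is None:
        filters = RGBFilterBank.rayleigh(wl)
    if filters.responses.shape[1] != data.shape[-1]:
        raise ValueError("filter bank not sampled on the cube's wavelength grid")
    dw = np.gradient(np.asarray(wl, float))
    rgb = np.einsum("yxl,cl->yxc", np.nan_to_num(data), filters.responses * dw)
    top = np.nanpercentile(rgb, percentile)
    if top > 0:
        rgb = rgb / top
    return np.clip(rgb, 0.0, 1.0)


# ---------------------------------------------------------------------------
# NNLS unmixing


def _nnls_two(spectra: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Exact vectorised NNLS for exactly two endmembers.

    The KKT conditions for a 2-variable non-negative least squares admit a
    closed form: take the unconstrained solution if it is feasible,
    otherwise the best single-endmember fit with the other coefficient
    clamped at zero.
    """
    g = e @ e.T  # (2,2) Gram
    b = spectra @ e.T  # (n,2)
    det = g[0, 0] * g[1, 1] - g[0, 1] ** 2
    if det > 1e-12 * g[0, 0] * g[1, 1]:
        a0 = (g[1, 1] * b[:, 0] - g[0, 1] * b[:, 1]) / det
        a1 = (g[0, 0] * b[:, 1] - g[0, 1] * b[:, 0]) / det
    else:  # collinear endmembers: fall back to single-endmember fits
        a0 = np.full(len(b), -1.0)
        a1 = np.full(len(b), -1.0)
    out = np.stack([a0, a1], axis=1)
    infeasible = (out < 0).any(axis=1)
    if infeasible.any():
        c0 = np.maximum(b[infeasible, 0] / g[0, 0], 0.0)
        c1 = np.maximum(b[infeasible, 1] / g[1, 1], 0.0)
        r0 = -2 * c0 * b[infeasible, 0] + c0**2 * g[0, 0]
        r1 = -2 * c1 * b[infeasible, 1] + c1**2 * g[1, 1]
        pick0 = r0 <= r1
        sub = np.zeros((infeasible.sum(), 2))
        sub[pick0, 0] = c0[pick0]
        sub[~pick0, 1] = c1[~pick0]
        out[infeasible] = sub
    return out


def nnls_unmix(a_cube: AbsorbanceCube, lib: EndmemberLibrary) -> UnmixResult:
    """Unmix every valid pixel spectrum as a non-negative endmember combination.

    Solves ``min ||S(x,y,:) - sum_k c_k E_k||`` with ``c_k >= 0`` per pixel.
    When the library holds endmembers named ``oxy`` and ``deoxy``, the
    oxygen saturation map ``sO2 = alpha / (alpha + beta)`` is attached,
    NaN where ``alpha + beta == 0`` (never silently zero).
    """
    if len(lib.wavelengths) != len(a_cube.wavelengths) or not np.allclose(
        lib.wavelengths, a_cube.wavelengths
    ):
        raise ValueError("endmember library not on the cube's wavelength grid")
    e = lib.spectra
    h, w, n_ch = a_cube.data.shape
    flat = a_cube.data.reshape(-1, n_ch)
    valid = a_cube.valid.reshape(-1)
    coeffs = np.full((h * w, e.shape[0]), np.nan)
    if e.shape[0] == 2:
        coeffs[valid] = _nnls_two(flat[valid], e)
    else:
        for i in np.flatnonzero(valid):
            coeffs[i], _ = optimize.nnls(e.T, flat[i])
    resid = np.full(h * w, np.nan)
    fit = coeffs[valid] @ e
    resid[valid] = np.linalg.norm(flat[valid] - fit, axis=1)
    coeffs = coeffs.reshape(h, w, -1)
    so2 = None
    if OXY in lib.names and DEOXY in lib.names:
        alpha = coeffs[:, :, lib.names.index(OXY)]
        beta = coeffs[:, :, lib.names.index(DEOXY)]
        total = alpha + beta
        with np.errstate(invalid="ignore", divide="ignore"):
            so2 = np.where(total > 0, alpha / total, np.nan)
    return UnmixResult(coeffs, resid.reshape(h, w), list(lib.names), so2)


# ---------------------------------------------------------------------------
# spectral angle mapper


def spectral_angle(target: np.ndarray, reference: np.ndarray) -> float:
    """Angle in radians between two spectra (scale-invariant similarity).

    ``arccos`` of the normalised inner product, in ``[0, pi]``; independent
    of positive scaling of either spectrum.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.shape != r.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("spectra must be 1D, equal length >= 2")
    nt, nr = np.linalg.norm(t), np.linalg.norm(r)
    if nt == 0 or nr == 0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    return float(np.arccos(np.clip(t @ r / (nt * nr), -1.0, 1.0)))


def sam_map(a_cube: AbsorbanceCube, reference: np.ndarray) -> np.ndarray:
    """Per-pixel spectral angle against a reference spectrum (NaN where invalid)."""
    ref = np.asarray(reference, dtype=float)
    if len(ref) != a_cube.data.shape[-1]:
        raise ValueError("reference length must match the spectral axis")
    nr = np.linalg.norm(ref)
    if nr == 0:
        raise ValueError("spectral angle undefined for a zero reference")
    flat = a_cube.data.reshape(-1, a_cube.data.shape[-1])
    norms = np.linalg.norm(flat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (flat @ ref) / (norms * nr)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[~a_cube.valid.reshape(-1) | (norms == 0)] = np.nan
    return ang.reshape(a_cube.data.shape[:2])


def sam_classify(
    a_cube: AbsorbanceCube,
    reference: np.ndarray,
    regions: np.ndarray,
    alpha: float = 0.05,
) -> SamRegionStats:
    """Per-region spectral-angle statistics with a group comparison.

    ``regions`` is an integer label map (< 0 = unlabelled).  Angles are
    aggregated per region (mean, SD, n); regions are compared with a
    one-way ANOVA and, when more than two regions are present, Tukey HSD
    pairwise post-hoc tests.
    """
    regions = np.asarray(regions)
    if regions.shape != a_cube.data.shape[:2]:
        raise ValueError("region label map must match the spatial shape")
    angles = sam_map(a_cube, reference)
    labels = np.unique(regions[regions >= 0])
    groups, rows = [], []
    for lab in labels:
        vals = angles[(regions == lab) & np.isfinite(angles)]
        if len(vals) == 0:
            raise ValueError(f"region {lab} has no valid pixels")
        groups.append(vals)
        rows.append(
            {"region": int(lab), "n": len(vals), "mean": vals.mean(), "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0}
        )
    if len(groups) < 2:
        raise ValueError("at least two labelled regions are required")
    f, p = stats.f_oneway(*groups)
    posthoc = None
    if len(groups) >= 2:
        hsd = stats.tukey_hsd(*groups)
        pairs = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pairs.append(
                    {
                        "region_a": int(labels[i]),
                        "region_b": int(labels[j]),
                        "p_value": float(hsd.pvalue[i, j]),
                        "significant": bool(hsd.pvalue[i, j] < alpha),
                    }
                )
        posthoc = pd.DataFrame(pairs)
    return SamRegionStats(pd.DataFrame(rows), float(f), float(p), posthoc, angles)


# ---------------------------------------------------------------------------
# PCA + k-means segmentation


def _bin_spectra(a_cube: AbsorbanceCube, bin_px: int):
    """Mean-pool the cube in bin_px x bin_px spatial blocks (NaN-aware)."""
    h, w, n_ch = a_cube.data.shape
    nh, nw = h // bin_px, w // bin_px
    if nh == 0 or nw == 0:
        raise ValueError("bin size exceeds the cube extent")
    trimmed = a_cube.data[: nh * bin_px, : nw * bin_px]
    blocks = trimmed.reshape(nh, bin_px, nw, bin_px, n_ch)
    with np.errstate(invalid="ignore"):
        binned = np.nanmean(blocks, axis=(1, 3))
    ok = np.isfinite(binned).all(axis=-1)
    return binned, ok, (nh, nw)


def pca_kmeans_classify(
    a_cube: AbsorbanceCube,
    k: int = 2,
    variance_target: float = 0.999,
    bin_px: int = 5,
    seed: int = 0,
):
    """Unsupervised tissue segmentation: bin -> PCA -> k-means.

    Spectra are mean-pooled in ``bin_px`` square blocks, decomposed by PCA
    (SVD) keeping the smallest number of components whose cumulative
    explained variance reaches ``variance_target``, and clustered with
    k-means (k-means++ init, 10 restarts, fixed seed).  Returns the
    full-resolution label map (-1 where uncovered), the per-cluster mean
    absorbance spectra and the number of retained components.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    binned, ok, (nh, nw) = _bin_spectra(a_cube, bin_px)
    x = binned[ok]
    if len(x) < k:
        raise ValueError(f"k={k} exceeds the {len(x)} covered bins")
    pca = PCA(n_components=min(x.shape[0], x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(m, scores.shape[1])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    lab = km.fit_predict(scores[:, :m])
    bin_labels = np.full((nh, nw), -1, dtype=np.int32)
    bin_labels[ok] = lab
    full = np.full(a_cube.data.shape[:2], -1, dtype=np.int32)
    up = np.repeat(np.repeat(bin_labels, bin_px, axis=0), bin_px, axis=1)
    full[: nh * bin_px, : nw * bin_px] = up
    means = np.vstack([x[lab == i].mean(axis=0) for i in range(k)])
    return full, means, m
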