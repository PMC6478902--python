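"""Absorbance, RGB synthesis, NNLS unmixing, SAM and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endocube.reconstruction import Hypercube
from endocube.spectral_analysis import (
    AbsorbanceCube,
    EndmemberLibrary,
    RGBFilterBank,
    absorbance,
    nnls_unmix,
    pca_kmeans_classify,
    sam_classify,
    sam_map,
    spectral_angle,
    synthesize_rgb,
)


def _cube(data, wl=None):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[-1], dtype=float) if wl is None else wl
    return Hypercube(data, wl, np.ones(data.shape[:2], np.int32), (0, 0))


def _acube(data, wl=None):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[-1], dtype=float) if wl is None else wl
    return AbsorbanceCube(data, wl, np.isfinite(data).all(axis=-1))


@pytest.fixture()
def hemoglobin_like():
    """Two distinct smooth endmembers standing in for oxy/deoxy absorbance."""
    wl = np.linspace(500, 700, 60)
    oxy = 0.6 * np.exp(-0.5 * ((wl - 542) / 12) ** 2) + 0.55 * np.exp(
        -0.5 * ((wl - 577) / 10) ** 2
    ) + 0.05
    deoxy = 0.8 * np.exp(-0.5 * ((wl - 556) / 22) ** 2) + 0.15 * np.exp(
        -0.5 * ((wl - 650) / 30) ** 2
    ) + 0.05
    return EndmemberLibrary(["oxy", "deoxy"], np.vstack([oxy, deoxy]), wl)


class TestAbsorbance:
    @pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_decade_attenuation(self, factor, expected):
        i0 = np.full((4, 5, 6), 0.8)
        out = absorbance(_cube(factor * i0), _cube(i0))
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_background_spectrum_broadcast(self):
        spec = np.linspace(0.5, 1.0, 6)
        data = 0.1 * np.broadcast_to(spec, (3, 3, 6))
        out = absorbance(_cube(data), spec)
        assert np.allclose(out.data, 1.0, atol=1e-10)

    def test_nonpositive_reflectance_flagged_invalid(self):
        data = np.full((2, 2, 4), 0.5)
        data[0, 0, 2] = 0.0
        out = absorbance(_cube(data), _cube(np.ones((2, 2, 4))))
        assert np.isnan(out.data[0, 0, 2])
        assert not out.valid[0, 0]
        assert out.valid[1, 1]

    def test_grid_mismatch_rejected(self):
        a = _cube(np.ones((2, 2, 5)))
        b = Hypercube(np.ones((2, 2, 5)), np.arange(5) + 100.0, np.ones((2, 2), np.int32))
        with pytest.raises(ValueError):
            absorbance(a, b)


class TestSynthesizeRGB:
    def test_flat_spectrum_renders_grey(self):
        wl = np.linspace(400, 720, 90)
        cube = _cube(np.full((8, 8, 90), 0.7), wl)
        rgb = synthesize_rgb(cube, RGBFilterBank.rayleigh(wl))
        r, g, b = rgb[4, 4]
        assert abs(r - g) < 0.01 and abs(g - b) < 0.01

    def test_energy_at_442_renders_blue_dominant(self):
        wl = np.linspace(400, 720, 90)
        data = np.zeros((4, 4, 90))
        data[:, :, np.argmin(np.abs(wl - 442))] = 1.0
        rgb = synthesize_rgb(_cube(data, wl), RGBFilterBank.rayleigh(wl))
        r, g, b = rgb[0, 0]
        assert b > r and b > g

    def test_zero_cube_renders_black(self):
        wl = np.linspace(400, 720, 50)
        rgb = synthesize_rgb(_cube(np.zeros((3, 3, 50)), wl), RGBFilterBank.rayleigh(wl))
        assert np.all(rgb == 0)

    def test_centre_outside_range_rejected(self):
        with pytest.raises(ValueError):
            RGBFilterBank.rayleigh(np.linspace(500, 600, 20), centers=(442, 518, 579))


class TestNnlsUnmix:
    def test_pure_endmembers_give_saturation_extremes(self, hemoglobin_like):
        lib = hemoglobin_like
        data = np.stack([lib["oxy"], lib["deoxy"]])[None]  # (1, 2, n)
        res = nnls_unmix(_acube(data, lib.wavelengths), lib)
        assert res.so2[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert res.so2[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_equal_mixture_gives_half(self, hemoglobin_like):
        lib = hemoglobin_like
        mix = 0.5 * lib["oxy"] + 0.5 * lib["deoxy"]
        res = nnls_unmix(_acube(mix[None, None], lib.wavelengths), lib)
        assert res.so2[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert res.residual[0, 0] < 1e-10

    def test_matches_scipy_nnls_reference(self, hemoglobin_like):
        # closed-form 2-endmember route vs the generic solver on spectra
        # that force the non-negativity constraint to bind
        from scipy.optimize import nnls as scipy_nnls

        lib = hemoglobin_like
        rng = np.random.default_rng(0)
        spectra = np.clip(
            rng.uniform(-0.2, 1.0, (40, 1, len(lib.wavelengths)))
            * lib["oxy"] - 0.3 * lib["deoxy"],
            -0.5, None,
        )
        res = nnls_unmix(_acube(spectra, lib.wavelengths), lib)
        for i in range(spectra.shape[0]):
            ref, _ = scipy_nnls(lib.spectra.T, spectra[i, 0])
            assert np.allclose(res.coefficients[i, 0], ref, atol=1e-8)

    def test_three_endmember_path(self, hemoglobin_like):
        lib3 = EndmemberLibrary(
            ["oxy", "deoxy", "dye"],
            np.vstack([hemoglobin_like.spectra, np.linspace(1.0, 0.1, 60)]),
            hemoglobin_like.wavelengths,
        )
        mix = 0.3 * lib3.spectra[0] + 0.2 * lib3.spectra[1] + 0.4 * lib3.spectra[2]
        res = nnls_unmix(_acube(mix[None, None], lib3.wavelengths), lib3)
        assert np.allclose(res.coefficients[0, 0], [0.3, 0.2, 0.4], atol=1e-8)

    def test_noise_recovery_of_mixing_fractions(self, hemoglobin_like):
        # parameter recovery: 1% relative noise, |mean error| < 0.02
        lib = hemoglobin_like
        rng = np.random.default_rng(1)
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            mix = frac * lib["oxy"] + (1 - frac) * lib["deoxy"]
            noisy = mix[None, None] + rng.normal(
                0, 0.01 * np.abs(mix).mean(), (1, 200, len(lib.wavelengths))
            )
            res = nnls_unmix(_acube(noisy, lib.wavelengths), lib)
            err = np.abs(res.so2[0] - frac).mean()
            assert err < 0.02

    def test_so2_stays_in_unit_interval_and_flags_undefined(self, hemoglobin_like):
        lib = hemoglobin_like
        data = np.zeros((1, 2, 60))
        data[0, 1] = lib["oxy"]
        res = nnls_unmix(_acube(data, lib.wavelengths), lib)
        assert np.isnan(res.so2[0, 0])  # zero spectrum: alpha + beta == 0
        assert 0.0 <= res.so2[0, 1] <= 1.0

    def test_all_zero_endmember_rejected(self):
        with pytest.raises(ValueError):
            EndmemberLibrary(["a", "b"], np.vstack([np.zeros(5), np.ones(5)]), np.arange(5))


class TestSpectralAngle:
    def test_identical_spectra_angle_zero(self):
        s = np.array([1.0, 2.0, 3.0])
        assert spectral_angle(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_positive_scaling_invariance(self):
        s = np.array([0.3, 0.9, 0.1, 0.5])
        assert spectral_angle(4.2 * s, s) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_vectors_give_right_angle(self):
        assert spectral_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    @given(
        st.lists(st.floats(0.01, 10), min_size=4, max_size=12),
        st.floats(0.1, 10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_scale_invariance(self, vals, c):
        rng = np.random.default_rng(hash(tuple(vals)) % 2**31)
        t = np.array(vals)
        r = rng.uniform(0.01, 10, len(t))
        a1 = spectral_angle(t, r)
        assert spectral_angle(r, t) == pytest.approx(a1, abs=1e-9)
        assert spectral_angle(c * t, r) == pytest.approx(a1, abs=1e-7)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([0.0, 0.0], [1.0, 2.0])


class TestSamClassify:
    def test_region_equal_to_reference_has_zero_angle(self):
        ref = np.array([0.2, 0.5, 0.9, 0.4])
        data = np.broadcast_to(ref, (4, 6, 4)).copy()
        regions = np.zeros((4, 6), int)
        regions[:, 3:] = 1
        res = sam_classify(_acube(data), ref, regions)
        assert np.allclose(res.per_region["mean"], 0.0, atol=1e-9)
        assert np.allclose(res.per_region["sd"], 0.0, atol=1e-9)

    def test_region_means_match_analytic_angles(self):
        ref = np.array([1.0, 0.0, 0.0, 1.0])
        s1 = np.array([1.0, 1.0, 0.0, 1.0])
        s2 = np.array([0.0, 1.0, 1.0, 0.0])
        data = np.zeros((2, 5, 4))
        data[0] = s1
        data[1] = s2
        regions = np.array([[0] * 5, [1] * 5])
        res = sam_classify(_acube(data), ref, regions)
        means = res.per_region.set_index("region")["mean"]
        assert means[0] == pytest.approx(spectral_angle(s1, ref), abs=1e-9)
        assert means[1] == pytest.approx(spectral_angle(s2, ref), abs=1e-9)

    def test_distinct_regions_detected_by_anova(self):
        rng = np.random.default_rng(2)
        ref = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
        a = ref + rng.normal(0, 0.02, (60, 5))
        b = ref[::-1] + rng.normal(0, 0.02, (60, 5))
        data = np.concatenate([a, b]).reshape(2, 60, 5)
        regions = np.repeat([[0], [1]], 60, axis=1).reshape(2, 60)
        res = sam_classify(_acube(data), ref, regions)
        assert res.anova_p < 1e-6
        assert res.posthoc["significant"].all()

    def test_empty_region_label_rejected(self):
        data = np.ones((2, 2, 4))
        regions = np.zeros((2, 2), int)
        with pytest.raises(ValueError):
            sam_classify(_acube(data), np.ones(4), regions)  # single region

    def test_sam_map_flags_zero_spectra(self):
        data = np.ones((2, 2, 4))
        data[0, 0] = 0.0
        ang = sam_map(_acube(data), np.ones(4))
        assert np.isnan(ang[0, 0])
        assert ang[1, 1] == pytest.approx(0.0, abs=1e-9)


class TestPcaKmeans:
    def _two_region_cube(self, noise=0.01, seed=3, h=40, w=60):
        rng = np.random.default_rng(seed)
        wl = np.arange(20, dtype=float)
        sa = np.exp(-0.5 * ((wl - 6) / 3.0) ** 2)
        sb = np.exp(-0.5 * ((wl - 14) / 3.0) ** 2)
        data = np.empty((h, w, 20))
        data[:, : w // 2] = sa
        data[:, w // 2 :] = sb
        data += rng.normal(0, noise, data.shape)
        truth = np.zeros((h, w), int)
        truth[:, w // 2 :] = 1
        return _acube(data, wl), truth

    def test_two_region_recovery_above_99_percent(self):
        acube, truth = self._two_region_cube()
        labels, means, m = pca_kmeans_classify(acube, k=2, bin_px=5, seed=0)
        agree = max(
            (labels == truth).mean(), (labels == 1 - truth).mean()
        )
        assert agree >= 0.99

    def test_rank3_data_keeps_three_components(self):
        rng = np.random.default_rng(4)
        basis = rng.uniform(0, 1, (3, 30))
        weights = rng.uniform(0.2, 1.0, (25, 25, 3))
        data = np.einsum("yxk,kl->yxl", weights, basis)
        labels, means, m = pca_kmeans_classify(
            _acube(data), k=2, variance_target=0.999, bin_px=5, seed=0
        )
        assert m == 3

    def test_same_seed_reproduces_labels(self):
        acube, _ = self._two_region_cube(noise=0.1, seed=6)
        l1, _, _ = pca_kmeans_classify(acube, k=2, bin_px=5, seed=9)
        l2, _, _ = pca_kmeans_classify(acube, k=2, bin_px=5, seed=9)
        assert np.array_equal(l1, l2)

    def test_k_larger_than_bins_rejected(self):
        acube, _ = self._two_region_cube(h=10, w=10)
        with pytest.raises(ValueError):
            pca_kmeans_classify(acube, k=50, bin_px=5)

    def test_cluster_mean_spectra_match_generators(self):
        acube, truth = self._two_region_cube()
        labels, means, _ = pca_kmeans_classify(acube, k=2, bin_px=5, seed=0)
        wl = np.arange(20, dtype=float)
        sa = np.exp(-0.5 * ((wl - 6) / 3.0) ** 2)
        sb = np.exp(-0.5 * ((wl - 14) / 3.0) ** 2)
        angs = sorted(
            [spectral_angle(means[0], sa), spectral_angle(means[0], sb)]
        )
        assert angs[0] < 0.05  # one generator matches closely
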