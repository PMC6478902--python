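"""Feature extraction, pairwise similarity estimation, chaining, panorama."""

import numpy as np
import pytest

from endocube import preprocess as pp
from endocube import registration as reg
from endocube.geometry import GeometricTransform
from endocube.preprocess import WidefieldFrame


@pytest.fixture(scope="module")
def textured_frame(small_target):
    """One preprocessed simulated frame with plenty of structure."""
    from endocube.simulation import ViewSpec, emulate_widefield_frame

    view = ViewSpec(
        transform=GeometricTransform.from_params(translation=(30, 30)),
        crop_size=192,
        mask_radius=90,
        honeycomb_depth=0.0,
    )
    return emulate_widefield_frame(small_target, view)


class TestExtractFeatures:
    def test_textured_frame_yields_many_keypoints(self, textured_frame):
        feats = reg.extract_features(textured_frame)
        assert len(feats) >= 20

    def test_constant_frame_yields_empty_set(self):
        feats = reg.extract_features(WidefieldFrame(np.full((96, 96), 0.5)))
        assert len(feats) == 0

    def test_keypoints_lie_inside_valid_mask(self, textured_frame):
        feats = reg.extract_features(textured_frame)
        c = (192 - 1) / 2.0
        r = np.hypot(feats.keypoints[:, 0] - c, feats.keypoints[:, 1] - c)
        assert np.all(r <= 90)

    def test_rotated_copy_still_matches(self, textured_frame):
        from skimage.feature import match_descriptors

        rot = WidefieldFrame(
            np.rot90(textured_frame.data).copy(),
            valid_mask=np.rot90(textured_frame.valid_mask).copy(),
        )
        fa = reg.extract_features(textured_frame)
        fb = reg.extract_features(rot)
        matches = match_descriptors(
            fa.descriptors, fb.descriptors, cross_check=True, max_ratio=0.8
        )
        assert len(matches) >= 10

    def test_origin_offsets_keypoint_coordinates(self, textured_frame):
        base = reg.extract_features(textured_frame)
        shifted = WidefieldFrame(
            textured_frame.data,
            valid_mask=textured_frame.valid_mask,
            origin=(10.0, 20.0),
        )
        feats = reg.extract_features(shifted)
        assert np.allclose(feats.keypoints, base.keypoints + [20.0, 10.0])


class TestEstimatePairwise:
    def test_self_registration_is_identity(self, textured_frame):
        feats = reg.extract_features(textured_frame)
        res = reg.estimate_pairwise(feats, feats)
        assert res.ok
        assert np.allclose(res.transform.matrix, np.eye(3), atol=1e-3)

    def test_pure_shift_recovered_vs_phase_correlation(self, textured_frame):
        from skimage.registration import phase_cross_correlation

        data = textured_frame.data
        shifted = np.roll(np.roll(data, 3, axis=0), 8, axis=1)
        fa = reg.extract_features(textured_frame)
        fb = reg.extract_features(WidefieldFrame(shifted, valid_mask=textured_frame.valid_mask))
        res = reg.estimate_pairwise(fa, fb)
        assert res.ok
        # independent oracle: Fourier phase correlation on the same pair
        oracle, *_ = phase_cross_correlation(data, shifted, upsample_factor=50)
        assert res.transform.translation[0] == pytest.approx(oracle[1], abs=0.5)
        assert res.transform.translation[1] == pytest.approx(oracle[0], abs=0.5)
        assert res.transform.translation[0] == pytest.approx(-8.0, abs=0.5)

    def test_simulated_rotation_and_scale_recovered(self, small_target, clean_acq):
        frames = clean_acq.frames
        fa = reg.extract_features(frames[0])
        fb = reg.extract_features(frames[1])
        res = reg.estimate_pairwise(fa, fb)
        true_rel = clean_acq.true_transforms[0].inverse() @ clean_acq.true_transforms[1]
        assert res.ok
        assert res.transform.rotation_deg == pytest.approx(true_rel.rotation_deg, abs=0.1)
        assert res.transform.scale == pytest.approx(true_rel.scale, abs=0.005)

    def test_accepted_transform_is_similarity(self, clean_acq):
        fa = reg.extract_features(clean_acq.frames[0])
        fb = reg.extract_features(clean_acq.frames[1])
        res = reg.estimate_pairwise(fa, fb)
        sv = np.linalg.svd(res.transform.matrix[:2, :2], compute_uv=False)
        assert abs(sv[0] - sv[1]) <= 1e-6 * sv[0]

    def test_unmatchable_pair_signals_failure_without_raising(self, textured_frame):
        rng = np.random.default_rng(0)
        noise = WidefieldFrame(rng.uniform(0, 1, (96, 96)))
        fa = reg.extract_features(textured_frame)
        fb = reg.extract_features(noise)
        res = reg.estimate_pairwise(fa, fb)
        assert not res.ok


class TestChainToGlobal:
    def test_identity_pairs_give_identity_globals(self):
        pairs = [reg.PairwiseRegistration(GeometricTransform.identity(), 10)] * 4
        chain = reg.chain_to_global(pairs)
        for t, s in zip(chain.transforms, chain.status):
            assert np.allclose(t.matrix, np.eye(3))
            assert s == reg.STATUS_REGISTERED

    def test_composition_of_translations(self):
        shift = GeometricTransform.from_params(translation=(8.0, 0.0))
        pairs = [reg.PairwiseRegistration(shift, 10)] * 5
        chain = reg.chain_to_global(pairs)
        for k, t in enumerate(chain.transforms):
            assert np.allclose(t.translation, [8.0 * k, 0.0])

    def test_failed_link_carries_fallback_then_failed(self):
        shift = GeometricTransform.from_params(translation=(8.0, 0.0))
        ok = reg.PairwiseRegistration(shift, 10)
        bad = reg.PairwiseRegistration(None)
        chain = reg.chain_to_global([ok, bad, bad, ok])
        assert chain.status[1] == reg.STATUS_REGISTERED
        assert chain.status[2] == reg.STATUS_FALLBACK
        assert chain.status[3] == reg.STATUS_FAILED
        assert np.allclose(chain.transforms[2].matrix, chain.transforms[1].matrix)

    def test_nonzero_reference_frame(self):
        shift = GeometricTransform.from_params(translation=(8.0, 0.0))
        pairs = [reg.PairwiseRegistration(shift, 10)] * 3
        chain = reg.chain_to_global(pairs, reference_index=2)
        assert np.allclose(chain.transforms[2].matrix, np.eye(3))
        assert np.allclose(chain.transforms[0].translation, [-16.0, 0.0])

    def test_reference_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reg.chain_to_global([reg.PairwiseRegistration(None)], reference_index=5)


class TestRegisterSequence:
    def test_clean_roundtrip_recovers_true_transforms(self, clean_acq):
        """Zero-noise, honeycomb-free parameter recovery (round-trip oracle).

        Bounds scale with the reduced fixture geometry: these 192 px frames
        carry ~4x fewer keypoints and half the angular lever arm of the
        full-size frames, so rotation/scale noise is ~3x the full-scale
        recovery tolerance (which the acceptance suite checks at full size).
        """
        chain = reg.register_sequence(clean_acq.frames, seed=0)
        assert chain.n_registered == clean_acq.n_frames
        tg = clean_acq.true_globals()
        for est, true in zip(chain.transforms, tg):
            d, dr, ds = est.compare(true, extent=192)
            assert d < 0.75 and dr < 0.4 and ds < 0.02

    def test_noisy_honeycomb_sequence_registers_all_frames(self, small_acq):
        frames = [
            pp.preprocess_frame(f, cutoff="auto", crop=True) for f in small_acq.frames
        ]
        chain = reg.register_sequence(frames, seed=0)
        assert chain.n_registered == small_acq.n_frames

    def test_anchor_span_one_reduces_to_consecutive(self, clean_acq):
        chain = reg.register_sequence(clean_acq.frames[:5], seed=0, anchor_span=1)
        assert chain.n_registered == 5
        assert all(s == reg.STATUS_REGISTERED for s in chain.status)


class TestComposePanorama:
    def test_single_identity_frame_reproduces_frame(self, textured_frame):
        chain = reg.RegistrationChain(
            [GeometricTransform.identity()], [reg.STATUS_REGISTERED], [99]
        )
        pano = reg.compose_panorama([textured_frame], chain)
        inside = textured_frame.valid_mask
        assert pano.image.shape == textured_frame.data.shape
        assert np.allclose(pano.image[inside], textured_frame.data[inside], atol=1e-9)

    def test_half_width_shift_extends_canvas(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0.1, 1.0, (64, 64))
        frames = [WidefieldFrame(data), WidefieldFrame(data)]
        shift = GeometricTransform.from_params(translation=(32.0, 0.0))
        chain = reg.RegistrationChain(
            [GeometricTransform.identity(), shift],
            [reg.STATUS_REGISTERED] * 2,
            [99, 99],
        )
        pano = reg.compose_panorama(frames, chain)
        assert abs(pano.image.shape[1] - 96) <= 1
        assert abs(pano.image.shape[0] - 64) <= 1

    def test_overlap_of_identical_frames_averages_to_frame(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0.1, 1.0, (64, 64))
        frames = [WidefieldFrame(data), WidefieldFrame(data)]
        chain = reg.RegistrationChain(
            [GeometricTransform.identity()] * 2, [reg.STATUS_REGISTERED] * 2, [9, 9]
        )
        pano = reg.compose_panorama(frames, chain)
        assert np.allclose(pano.image, data, atol=1e-9)
        assert np.all(pano.coverage == 2)

    def test_frame_order_does_not_change_panorama(self, small_acq):
        frames = small_acq.frames[:4]
        chain = reg.register_sequence(
            [pp.preprocess_frame(f, cutoff="auto") for f in frames], seed=0
        )
        pano = reg.compose_panorama(frames, chain)
        perm = [2, 0, 3, 1]
        chain_p = reg.RegistrationChain(
            [chain.transforms[i] for i in perm],
            [chain.status[i] for i in perm],
            [chain.inlier_counts[i] for i in perm],
        )
        pano_p = reg.compose_panorama([frames[i] for i in perm], chain_p)
        both = np.isfinite(pano.image) & np.isfinite(pano_p.image)
        assert np.allclose(pano.image[both], pano_p.image[both], atol=1e-6)

    def test_no_registered_frames_raises(self, textured_frame):
        chain = reg.RegistrationChain([None], [reg.STATUS_FAILED], [0])
        with pytest.raises(ValueError):
            reg.compose_panorama([textured_frame], chain)
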