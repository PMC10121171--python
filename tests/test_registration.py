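import functools

import numpy as np
import pytest

from tinytrack.register import (
    FeatureSet,
    GlobalTransformSet,
    MatchSet,
    PairwiseTransform,
    RegistrationError,
    chain_global_transforms,
    detect_features,
    estimate_pairwise_transform,
    match_features,
    optimize_global_transforms,
    reintegrate_and_refine,
    register_sequence,
    register_sequences,
    select_keyframes,
)
from tinytrack.synth import (
    default_scene,
    generate_background,
    generate_camera_script,
    loop_registration_problem,
    render_sequence,
    TargetScript,
)
from tinytrack.transforms import apply_transform, is_similarity, similarity_from_params, translation_of
from tinytrack.types import Frame, FrameSequence


class TestDetectFeatures:
    def test_uniform_frame_no_keypoints(self):
        fs = detect_features(Frame(0, np.full((96, 128), 0.5)))
        assert len(fs) == 0

    def test_textured_frame_many_keypoints(self, small_scene):
        seq, _ = small_scene
        fs = detect_features(seq[0])
        assert len(fs) >= 100

    def test_deterministic(self, small_scene):
        seq, _ = small_scene
        a = detect_features(seq[0])
        b = detect_features(seq[0])
        assert np.array_equal(a.keypoints, b.keypoints)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_keypoints_in_bounds(self, small_scene):
        seq, _ = small_scene
        fs = detect_features(seq[0])
        assert fs.keypoints[:, 0].min() >= 0 and fs.keypoints[:, 0].max() < seq.width
        assert fs.keypoints[:, 1].min() >= 0 and fs.keypoints[:, 1].max() < seq.height


class TestMatchFeatures:
    def test_self_match_identity(self, small_scene):
        seq, _ = small_scene
        fs = detect_features(seq[0])
        ms = match_features(fs, fs)
        # every match must be a self-pair; near-duplicate descriptors may drop
        assert len(ms) >= 0.9 * len(fs)
        assert np.array_equal(ms.coords_a, ms.coords_b)

    def test_random_descriptors_rarely_match(self):
        rng = np.random.default_rng(0)
        a = FeatureSet(0, rng.random((200, 2)) * 100, rng.random((200, 256)) > 0.5)
        b = FeatureSet(1, rng.random((200, 2)) * 100, rng.random((200, 256)) > 0.5)
        ms = match_features(a, b)
        assert len(ms) < 20

    def test_swap_symmetry(self, small_scene):
        seq, _ = small_scene
        fa = detect_features(seq[0])
        fb = detect_features(seq[1])
        ab = match_features(fa, fb)
        ba = match_features(fb, fa)
        set_ab = {(tuple(p), tuple(q)) for p, q in zip(ab.coords_a, ab.coords_b)}
        set_ba = {(tuple(q), tuple(p)) for p, q in zip(ba.coords_a, ba.coords_b)}
        assert set_ab == set_ba

    def test_descriptor_length_mismatch(self):
        a = FeatureSet(0, np.zeros((2, 2)), np.zeros((2, 256), dtype=bool))
        b = FeatureSet(1, np.zeros((2, 2)), np.zeros((2, 128), dtype=bool))
        with pytest.raises(ValueError, match="descriptor lengths"):
            match_features(a, b)


def _matches_from_transform(M, n=20, noise=0.0, outliers=0, seed=0):
    rng = np.random.default_rng(seed)
    pa = rng.uniform(0, 200, (n + outliers, 2))
    pb = apply_transform(M, pa)
    if noise:
        pb = pb + rng.normal(0, noise, pb.shape)
    if outliers:
        pb[n:] += rng.uniform(40, 90, (outliers, 2))
    return MatchSet((0, 1), pa, pb)


class TestEstimatePairwise:
    def test_exact_similarity_recovery(self):
        M = similarity_from_params(np.deg2rad(10.0), np.log(1.1), 5.0, -3.0)
        pw = estimate_pairwise_transform(_matches_from_transform(M), "similarity")
        assert np.allclose(pw.matrix, M, atol=1e-6)
        assert pw.mean_error < 1e-6

    def test_robust_to_gross_outliers(self):
        M = similarity_from_params(np.deg2rad(10.0), np.log(1.1), 5.0, -3.0)
        ms = _matches_from_transform(M, n=20, outliers=8)
        pw = estimate_pairwise_transform(ms, "similarity")
        assert pw.inlier_count == 20
        assert np.allclose(pw.matrix, M, atol=1e-3)

    def test_homography_recovery(self):
        H = np.array([[1.02, 0.01, 3.0], [-0.02, 0.99, -2.0], [1e-5, -2e-5, 1.0]])
        pw = estimate_pairwise_transform(_matches_from_transform(H, n=30), "homography")
        assert np.allclose(pw.matrix, H, atol=1e-5)

    def test_collinear_homography_fails(self):
        pa = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        ms = MatchSet((0, 1), pa, pa)
        with pytest.raises(RegistrationError, match="estimation failed"):
            estimate_pairwise_transform(ms, "homography")

    def test_too_few_matches(self):
        ms = MatchSet((3, 4), np.zeros((1, 2)), np.zeros((1, 2)))
        with pytest.raises(RegistrationError, match=r"\(3, 4\)"):
            estimate_pairwise_transform(ms, "similarity")

    def test_similarity_closure(self):
        M = similarity_from_params(0.4, 0.05, 12.0, 8.0)
        pw = estimate_pairwise_transform(_matches_from_transform(M, noise=0.5), "similarity")
        assert is_similarity(pw.matrix, tol=1e-9)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            estimate_pairwise_transform(_matches_from_transform(np.eye(3)), "affine")


def _synthetic_chain(n_frames, dx, width=512, height=384, inliers=500):
    """Identity feature sets + pure-translation pairwise chain."""
    frames = [Frame(i, np.full((height, width), 0.5)) for i in range(n_frames)]
    seq = FrameSequence(frames=frames, fps=50.0)
    rng = np.random.default_rng(0)
    kp = rng.uniform(0, [width, height], (200, 2))
    feats = [FeatureSet(i, kp, np.zeros((200, 256), dtype=bool)) for i in range(n_frames)]
    M = similarity_from_params(0.0, 0.0, dx, 0.0)
    chain = [
        PairwiseTransform((i, i + 1), "similarity", M.copy(), inliers, 0.1)
        for i in range(n_frames - 1)
    ]
    return seq, feats, chain


class TestSelectKeyframes:
    def test_static_camera_single_key(self):
        seq, feats, chain = _synthetic_chain(100, dx=0.0)
        keys = select_keyframes(seq, feats, chain, overlap_threshold=0.5, max_gap=100)
        assert keys == [0]

    def test_static_camera_max_gap_rule(self):
        seq, feats, chain = _synthetic_chain(100, dx=0.0)
        keys = select_keyframes(seq, feats, chain, overlap_threshold=0.5, max_gap=30)
        assert keys[0] == 0
        gaps = np.diff(keys + [99])
        assert gaps.max() <= 30
        assert len(keys) <= 5  # forced by max-gap only, not overlap

    def test_pan_spacing_matches_overlap(self):
        # 4 px/frame on a 512-px-wide frame: overlap >= 0.5 allows gaps <= 64
        seq, feats, chain = _synthetic_chain(200, dx=4.0)
        keys = select_keyframes(seq, feats, chain, overlap_threshold=0.5, max_gap=100)
        gaps = np.diff(keys)
        assert gaps.max() <= 64
        assert gaps.min() >= 52  # frontier keeps the far end of the window

    def test_single_frame(self):
        frame = Frame(0, np.full((96, 128), 0.5))
        seq = FrameSequence(frames=[frame], fps=50.0)
        feats = [FeatureSet(0, np.empty((0, 2)), np.empty((0, 256), dtype=bool))]
        keys = select_keyframes(seq, feats, [], overlap_threshold=0.5)
        assert keys == [0]


def _random_similarity_chain(rng, K):
    mats = [
        similarity_from_params(
            rng.uniform(-0.5, 0.5), rng.uniform(-0.1, 0.1), rng.uniform(-20, 20), rng.uniform(-20, 20)
        )
        for _ in range(K - 1)
    ]
    return [
        PairwiseTransform((i, i + 1), "similarity", mats[i]) for i in range(K - 1)
    ]


class TestChainGlobalTransforms:
    def test_first_is_identity(self):
        chain = _random_similarity_chain(np.random.default_rng(0), 5)
        gset = chain_global_transforms(chain)
        assert np.array_equal(gset.transforms[0], np.eye(3))

    def test_two_translations(self):
        M = similarity_from_params(0.0, 0.0, 10.0, 0.0)
        chain = [
            PairwiseTransform((0, 1), "similarity", M.copy()),
            PairwiseTransform((1, 2), "similarity", M.copy()),
        ]
        gset = chain_global_transforms(chain)
        assert np.allclose(translation_of(gset.transforms[2]), [-20.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_product(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(3, 11))
        chain = _random_similarity_chain(rng, K)
        gset = chain_global_transforms(chain)
        # independent oracle: accumulate the product front-to-back
        expected = functools.reduce(
            np.matmul, [np.linalg.inv(p.matrix) for p in chain], np.eye(3)
        )
        assert np.allclose(gset.transforms[K - 1], expected, atol=1e-9)

    def test_broken_chain(self):
        chain = [
            PairwiseTransform((0, 1), "similarity", np.eye(3)),
            PairwiseTransform((2, 3), "similarity", np.eye(3)),
        ]
        with pytest.raises(RegistrationError, match="broken chain"):
            chain_global_transforms(chain)


class TestOptimizeGlobal:
    def test_consistent_matches_zero_objective(self):
        rng = np.random.default_rng(1)
        true = {0: np.eye(3), 1: similarity_from_params(0.1, 0.02, 30.0, -10.0)}
        pts = rng.uniform(0, 100, (25, 2))
        # matches exactly consistent with the true transforms
        fa = pts
        fb = apply_transform(np.linalg.inv(true[1]) @ true[0], pts)
        gset = GlobalTransformSet(transforms={k: v.copy() for k, v in true.items()}, keyframes=[0, 1])
        out, report = optimize_global_transforms([MatchSet((0, 1), fa, fb)], gset)
        assert report.j_after <= 1e-9

    def test_never_increases_objective(self):
        prob = loop_registration_problem(seed=2, n_frames=60, key_stride=6)
        _, report = optimize_global_transforms(prob["matchsets"], prob["initial"])
        assert report.j_after <= report.j_before

    def test_loop_drift_correction(self):
        prob = loop_registration_problem(seed=0, n_frames=120, key_stride=6)
        first, last = prob["loop_pair"]
        w, h = prob["frame_size"]
        S = prob["camera"].transforms

        def loop_error(gset):
            # a world point seen in both first and last key frames
            wpt = translation_of(S[first]) + np.array([w / 2.0, h / 2.0])
            pa = apply_transform(np.linalg.inv(S[first]), wpt)
            pb = apply_transform(np.linalg.inv(S[last]), wpt)
            return np.linalg.norm(
                apply_transform(gset.transforms[first], pa) - apply_transform(gset.transforms[last], pb)
            )

        err_before = loop_error(prob["initial"])
        optimized, report = optimize_global_transforms(prob["matchsets"], prob["initial"])
        err_after = loop_error(optimized)
        assert err_before > 10.0  # injected drift is substantial
        assert err_after <= err_before / 10.0

    def test_single_keyframe(self):
        gset = GlobalTransformSet(transforms={0: np.eye(3)}, keyframes=[0])
        out, report = optimize_global_transforms([], gset)
        assert np.array_equal(out.transforms[0], np.eye(3))
        assert report.j_after == 0.0

    def test_gauge_fixed(self):
        prob = loop_registration_problem(seed=3, n_frames=60, key_stride=10)
        optimized, _ = optimize_global_transforms(prob["matchsets"], prob["initial"])
        assert np.allclose(optimized.transforms[prob["keys"][0]], np.eye(3))

    def test_similarity_closure(self):
        prob = loop_registration_problem(seed=4, n_frames=60, key_stride=10)
        optimized, _ = optimize_global_transforms(prob["matchsets"], prob["initial"])
        optimized.validate(tol=1e-9)


class TestReintegrate:
    def test_all_keyframes_identity_passthrough(self, small_scene, small_scene_registered):
        seq, _ = small_scene
        feats, sims, _ = small_scene_registered
        sub = [seq[i] for i in range(3)]
        subseq = FrameSequence(frames=sub, fps=seq.fps)
        mats = {0: np.eye(3), 1: similarity_from_params(0, 0, 1.0, 0), 2: similarity_from_params(0, 0, 2.0, 0)}
        gset = GlobalTransformSet(transforms=mats, keyframes=[0, 1, 2])
        dense = reintegrate_and_refine(subseq, gset, feats[:3])
        for k in (0, 1, 2):
            assert np.array_equal(dense.transforms[k], mats[k])

    def test_dense_recovery_on_scene(self, small_scene):
        seq, truth = small_scene
        dense, report, _, _ = register_sequence(seq)
        S0 = truth.camera.transforms[0]
        c = np.array([seq.width / 2.0, seq.height / 2.0])
        errs = []
        for i in range(len(seq)):
            true_T = np.linalg.inv(S0) @ truth.camera.transforms[i]
            errs.append(
                np.linalg.norm(
                    apply_transform(dense.transforms[i], c) - apply_transform(true_T, c)
                )
            )
        assert np.median(errs) <= 1.0

    def test_every_frame_has_transform(self, small_scene):
        seq, _ = small_scene
        dense, _, _, _ = register_sequence(seq)
        assert set(dense.transforms) == set(range(len(seq)))
        dense.validate(tol=1e-6)


class TestMultiVideo:
    def test_shared_coordinate_system(self, background):
        # two target-free videos panning over overlapping background regions
        n = 8
        cam1 = generate_camera_script("static", n, start_xy=(100.0, 150.0))
        cam2 = generate_camera_script("static", n, start_xy=(140.0, 170.0))
        tgt = TargetScript(positions=np.tile([0.0, 0.0], (n, 1)), headings=np.zeros(n), contrast=0.0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            seq1, _ = render_sequence(background, cam1, tgt, frame_size=(192, 144), noise_sd=0.005, seed=1, source_id="v1")
            seq2, _ = render_sequence(background, cam2, tgt, frame_size=(192, 144), noise_sd=0.005, seed=2, source_id="v2")
        merged, report = register_sequences([seq1, seq2])
        wpt = np.array([230.0, 240.0])  # world point visible in both
        p1 = wpt - [100.0, 150.0]
        p2 = wpt - [140.0, 170.0]
        m1 = apply_transform(merged.transforms[0], p1)
        m2 = apply_transform(merged.transforms[n], p2)
        assert np.linalg.norm(m1 - m2) < 3.0
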