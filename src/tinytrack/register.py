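"""Frame registration: features, pairwise transforms, key frames, and
globally consistent similarity transforms.

Pairwise convention: ``PairwiseTransform(i, j).matrix`` maps frame-``i``
pixel coordinates into frame-``j`` pixel coordinates.  Global transforms
map frame coordinates into the common mosaic coordinate system anchored
at the first key frame (whose transform is the identity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import MultiPoint, Polygon, box
from skimage.feature import ORB
from skimage.measure import ransac as _sk_ransac
from skimage.transform import ProjectiveTransform, SimilarityTransform

from .transforms import (
    apply_transform,
    geodesic_interpolate,
    is_similarity,
    similarity_from_params,
    similarity_params,
)
from .types import Frame, FrameSequence

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "MatchSet",
    "PairwiseTransform",
    "GlobalTransformSet",
    "ObjectiveReport",
    "RegistrationError",
    "detect_features",
    "match_features",
    "estimate_pairwise_transform",
    "select_keyframes",
    "chain_global_transforms",
    "optimize_global_transforms",
    "reintegrate_and_refine",
    "register_sequence",
    "register_sequences",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class FeatureSet:
    frame_index: int
    keypoints: np.ndarray           # (n, 2) sub-pixel (x, y)
    descriptors: np.ndarray         # (n, L)

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class MatchSet:
    pair: tuple[int, int]
    coords_a: np.ndarray            # (m, 2) points in frame pair[0]
    coords_b: np.ndarray            # (m, 2) points in frame pair[1]
    inliers: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coords_a)

    def swapped(self) -> "MatchSet":
        return MatchSet(
            pair=(self.pair[1], self.pair[0]),
            coords_a=self.coords_b.copy(),
            coords_b=self.coords_a.copy(),
            inliers=None if self.inliers is None else self.inliers.copy(),
        )


@dataclass
class PairwiseTransform:
    pair: tuple[int, int]
    model: str                      # "homography" | "similarity"
    matrix: np.ndarray              # maps frame pair[0] -> frame pair[1]
    inlier_count: int = 0
    mean_error: float = float("nan")

    def inverse(self) -> "PairwiseTransform":
        return PairwiseTransform(
            pair=(self.pair[1], self.pair[0]),
            model=self.model,
            matrix=np.linalg.inv(self.matrix),
            inlier_count=self.inlier_count,
            mean_error=self.mean_error,
        )


@dataclass
class GlobalTransformSet:
    """Per-frame transforms into the common mosaic coordinate system."""

    transforms: dict[int, np.ndarray]
    keyframes: list[int] = field(default_factory=list)
    video_offsets: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.transforms[frame]

    def validate(self, tol: float = 1e-9) -> None:
        for i, M in self.transforms.items():
            if not is_similarity(M, tol):
                raise ValueError(f"transform for frame {i} is not a similarity")


@dataclass
class ObjectiveReport:
    j_before: float
    j_after: float
    iterations: int
    converged: bool


def detect_features(frame: Frame, n_keypoints: int = 1000) -> FeatureSet:
    """ORB keypoints + binary descriptors; deterministic per frame."""
    img = frame.image
    if img.std() < 1e-6:
        return FeatureSet(frame.index, np.empty((0, 2)), np.empty((0, 256), dtype=bool))
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
    try:
        orb.detect_and_extract(img)
    except RuntimeError:  # no features found
        return FeatureSet(frame.index, np.empty((0, 2)), np.empty((0, 256), dtype=bool))
    kp = orb.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return FeatureSet(frame.index, kp, orb.descriptors)


_POPCOUNT = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(axis=1).astype(np.uint16)


def _hamming_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise hamming distances between binary descriptor sets."""
    pa = np.packbits(a.astype(bool), axis=1)
    pb = np.packbits(b.astype(bool), axis=1)
    out = np.empty((len(pa), len(pb)), dtype=np.int32)
    step = max(1, 2_000_000 // max(len(pb), 1))
    for lo in range(0, len(pa), step):
        hi = min(lo + step, len(pa))
        out[lo:hi] = _POPCOUNT[pa[lo:hi, None, :] ^ pb[None, :, :]].sum(axis=2, dtype=np.int32)
    return out


def _ratio_ok(d: np.ndarray, axis: int, max_ratio: float) -> np.ndarray:
    """Lowe ratio test along ``axis``; rows/cols with a single candidate pass."""
    if d.shape[axis] < 2:
        return np.ones(d.shape[1 - axis], dtype=bool)
    two = np.partition(d, 1, axis=axis).take([0, 1], axis=axis)
    d1 = two.take(0, axis=axis).astype(float)
    d2 = two.take(1, axis=axis).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(d2 > 0, d1 / d2, np.where(d1 > 0, np.inf, 0.0))
    return ratio <= max_ratio


def match_features(a: FeatureSet, b: FeatureSet, max_ratio: float = 0.8) -> MatchSet:
    """Mutual-nearest-neighbor matching with a two-sided ratio test.

    Symmetric by construction: matching (b, a) yields the same
    correspondence set with endpoints swapped.
    """
    if len(a) == 0 or len(b) == 0:
        return MatchSet((a.frame_index, b.frame_index), np.empty((0, 2)), np.empty((0, 2)))
    if a.descriptors.shape[1] != b.descriptors.shape[1]:
        raise ValueError("descriptor lengths differ")
    d = _hamming_matrix(a.descriptors, b.descriptors)
    best_b = d.argmin(axis=1)
    best_a = d.argmin(axis=0)
    ia = np.arange(len(a))
    mutual = best_a[best_b] == ia
    ok = mutual & _ratio_ok(d, 1, max_ratio) & _ratio_ok(d, 0, max_ratio)[best_b]
    idx_a = ia[ok]
    idx_b = best_b[ok]
    return MatchSet(
        pair=(a.frame_index, b.frame_index),
        coords_a=a.keypoints[idx_a],
        coords_b=b.keypoints[idx_b],
    )


def _symmetric_error(M: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Per-match mean of forward and backward transfer errors."""
    fwd = np.linalg.norm(apply_transform(M, pa) - pb, axis=1)
    bwd = np.linalg.norm(apply_transform(np.linalg.inv(M), pb) - pa, axis=1)
    return 0.5 * (fwd + bwd)


def estimate_pairwise_transform(
    matches: MatchSet,
    model: str = "similarity",
    ransac_threshold: float = 3.0,
    rng: int = 0,
) -> PairwiseTransform:
    """RANSAC estimate followed by a least-squares refit on the inliers."""
    if model == "similarity":
        tform_cls, min_samples = SimilarityTransform, 2
    elif model == "homography":
        tform_cls, min_samples = ProjectiveTransform, 4
    else:
        raise ValueError(f"unknown model {model!r}")
    pa, pb = matches.coords_a, matches.coords_b
    if len(pa) < min_samples:
        raise RegistrationError(
            f"estimation failed for pair {matches.pair}: only {len(pa)} matches"
        )
    if len(pa) == min_samples:
        tf = tform_cls.from_estimate(pa, pb)
        if not tf:
            raise RegistrationError(f"estimation failed for pair {matches.pair}: degenerate")
        inl = np.ones(len(pa), dtype=bool)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tf, inl = _sk_ransac(
                (pa, pb),
                tform_cls,
                min_samples=min_samples,
                residual_threshold=ransac_threshold,
                max_trials=500,
                stop_probability=0.9999,
                rng=rng,
            )
        if tf is None or inl is None or inl.sum() < min_samples:
            raise RegistrationError(f"estimation failed for pair {matches.pair}: degenerate")
        refit = tform_cls.from_estimate(pa[inl], pb[inl])
        if refit:
            tf = refit
    M = np.asarray(tf.params, dtype=float)
    if not np.isfinite(M).all() or abs(np.linalg.det(M)) < 1e-12:
        raise RegistrationError(f"estimation failed for pair {matches.pair}: singular matrix")
    if model == "homography" and abs(M[2, 2]) > 1e-12:
        M = M / M[2, 2]
    inl = inl.astype(bool)
    matches.inliers = inl
    err = float(np.mean(_symmetric_error(M, pa[inl], pb[inl]))) if inl.any() else float("nan")
    return PairwiseTransform(matches.pair, model, M, int(inl.sum()), err)


def _overlap_fraction(M: np.ndarray, width: int, height: int) -> float:
    """Intersection-over-area of the warped frame polygon vs the reference frame."""
    corners = np.array([[0, 0], [width, 0], [width, height], [0, height]], dtype=float)
    warped = Polygon(apply_transform(M, corners))
    if not warped.is_valid:
        return 0.0
    ref = box(0, 0, width, height)
    return warped.intersection(ref).area / ref.area


def _coverage_fraction(keypoints: np.ndarray, width: int, height: int) -> float:
    if len(keypoints) < 3:
        return 0.0
    hull = MultiPoint(keypoints).convex_hull
    return hull.area / (width * height)


def select_keyframes(
    sequence: FrameSequence,
    features: list[FeatureSet],
    chain: list[PairwiseTransform],
    overlap_threshold: float = 0.5,
    max_gap: int = 100,
) -> list[int]:
    """Greedy key-frame selection by overlap, quality and a max-gap rule.

    From the current key frame, candidate frames keep estimated overlap
    >= ``overlap_threshold``; among the candidates at the far end of the
    acceptable window the one maximizing
    ``inliers * coverage / (1 + reprojection_error)`` is chosen.  A new
    key frame is only forced when the remaining frames would otherwise
    violate the overlap or max-gap constraints.
    """
    n = len(sequence)
    w, h = sequence.width, sequence.height
    if len(chain) != n - 1:
        raise ValueError("need a pairwise transform for every consecutive pair")
    keys = [0]
    k = 0
    while True:
        limit = min(k + max_gap, n - 1)
        cands: list[int] = []
        M = np.eye(3)
        reached_end = limit == n - 1
        for j in range(k + 1, limit + 1):
            M = chain[j - 1].matrix @ M  # frame k -> frame j
            if _overlap_fraction(np.linalg.inv(M), w, h) < overlap_threshold:
                reached_end = False
                cands = cands or [j]  # fall back to the nearest frame
                if len(cands) == 1 and cands[0] == j:
                    logger.warning("no candidate met overlap %.2f after frame %d", overlap_threshold, k)
                break
            cands.append(j)
        if reached_end and n - 1 - k <= max_gap:
            break  # remaining frames all overlap the current key frame
        if not cands:
            break
        frontier = cands[-max(1, len(cands) // 10):]

        def quality(j: int) -> float:
            pw = chain[j - 1]
            cov = _coverage_fraction(features[j].keypoints, w, h)
            err = pw.mean_error if np.isfinite(pw.mean_error) else 10.0
            return pw.inlier_count * cov / (1.0 + err)

        k = max(frontier, key=quality)
        keys.append(k)
        if k >= n - 1:
            break
    return keys


def chain_global_transforms(pairwise: list[PairwiseTransform]) -> GlobalTransformSet:
    """Chain consecutive key-frame similarities into global transforms.

    The first key frame is the identity; key frame ``j`` gets the ordered
    product of the inverses of the consecutive pairwise transforms.
    """
    if not pairwise:
        raise ValueError("empty pairwise chain")
    keys = [pairwise[0].pair[0]] + [p.pair[1] for p in pairwise]
    for p, expected in zip(pairwise, keys):
        if p.pair[0] != expected:
            raise RegistrationError(f"broken chain at pair {p.pair}: expected start {expected}")
    transforms = {keys[0]: np.eye(3)}
    M = np.eye(3)
    for p in pairwise:
        M = M @ np.linalg.inv(p.matrix)
        transforms[p.pair[1]] = M.copy()
    return GlobalTransformSet(transforms=transforms, keyframes=keys)


def _objective(global_mats: dict[int, np.ndarray], matchsets: list[MatchSet]) -> float:
    """Symmetric reprojection objective over all key-frame match sets."""
    total = 0.0
    for ms in matchsets:
        i, j = ms.pair
        Ti, Tj = global_mats[i], global_mats[j]
        A = np.linalg.inv(Tj) @ Ti
        fwd = apply_transform(A, ms.coords_a) - ms.coords_b
        bwd = apply_transform(np.linalg.inv(A), ms.coords_b) - ms.coords_a
        total += float(np.sum(fwd**2) + np.sum(bwd**2))
    return total


def optimize_global_transforms(
    matchsets: list[MatchSet],
    initial: GlobalTransformSet,
    robust_scale: float = 3.0,
    max_iter: int = 200,
) -> tuple[GlobalTransformSet, ObjectiveReport]:
    """Jointly refine key-frame similarities by minimizing the symmetric
    reprojection error over all key-frame match sets.

    Parameterized per key frame as (theta, log_s, tx, ty) with the first
    key frame frozen to the identity (gauge fixing); a soft-L1 loss
    down-weights gross outlier matches.
    """
    keys = list(initial.keyframes)
    if len(keys) == 1:
        return initial, ObjectiveReport(0.0, 0.0, 0, True)
    if not matchsets:
        raise ValueError("need at least one match set")
    key_pos = {k: i for i, k in enumerate(keys)}
    usable = [ms for ms in matchsets if ms.pair[0] in key_pos and ms.pair[1] in key_pos and len(ms)]
    x0 = np.concatenate([similarity_params(initial.transforms[k]) for k in keys[1:]])

    def unpack(x: np.ndarray) -> dict[int, np.ndarray]:
        mats = {keys[0]: np.eye(3)}
        for n, k in enumerate(keys[1:]):
            mats[k] = similarity_from_params(*x[4 * n : 4 * n + 4])
        return mats

    def residuals(x: np.ndarray) -> np.ndarray:
        mats = unpack(x)
        out = []
        for ms in usable:
            A = np.linalg.inv(mats[ms.pair[1]]) @ mats[ms.pair[0]]
            out.append((apply_transform(A, ms.coords_a) - ms.coords_b).ravel())
            out.append((apply_transform(np.linalg.inv(A), ms.coords_b) - ms.coords_a).ravel())
        return np.concatenate(out)

    j_before = _objective(initial.transforms, usable)
    res = least_squares(
        residuals, x0, loss="soft_l1", f_scale=robust_scale, max_nfev=max_iter * len(x0),
        x_scale="jac",
    )
    mats = unpack(res.x)
    j_after = _objective(mats, usable)
    converged = bool(res.status > 0)
    if j_after > j_before:  # robust loss may trade raw J; never report a regression
        mats = {k: v.copy() for k, v in initial.transforms.items()}
        j_after, converged = j_before, False
    out = GlobalTransformSet(
        transforms=mats, keyframes=keys, video_offsets=dict(initial.video_offsets)
    )
    return out, ObjectiveReport(j_before, j_after, int(res.nfev), converged)


_MAX_REFINE_MATCHES = 150


def _thin_matches(ms: MatchSet) -> MatchSet:
    """Deterministically subsample an oversized match set for refinement."""
    if len(ms) <= _MAX_REFINE_MATCHES:
        return ms
    idx = np.linspace(0, len(ms) - 1, _MAX_REFINE_MATCHES).astype(int)
    return MatchSet(ms.pair, ms.coords_a[idx], ms.coords_b[idx])


def _refine_frame(
    T0: np.ndarray, anchors: list[tuple[np.ndarray, MatchSet]]
) -> tuple[np.ndarray, float, float]:
    """Refine one frame's similarity against fixed anchor key frames.

    Returns (matrix, error_before, error_after); never returns a transform
    with a larger symmetric reprojection error than the initialization.
    """
    anchors = [(T, _thin_matches(ms)) for T, ms in anchors]

    def error_of(M: np.ndarray) -> float:
        total = 0.0
        for T_anchor, ms in anchors:
            A = np.linalg.inv(T_anchor) @ M
            fwd = apply_transform(A, ms.coords_a) - ms.coords_b
            bwd = apply_transform(np.linalg.inv(A), ms.coords_b) - ms.coords_a
            total += float(np.sum(fwd**2) + np.sum(bwd**2))
        return total

    def residuals(x: np.ndarray) -> np.ndarray:
        M = similarity_from_params(*x)
        out = []
        for T_anchor, ms in anchors:
            A = np.linalg.inv(T_anchor) @ M
            out.append((apply_transform(A, ms.coords_a) - ms.coords_b).ravel())
            out.append((apply_transform(np.linalg.inv(A), ms.coords_b) - ms.coords_a).ravel())
        return np.concatenate(out)

    e0 = error_of(T0)
    res = least_squares(residuals, np.array(similarity_params(T0)), loss="soft_l1", f_scale=3.0)
    M = similarity_from_params(*res.x)
    e1 = error_of(M)
    if e1 > e0:
        return T0.copy(), e0, e0
    return M, e0, e1


def reintegrate_and_refine(
    sequence: FrameSequence,
    keyframe_set: GlobalTransformSet,
    features: list[FeatureSet],
    max_ratio: float = 0.8,
    frame_offset: int = 0,
) -> GlobalTransformSet:
    """Reinstate dense per-frame transforms between optimized key frames.

    Each intermediate frame is initialized by geodesic interpolation
    between its bracketing key frames, then refined against its feature
    matches to those key frames.  Key-frame transforms are left unchanged.
    """
    keys = sorted(k for k in keyframe_set.keyframes if k - frame_offset < len(sequence))
    dense = {k: keyframe_set.transforms[k].copy() for k in keys}
    for a, b in zip(keys, keys[1:]):
        Ta, Tb = keyframe_set.transforms[a], keyframe_set.transforms[b]
        for i in range(a + 1, b):
            u = (i - a) / (b - a)
            T0 = geodesic_interpolate(Ta, Tb, u)
            anchors = []
            for key, T_anchor in ((a, Ta), (b, Tb)):
                ms = match_features(
                    features[i - frame_offset], features[key - frame_offset], max_ratio=max_ratio
                )
                if len(ms) >= 3:
                    anchors.append((T_anchor, ms))
            if not anchors:
                logger.warning("frame %d: no usable matches; keeping interpolated transform", i)
                dense[i] = T0
                continue
            dense[i], _, _ = _refine_frame(T0, anchors)
    # trailing frames beyond the last key frame: refine against that key frame
    last = keys[-1]
    T_last = keyframe_set.transforms[last]
    for i in range(last + 1, frame_offset + len(sequence)):
        ms = match_features(
            features[i - frame_offset], features[last - frame_offset], max_ratio=max_ratio
        )
        if len(ms) >= 3:
            dense[i], _, _ = _refine_frame(T_last, [(T_last, ms)])
        else:
            logger.warning("frame %d: no usable matches; carrying last key-frame transform", i)
            dense[i] = T_last.copy()
    return GlobalTransformSet(
        transforms=dense, keyframes=keys, video_offsets=dict(keyframe_set.video_offsets)
    )


# ---------------------------------------------------------------------------
# High-level drivers


def register_sequence(
    sequence: FrameSequence,
    n_keypoints: int = 1000,
    max_ratio: float = 0.8,
    ransac_threshold: float = 3.0,
    overlap_threshold: float = 0.5,
    max_gap: int = 100,
    min_keyframe_matches: int = 15,
) -> tuple[GlobalTransformSet, ObjectiveReport, list[FeatureSet], list[PairwiseTransform]]:
    """Full single-video registration: features, consecutive similarities,
    key frames, exhaustive key-frame matching, global optimization, and
    dense reintegration."""
    features = [detect_features(f, n_keypoints) for f in sequence.frames]
    chain = []
    for i in range(len(sequence) - 1):
        ms = match_features(features[i], features[i + 1], max_ratio=max_ratio)
        chain.append(estimate_pairwise_transform(ms, "similarity", ransac_threshold))
    if not chain:
        single = GlobalTransformSet(transforms={sequence[0].index: np.eye(3)}, keyframes=[0])
        return single, ObjectiveReport(0.0, 0.0, 0, True), features, []
    keys = select_keyframes(sequence, features, chain, overlap_threshold, max_gap)
    if len(keys) == 1:
        single = GlobalTransformSet(transforms={keys[0]: np.eye(3)}, keyframes=keys)
        dense = reintegrate_and_refine(sequence, single, features, max_ratio)
        return dense, ObjectiveReport(0.0, 0.0, 0, True), features, chain
    key_pairwise = []
    for a, b in zip(keys, keys[1:]):
        M = np.eye(3)
        for i in range(a, b):
            M = chain[i].matrix @ M
        inl = min(chain[i].inlier_count for i in range(a, b))
        err = float(np.mean([chain[i].mean_error for i in range(a, b)]))
        key_pairwise.append(PairwiseTransform((a, b), "similarity", M, inl, err))
    initial = chain_global_transforms(key_pairwise)
    matchsets = []
    for ai in range(len(keys)):
        for bi in range(ai + 1, len(keys)):
            ms = match_features(features[keys[ai]], features[keys[bi]], max_ratio=max_ratio)
            if len(ms) < min_keyframe_matches:
                continue
            try:
                estimate_pairwise_transform(ms, "similarity", ransac_threshold)
            except RegistrationError:
                continue
            if ms.inliers is not None:
                ms = MatchSet(ms.pair, ms.coords_a[ms.inliers], ms.coords_b[ms.inliers])
            if len(ms) >= min_keyframe_matches:
                matchsets.append(ms)
    optimized, report = optimize_global_transforms(matchsets, initial)
    dense = reintegrate_and_refine(sequence, optimized, features, max_ratio)
    return dense, report, features, chain


def register_sequences(
    sequences: list[FrameSequence],
    n_keypoints: int = 1000,
    max_ratio: float = 0.8,
    ransac_threshold: float = 3.0,
    overlap_threshold: float = 0.5,
    max_gap: int = 100,
    min_keyframe_matches: int = 15,
) -> tuple[GlobalTransformSet, ObjectiveReport]:
    """Multi-video registration in one shared coordinate system.

    Key frames from all videos enter a single exhaustive matching and
    joint optimization; cross-video chains are seeded by the best
    cross-video key-frame match.  Frame indices of video ``v`` are offset
    by the cumulative frame count of the preceding videos.
    """
    per_video = []
    offset = 0
    offsets = {}
    for seq in sequences:
        features = [detect_features(f, n_keypoints) for f in seq.frames]
        chain = []
        for i in range(len(seq) - 1):
            ms = match_features(features[i], features[i + 1], max_ratio=max_ratio)
            chain.append(estimate_pairwise_transform(ms, "similarity", ransac_threshold))
        keys = select_keyframes(seq, features, chain, overlap_threshold, max_gap)
        per_video.append((seq, features, chain, keys, offset))
        offsets[seq.source_id or str(len(offsets))] = offset
        offset += len(seq)

    # global key list with offsets, initial chains per video
    all_keys: list[int] = []
    all_features: dict[int, FeatureSet] = {}
    initial_mats: dict[int, np.ndarray] = {}
    prev_anchor: np.ndarray | None = None
    for seq, features, chain, keys, off in per_video:
        key_pairwise = []
        for a, b in zip(keys, keys[1:]):
            M = np.eye(3)
            for i in range(a, b):
                M = chain[i].matrix @ M
            key_pairwise.append(PairwiseTransform((a, b), "similarity", M))
        local = (
            chain_global_transforms(key_pairwise)
            if key_pairwise
            else GlobalTransformSet(transforms={keys[0]: np.eye(3)}, keyframes=keys)
        )
        # anchor this video to the already-placed ones via its best cross match
        anchor = np.eye(3)
        if prev_anchor is not None:
            best: tuple[int, PairwiseTransform] | None = None
            for gk in all_keys:
                for lk in keys:
                    ms = match_features(features[lk], all_features[gk], max_ratio=max_ratio)
                    if len(ms) < min_keyframe_matches:
                        continue
                    try:
                        pw = estimate_pairwise_transform(ms, "similarity", ransac_threshold)
                    except RegistrationError:
                        continue
                    if best is None or pw.inlier_count > best[1].inlier_count:
                        # maps local frame lk -> placed frame gk
                        best = (lk, PairwiseTransform((lk + off, gk), "similarity", pw.matrix))
            if best is None:
                raise RegistrationError("could not anchor video to the shared coordinate system")
            lk, pw = best
            anchor = initial_mats[pw.pair[1]] @ pw.matrix @ np.linalg.inv(local.transforms[lk])
        for k in keys:
            all_keys.append(k + off)
            all_features[k + off] = features[k]
            initial_mats[k + off] = anchor @ local.transforms[k]
        prev_anchor = anchor

    matchsets = []
    for ai in range(len(all_keys)):
        for bi in range(ai + 1, len(all_keys)):
            ka, kb = all_keys[ai], all_keys[bi]
            ms = match_features(all_features[ka], all_features[kb], max_ratio=max_ratio)
            ms = MatchSet((ka, kb), ms.coords_a, ms.coords_b)
            if len(ms) < min_keyframe_matches:
                continue
            try:
                estimate_pairwise_transform(ms, "similarity", ransac_threshold)
            except RegistrationError:
                continue
            if ms.inliers is not None:
                ms = MatchSet(ms.pair, ms.coords_a[ms.inliers], ms.coords_b[ms.inliers])
            if len(ms) >= min_keyframe_matches:
                matchsets.append(ms)
    initial = GlobalTransformSet(
        transforms=initial_mats, keyframes=all_keys, video_offsets=offsets
    )
    optimized, report = optimize_global_transforms(matchsets, initial)

    dense_all: dict[int, np.ndarray] = {}
    for seq, features, chain, keys, off in per_video:
        sub = GlobalTransformSet(
            transforms={k + off: optimized.transforms[k + off] for k in keys},
            keyframes=[k + off for k in keys],
            video_offsets=offsets,
        )
        dense = reintegrate_and_refine(seq, sub, features, max_ratio, frame_offset=off)
        dense_all.update(dense.transforms)
    return (
        GlobalTransformSet(transforms=dense_all, keyframes=all_keys, video_offsets=offsets),
        report,
    )
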