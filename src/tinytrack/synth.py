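"""Synthetic moving-camera scenes with a small moving target.

Produces ground-truthed fixtures for every pipeline stage: a static
high-texture background, a camera following a smooth similarity path
(``pan``/``loop``/``static``), and a small low-contrast elliptical target
performing a correlated random walk over the background.

Conventions: camera transform ``S_i`` maps frame coordinates to world
(background) coordinates; frames are rendered by sampling the background
at ``S_i @ p`` for each frame pixel ``p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter1d

from .transforms import apply_transform, similarity_from_params, translation_of
from .types import Frame, FrameSequence

__all__ = [
    "CameraScript",
    "TargetScript",
    "GroundTruth",
    "generate_background",
    "generate_camera_script",
    "generate_follow_script",
    "generate_target_script",
    "render_sequence",
    "default_scene",
    "loop_registration_problem",
]


@dataclass
class CameraScript:
    """Per-frame true similarities mapping frame -> world coordinates."""

    transforms: list[np.ndarray]
    kind: str = "pan"

    def __len__(self) -> int:
        return len(self.transforms)


@dataclass
class TargetScript:
    """Per-frame true target world positions plus appearance."""

    positions: np.ndarray            # (n, 2) world pixels
    headings: np.ndarray             # (n,) radians
    axes: tuple[float, float] = (4.0, 1.5)   # semi-axes along/across heading, px
    contrast: float = 0.08           # intensity deficit vs local background

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class GroundTruth:
    """Everything the downstream stages can be scored against."""

    camera: CameraScript
    target: TargetScript
    frame_positions: np.ndarray      # (n, 2) target in frame pixel coords
    world_positions: np.ndarray      # (n, 2) target in world pixel coords
    visible: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def generate_background(seed: int, size: tuple[int, int] = (512, 512), texture_scale: float = 6.0) -> np.ndarray:
    """Deterministic broadband texture: multiscale smoothed noise + blobs.

    Returns a (H, W) float image in [0, 1] with intensity std >= 0.05
    (a warning is emitted if the requested texture is too smooth).
    """
    W, H = int(size[0]), int(size[1])
    if W < 64 or H < 64:
        raise ValueError("background must be at least 64x64")
    rng = np.random.default_rng(seed)
    img = np.zeros((H, W))
    for octave, amp in ((1.0, 0.5), (2.5, 0.8), (6.0, 1.0)):
        img += amp * gaussian_filter(rng.standard_normal((H, W)), texture_scale / 6.0 * octave)
    # scattered dark/bright blobs to anchor distinctive features
    yy, xx = np.mgrid[0:H, 0:W]
    n_blobs = max(10, (W * H) // 6000)
    bx = rng.uniform(0, W, n_blobs)
    by = rng.uniform(0, H, n_blobs)
    br = rng.uniform(2.0, 6.0, n_blobs)
    bs = rng.choice([-1.0, 1.0], n_blobs) * rng.uniform(0.5, 1.0, n_blobs)
    bs *= 6.0 / texture_scale  # blob contrast fades with coarser texture
    for x0, y0, r, s in zip(bx, by, br, bs):
        lo_y, hi_y = max(0, int(y0 - 4 * r)), min(H, int(y0 + 4 * r) + 1)
        lo_x, hi_x = max(0, int(x0 - 4 * r)), min(W, int(x0 + 4 * r) + 1)
        d2 = (xx[lo_y:hi_y, lo_x:hi_x] - x0) ** 2 + (yy[lo_y:hi_y, lo_x:hi_x] - y0) ** 2
        img[lo_y:hi_y, lo_x:hi_x] += s * np.exp(-d2 / (2 * r * r))
    # fixed gain (calibrated at the default texture_scale) so contrast
    # genuinely decays as the texture coarsens
    img = np.clip(0.5 + (img - img.mean()) / 1.1, 0.0, 1.0)
    if img.std() < 0.05:
        warnings.warn("feature-poor background: intensity std below 0.05", stacklevel=2)
    return img


def generate_camera_script(
    kind: str,
    n_frames: int,
    *,
    start_xy: tuple[float, float] = (0.0, 0.0),
    max_translation: float = 2.0,
    max_rotation_deg: float = 0.3,
    max_scale_step: float = 0.002,
    loop_radius: float | None = None,
    seed: int = 0,
) -> CameraScript:
    """Generate a smooth per-frame camera path.

    ``pan`` drifts with low-pass-filtered random deltas bounded by the
    ``max_*`` arguments; ``loop`` traverses a closed circuit returning to
    its start; ``static`` holds the identity pose.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t0 = np.array(start_xy, dtype=float)
    if kind == "static":
        mats = [similarity_from_params(0.0, 0.0, *t0) for _ in range(n_frames)]
        return CameraScript(transforms=mats, kind="static")
    if kind == "pan":
        rng = np.random.default_rng(seed)
        smooth = lambda v: uniform_filter1d(v, size=max(3, n_frames // 20), mode="nearest")
        # biased drift so the camera actually travels, bounded per-frame
        direction = rng.uniform(0, 2 * np.pi)
        base = np.array([np.cos(direction), np.sin(direction)]) * 0.7 * max_translation
        dxy = base + 0.3 * max_translation * np.column_stack(
            [smooth(rng.standard_normal(n_frames - 1)), smooth(rng.standard_normal(n_frames - 1))]
        )
        norms = np.linalg.norm(dxy, axis=1, keepdims=True)
        over = norms[:, 0] > max_translation
        dxy[over] *= max_translation / norms[over]
        dth = np.deg2rad(max_rotation_deg) * np.clip(smooth(rng.standard_normal(n_frames - 1)), -1, 1)
        dls = max_scale_step * np.clip(smooth(rng.standard_normal(n_frames - 1)), -1, 1)
        theta = np.concatenate([[0.0], np.cumsum(dth)])
        log_s = np.concatenate([[0.0], np.cumsum(dls)])
        xy = np.vstack([t0, t0 + np.cumsum(dxy, axis=0)])
        mats = [similarity_from_params(theta[i], log_s[i], *xy[i]) for i in range(n_frames)]
        return CameraScript(transforms=mats, kind="pan")
    if kind == "loop":
        r = loop_radius if loop_radius is not None else max_translation * n_frames / (2 * np.pi)
        # closed circuit: t=0 and t=2*pi coincide exactly
        t = np.linspace(0.0, 2 * np.pi, n_frames)
        xy = np.column_stack([t0[0] + r * (np.cos(t) - 1.0), t0[1] + r * np.sin(t)])
        theta = np.deg2rad(max_rotation_deg) * n_frames / 8.0 * np.sin(t)
        log_s = max_scale_step * n_frames / 8.0 * np.sin(2 * t)
        mats = [similarity_from_params(theta[i], log_s[i], *xy[i]) for i in range(n_frames)]
        return CameraScript(transforms=mats, kind="loop")
    raise ValueError(f"unknown camera script kind: {kind!r}")


def generate_target_script(
    seed: int,
    n_frames: int,
    mean_step: float,
    turn_sd: float,
    extent: tuple[float, float, float, float],
    *,
    axes: tuple[float, float] = (4.0, 1.5),
    contrast: float = 0.08,
    start: tuple[float, float] | None = None,
    heading0: float | None = None,
) -> TargetScript:
    """Correlated random walk: heading += Normal(0, turn_sd deg), fixed step.

    Reflective at the ``extent`` boundary ``(x0, y0, x1, y1)``.
    """
    if mean_step <= 0:
        raise ValueError("mean_step must be positive")
    x0, y0, x1, y1 = map(float, extent)
    if min(x1 - x0, y1 - y0) < 10.0 * mean_step:
        raise ValueError("extent smaller than 10*mean_step")
    rng = np.random.default_rng(seed)
    pos = np.empty((n_frames, 2))
    hdg = np.empty(n_frames)
    pos[0] = start if start is not None else ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
    hdg[0] = heading0 if heading0 is not None else rng.uniform(0, 2 * np.pi)
    sd = np.deg2rad(turn_sd)
    for i in range(1, n_frames):
        h = hdg[i - 1] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        p = pos[i - 1] + mean_step * np.array([np.cos(h), np.sin(h)])
        # reflect off each violated boundary
        if p[0] < x0 or p[0] > x1:
            p[0] = 2 * (x0 if p[0] < x0 else x1) - p[0]
            h = np.pi - h
        if p[1] < y0 or p[1] > y1:
            p[1] = 2 * (y0 if p[1] < y0 else y1) - p[1]
            h = -h
        pos[i], hdg[i] = p, h
    return TargetScript(positions=pos, headings=hdg, axes=axes, contrast=contrast)


def generate_follow_script(
    target: TargetScript,
    frame_size: tuple[int, int],
    *,
    smooth_frames: int = 25,
    wobble: float = 6.0,
    max_rotation_deg: float = 0.2,
    max_scale_step: float = 0.001,
    seed: int = 0,
) -> CameraScript:
    """Camera that tracks the target, keeping it near the frame center.

    Emulates an operator following the animal: the camera translation is a
    low-passed copy of the target's world path (so it lags and overshoots
    naturally) plus smooth wobble, with slow rotation/scale drift.
    """
    n = len(target)
    if n < 2:
        raise ValueError("need at least 2 frames")
    w, h = frame_size
    rng = np.random.default_rng(seed)
    smooth = lambda v, size: uniform_filter1d(v, size=size, mode="nearest", axis=0)
    track = smooth(target.positions, max(3, smooth_frames))
    track = track + wobble * smooth(rng.standard_normal((n, 2)), max(5, n // 10))
    xy = track - np.array([w / 2.0, h / 2.0])
    dth = np.deg2rad(max_rotation_deg) * np.clip(
        smooth(rng.standard_normal(n - 1), max(3, n // 20)), -1, 1
    )
    dls = max_scale_step * np.clip(smooth(rng.standard_normal(n - 1), max(3, n // 20)), -1, 1)
    theta = np.concatenate([[0.0], np.cumsum(dth)])
    log_s = np.concatenate([[0.0], np.cumsum(dls)])
    mats = [similarity_from_params(theta[i], log_s[i], *xy[i]) for i in range(n)]
    return CameraScript(transforms=mats, kind="pan")


def _sample_background(background: np.ndarray, S: np.ndarray, shape: tuple[int, int]):
    """Sample the background through S (frame->world). Returns image + validity."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    world = apply_transform(S, pts)
    wx, wy = world[:, 0], world[:, 1]
    Hb, Wb = background.shape
    valid = (wx >= 0) & (wx <= Wb - 1) & (wy >= 0) & (wy <= Hb - 1)
    img = map_coordinates(background, [wy, wx], order=1, mode="constant", cval=0.5)
    img[~valid] = 0.5
    return img.reshape(h, w), valid.reshape(h, w), world


def render_sequence(
    background: np.ndarray,
    camera_script: CameraScript,
    target_script: TargetScript,
    *,
    frame_size: tuple[int, int] = (256, 192),
    noise_sd: float = 0.01,
    fps: float = 50.0,
    seed: int = 0,
    source_id: str = "synthetic",
) -> tuple[FrameSequence, GroundTruth]:
    """Render frames with the target composited as an anti-aliased ellipse.

    The target darkens the background by ``contrast`` inside its footprint,
    with ~1 px soft edges for honest sub-pixel localization error.
    """
    if len(camera_script) != len(target_script):
        raise ValueError("camera and target scripts must have equal length")
    n = len(camera_script)
    w, h = int(frame_size[0]), int(frame_size[1])
    rng = np.random.default_rng(seed)
    a, b = target_script.axes
    contrast = target_script.contrast
    frames = []
    frame_pos = np.empty((n, 2))
    visible = np.zeros(n, dtype=bool)
    for i in range(n):
        S = camera_script.transforms[i]
        img, valid, world = _sample_background(background, S, (h, w))
        q = target_script.positions[i]
        phi = target_script.headings[i]
        fp = apply_transform(np.linalg.inv(S), q)
        frame_pos[i] = fp
        visible[i] = (0 <= fp[0] < w) and (0 <= fp[1] < h)
        if contrast > 0:
            # composite in world coordinates over a local frame window
            wld = world.reshape(h, w, 2)
            margin = int(np.ceil(4 * max(a, b))) + 2
            cx, cy = int(round(fp[0])), int(round(fp[1]))
            lx, hx = max(0, cx - margin), min(w, cx + margin + 1)
            ly, hy = max(0, cy - margin), min(h, cy + margin + 1)
            if lx < hx and ly < hy:
                local = wld[ly:hy, lx:hx] - q
                u = local[..., 0] * np.cos(phi) + local[..., 1] * np.sin(phi)
                v = -local[..., 0] * np.sin(phi) + local[..., 1] * np.cos(phi)
                e = np.sqrt((u / a) ** 2 + (v / b) ** 2)
                d = (e - 1.0) * min(a, b)  # approx signed distance, px
                coverage = np.clip(0.5 - d, 0.0, 1.0)
                img[ly:hy, lx:hx] -= contrast * coverage
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames.append(Frame(index=i, image=np.clip(img, 0.0, 1.0)))
    if np.count_nonzero(~visible) > n / 2:
        warnings.warn("target rarely visible: outside the frame in >50% of frames", stacklevel=2)
    truth = GroundTruth(
        camera=camera_script,
        target=target_script,
        frame_positions=frame_pos,
        world_positions=target_script.positions.copy(),
        visible=visible,
    )
    return FrameSequence(frames=frames, fps=fps, source_id=source_id), truth


def default_scene(
    seed: int = 1,
    n_frames: int = 300,
    kind: str = "pan",
    *,
    frame_size: tuple[int, int] = (256, 192),
    background_size: tuple[int, int] = (512, 512),
    contrast: float = 0.08,
    noise_sd: float = 0.01,
    turn_sd: float = 8.0,
    mean_step: float = 1.2,
) -> tuple[FrameSequence, GroundTruth]:
    """The standard fixture: 512x512 background, 8x3 px target, moving camera.

    ``pan`` (the default) gives a target-following camera, matching the
    field situation the center-weighted unary assumes (operator keeps the
    animal near the frame center).  ``loop`` sends the camera around a
    closed circuit over an independently wandering target; ``static``
    holds the camera still.
    """
    w, h = frame_size
    W, H = background_size
    bg = generate_background(seed, size=background_size)
    margin = max(w, h) / 2.0 + 20.0
    if kind == "pan":
        tgt = generate_target_script(
            seed + 1, n_frames, mean_step=mean_step, turn_sd=turn_sd,
            extent=(margin, margin, W - margin, H - margin),
            axes=(4.0, 1.5), contrast=contrast, start=(W / 2.0, H / 2.0),
        )
        cam = generate_follow_script(tgt, frame_size, seed=seed)
    else:
        start = ((W - w) / 2.0, (H - h) / 2.0)
        if kind == "loop":
            cam = generate_camera_script(
                "loop", n_frames, start_xy=start, loop_radius=min(W - w, H - h) / 4.5,
                max_rotation_deg=0.02, max_scale_step=0.0002, seed=seed,
            )
        else:
            cam = generate_camera_script(kind, n_frames, start_xy=start, seed=seed)
        # keep the walk inside the union of camera views
        centers = np.array([translation_of(S) for S in cam.transforms])
        cx, cy = centers.mean(axis=0)
        half = min(w, h) / 3.0
        tgt = generate_target_script(
            seed + 1, n_frames, mean_step=mean_step, turn_sd=turn_sd,
            extent=(cx + w / 2 - half, cy + h / 2 - half, cx + w / 2 + half, cy + h / 2 + half),
            axes=(4.0, 1.5), contrast=contrast,
            start=(cx + w / 2.0, cy + h / 2.0),
        )
    return render_sequence(
        bg, cam, tgt, frame_size=frame_size, noise_sd=noise_sd, seed=seed + 2,
        source_id=f"synthetic-{kind}-{seed}",
    )


def loop_registration_problem(
    seed: int = 0,
    n_frames: int = 120,
    key_stride: int = 6,
    frame_size: tuple[int, int] = (256, 192),
    drift_rotation_deg: float = 0.15,
    drift_scale: float = 1.001,
    drift_translation: tuple[float, float] = (0.35, 0.2),
    match_noise: float = 0.05,
    points_per_pair: int = 40,
):
    """Ground-truthed key-frame registration problem on a camera loop with
    drift injected into the pairwise chain.

    Returns a dict with the true global transforms, a drifted initial
    ``GlobalTransformSet`` (each consecutive pairwise similarity multiplied
    by a fixed small bias, so the chained estimate accumulates drift), the
    key-frame ``MatchSet`` list (consecutive pairs plus the first-last
    loop-closure pair, built from shared world points), and the key/frame
    bookkeeping needed to measure loop-closure error.
    """
    from .register import GlobalTransformSet, MatchSet

    rng = np.random.default_rng(seed)
    w, h = frame_size
    cam = generate_camera_script(
        "loop", n_frames, start_xy=(0.0, 0.0), loop_radius=60.0,
        max_rotation_deg=0.02, max_scale_step=0.0002, seed=seed,
    )
    keys = list(range(0, n_frames, key_stride))
    if keys[-1] != n_frames - 1:
        keys.append(n_frames - 1)
    S = cam.transforms
    S0_inv = np.linalg.inv(S[keys[0]])
    true_transforms = {k: S0_inv @ S[k] for k in keys}

    bias = similarity_from_params(
        np.deg2rad(drift_rotation_deg), np.log(drift_scale), *drift_translation
    )
    drifted = {keys[0]: np.eye(3)}
    M = np.eye(3)
    for a, b in zip(keys, keys[1:]):
        pairwise_true = np.linalg.inv(S[b]) @ S[a]      # frame a -> frame b
        M = M @ np.linalg.inv(bias @ pairwise_true)
        drifted[b] = M.copy()

    pairs = list(zip(keys, keys[1:])) + [(keys[0], keys[-1])]
    matchsets = []
    for a, b in pairs:
        # world points visible in both views: sample around the midpoint pose
        mid = 0.5 * (translation_of(S[a]) + translation_of(S[b]))
        world = mid + np.array([w / 2.0, h / 2.0]) + rng.uniform(-40, 40, (points_per_pair, 2))
        fa = np.array([apply_transform(np.linalg.inv(S[a]), p) for p in world])
        fb = np.array([apply_transform(np.linalg.inv(S[b]), p) for p in world])
        fa += rng.normal(0, match_noise, fa.shape)
        fb += rng.normal(0, match_noise, fb.shape)
        matchsets.append(MatchSet((a, b), fa, fb))

    return {
        "camera": cam,
        "keys": keys,
        "frame_size": frame_size,
        "true_transforms": true_transforms,
        "initial": GlobalTransformSet(transforms=drifted, keyframes=keys),
        "matchsets": matchsets,
        "loop_pair": (keys[0], keys[-1]),
    }
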