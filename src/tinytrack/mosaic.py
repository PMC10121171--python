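"""Mosaic compositing and projection of detections into mosaic space."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .detect import DetectionPath
from .register import GlobalTransformSet
from .transforms import apply_transform
from .types import Frame, FrameSequence, Trajectory

__all__ = [
    "Mosaic",
    "compose_mosaic",
    "project_detections",
    "project_camera_centers",
    "calibrate_scale",
]


@dataclass
class Mosaic:
    image: np.ndarray
    origin: np.ndarray              # pure translation: global coords -> mosaic pixels
    counts: np.ndarray              # per-pixel contributing-frame count

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def compose_mosaic(
    keyframes: list[Frame],
    transforms: GlobalTransformSet,
    blend: str = "mean",
) -> Mosaic:
    """Warp key frames into the global system and composite them.

    The extent is the bounding box of all warped frame corners; the origin
    transform translates global coordinates so mosaic indices start at 0.
    """
    if not keyframes:
        raise ValueError("empty key-frame list")
    if blend not in ("mean", "overwrite"):
        raise ValueError(f"unknown blend mode {blend!r}")
    corners = []
    for f in keyframes:
        T = transforms[f.index]
        c = np.array([[0, 0], [f.width, 0], [f.width, f.height], [0, f.height]], dtype=float)
        corners.append(apply_transform(T, c))
    corners = np.vstack(corners)
    lo = np.floor(corners.min(axis=0))
    hi = np.ceil(corners.max(axis=0))
    origin = np.array([[1.0, 0.0, -lo[0]], [0.0, 1.0, -lo[1]], [0.0, 0.0, 1.0]])
    W, H = int(hi[0] - lo[0]), int(hi[1] - lo[1])
    acc = np.zeros((H, W))
    counts = np.zeros((H, W))
    for f in keyframes:
        A = origin @ transforms[f.index]          # frame -> mosaic pixels
        tf = ProjectiveTransform(np.linalg.inv(A))  # mosaic -> frame, for inverse warping
        img = warp(f.image, inverse_map=tf, output_shape=(H, W), order=1, mode="constant", cval=0.0)
        footprint = warp(np.ones_like(f.image), inverse_map=tf, output_shape=(H, W),
                         order=1, mode="constant", cval=0.0)
        hit = footprint > 0.999
        if blend == "mean":
            acc[hit] += img[hit]
            counts[hit] += 1.0
        else:
            acc[hit] = img[hit]
            counts[hit] += 1.0
    image = acc.copy()
    if blend == "mean":
        nz = counts > 0
        image[nz] = acc[nz] / counts[nz]
    return Mosaic(image=image, origin=origin, counts=counts)


def project_detections(
    path: DetectionPath,
    transforms: GlobalTransformSet,
    origin: np.ndarray | None = None,
    frame_indices: np.ndarray | None = None,
    source_id: str = "",
) -> Trajectory:
    """Project per-frame detections into mosaic pixels: ``p_hat = O T_i p``."""
    O = np.eye(3) if origin is None else np.asarray(origin, dtype=float)
    idx = (
        np.arange(len(path)) if frame_indices is None else np.asarray(frame_indices, dtype=int)
    )
    out = np.empty((len(path), 2))
    for n, i in enumerate(idx):
        if int(i) not in transforms.transforms:
            raise KeyError(f"no global transform for frame {int(i)}")
        out[n] = apply_transform(O @ transforms[int(i)], path.positions[n])
    return Trajectory(frames=idx, xy=out, source_id=source_id)


def project_camera_centers(
    sequence: FrameSequence,
    transforms: GlobalTransformSet,
    origin: np.ndarray | None = None,
) -> Trajectory:
    """Project frame centers (w/2, h/2) into mosaic pixels for all frames."""
    O = np.eye(3) if origin is None else np.asarray(origin, dtype=float)
    c = np.array([sequence.width / 2.0, sequence.height / 2.0])
    idx = np.array([f.index for f in sequence.frames])
    out = np.empty((len(idx), 2))
    for n, i in enumerate(idx):
        if int(i) not in transforms.transforms:
            raise KeyError(f"no global transform for frame {int(i)}")
        out[n] = apply_transform(O @ transforms[int(i)], c)
    return Trajectory(frames=idx, xy=out, source_id=sequence.source_id)


def calibrate_scale(point_a, point_b, known_length_cm: float) -> float:
    """Centimeters per mosaic pixel from one known-length point pair."""
    if known_length_cm <= 0:
        raise ValueError("known length must be positive")
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    dist = float(np.linalg.norm(a - b))
    if dist == 0.0:
        raise ValueError("calibration points are coincident")
    return known_length_cm / dist
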