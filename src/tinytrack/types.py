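"""Domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "FrameSequence",
    "AnnotationSet",
    "LabelTrack",
    "Trajectory",
]


@dataclass
class Frame:
    """A single grayscale video frame with intensities in [0, 1]."""

    index: int
    image: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.shape[0] < 1 or self.image.shape[1] < 1:
            raise ValueError("frame image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("frame intensities must be finite")
        if self.image.min() < 0.0 or self.image.max() > 1.0:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def center(self) -> np.ndarray:
        """Frame center (w/2, h/2), used for camera trajectories."""
        return np.array([self.width / 2.0, self.height / 2.0])


@dataclass
class FrameSequence:
    """Ordered frames of identical size from one video."""

    frames: list[Frame]
    fps: float = 50.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.frames:
            raise ValueError("no frames")
        shape = self.frames[0].image.shape
        for f in self.frames[1:]:
            if f.image.shape != shape:
                raise ValueError("dimension mismatch between frames")
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def width(self) -> int:
        return self.frames[0].width

    @property
    def height(self) -> int:
        return self.frames[0].height


@dataclass
class AnnotationSet:
    """Manual target-position corrections: frame index -> (x, y) pixels."""

    entries: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {int(k): (float(v[0]), float(v[1])) for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, frame: int) -> bool:
        return frame in self.entries

    def validate_bounds(self, width: int, height: int) -> None:
        for frame, (x, y) in self.entries.items():
            if not (0 <= x < width and 0 <= y < height):
                raise ValueError(f"annotation for frame {frame} outside [0,{width})x[0,{height})")


@dataclass
class LabelTrack:
    """Frame-interval labels, e.g. occlusion or behavioral state tags."""

    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for start, end, tag in self.intervals:
            start, end = int(start), int(end)
            if start > end:
                raise ValueError(f"label interval start {start} > end {end}")
            if not tag:
                raise ValueError("label tags must be nonempty")
            cleaned.append((start, end, str(tag)))
        self.intervals = cleaned

    def tagged(self, tag: str) -> list[tuple[int, int]]:
        """Maximal intervals carrying ``tag``, sorted by start frame."""
        return sorted((s, e) for s, e, t in self.intervals if t == tag)


@dataclass
class Trajectory:
    """Time-indexed 2D positions in frame or mosaic pixel space.

    ``xy_cm`` is populated once a real-world scale has been calibrated.
    """

    frames: np.ndarray
    xy: np.ndarray
    xy_cm: np.ndarray | None = None
    cm_per_pixel: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) == 0:
            raise ValueError("trajectory must be nonempty")
        if self.xy_cm is not None:
            self.xy_cm = np.asarray(self.xy_cm, dtype=float)
            if self.xy_cm.shape != self.xy.shape:
                raise ValueError("xy_cm must match xy shape")

    def __len__(self) -> int:
        return len(self.frames)

    def with_scale(self, cm_per_pixel: float) -> "Trajectory":
        """Return a copy carrying centimeter coordinates."""
        if cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")
        return Trajectory(
            frames=self.frames.copy(),
            xy=self.xy.copy(),
            xy_cm=self.xy * cm_per_pixel,
            cm_per_pixel=cm_per_pixel,
            source_id=self.source_id,
        )
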