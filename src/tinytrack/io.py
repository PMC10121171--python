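"""File I/O: frame sequences, annotations, labels, trajectories, transforms.

Tabular data is CSV (diff-able); transform sets are JSON arrays of 3x3
row-major matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import AnnotationSet, Frame, FrameSequence, LabelTrack, Trajectory

__all__ = [
    "load_frame_sequence",
    "write_frame_sequence",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_annotations",
    "write_annotations",
    "read_labels",
    "write_labels",
    "read_transforms",
    "write_transforms",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

# ITU-R BT.709 luma weights, matching skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def _to_gray01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    else:
        img = img.astype(float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return np.clip(img, 0.0, 1.0)


def load_frame_sequence(path: str | Path, fps: float = 50.0) -> FrameSequence:
    """Load a directory of lexicographically ordered image files.

    Images are converted to grayscale in [0, 1]; all frames must share
    one size.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise ValueError(f"no frames found in {path}")
    frames = []
    for i, f in enumerate(files):
        img = _to_gray01(iio.imread(f))
        if frames and img.shape != frames[0].image.shape:
            raise ValueError(
                f"dimension mismatch: {f.name} is {img.shape}, expected {frames[0].image.shape}"
            )
        frames.append(Frame(index=i, image=img))
    return FrameSequence(frames=frames, fps=fps, source_id=path.name)


def write_frame_sequence(seq: FrameSequence, path: str | Path, fmt: str = "png") -> list[Path]:
    """Write frames as 16-bit images named ``frame_<index:06d>.<fmt>``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for frame in seq.frames:
        out = path / f"frame_{frame.index:06d}.{fmt}"
        iio.imwrite(out, (np.clip(frame.image, 0, 1) * 65535).astype(np.uint16))
        written.append(out)
    return written


def write_trajectory_table(traj: Trajectory, path: str | Path) -> None:
    cols = {"frame": traj.frames, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}
    if traj.xy_cm is not None:
        cols["x_cm"] = traj.xy_cm[:, 0]
        cols["y_cm"] = traj.xy_cm[:, 1]
    df = pd.DataFrame(cols)
    df["source_id"] = traj.source_id
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectory_table(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"frame", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"trajectory table missing columns {sorted(required - set(df.columns))}")
    for col in ["frame", "x", "y", "x_cm", "y_cm"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise ValueError(f"non-numeric value in column '{col}' at row {row}")
        df[col] = coerced
    xy_cm = None
    if "x_cm" in df.columns and "y_cm" in df.columns:
        xy_cm = df[["x_cm", "y_cm"]].to_numpy(dtype=float)
    source = str(df["source_id"].iloc[0]) if "source_id" in df.columns and len(df) else ""
    if source == "nan":
        source = ""
    return Trajectory(
        frames=df["frame"].to_numpy(dtype=int),
        xy=df[["x", "y"]].to_numpy(dtype=float),
        xy_cm=xy_cm,
        source_id=source,
    )


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    rows = sorted(ann.entries.items())
    df = pd.DataFrame(
        {"frame": [f for f, _ in rows], "x": [p[0] for _, p in rows], "y": [p[1] for _, p in rows]}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_annotations(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path)
    if df["frame"].duplicated().any():
        dup = int(df["frame"][df["frame"].duplicated()].iloc[0])
        raise ValueError(f"duplicate annotation for frame {dup}")
    return AnnotationSet(
        entries={int(r.frame): (float(r.x), float(r.y)) for r in df.itertuples()}
    )


def write_labels(labels: LabelTrack, path: str | Path) -> None:
    df = pd.DataFrame(labels.intervals, columns=["start", "end", "tag"])
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> LabelTrack:
    df = pd.read_csv(path)
    return LabelTrack(
        intervals=[(int(r.start), int(r.end), str(r.tag)) for r in df.itertuples()]
    )


def write_transforms(transforms: dict[int, np.ndarray], path: str | Path, **meta) -> None:
    """Write frame-indexed 3x3 transforms (row-major) plus metadata to JSON."""
    payload = {
        "transforms": {str(k): np.asarray(v, dtype=float).tolist() for k, v in transforms.items()},
        **meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transforms(path: str | Path) -> tuple[dict[int, np.ndarray], dict]:
    payload = json.loads(Path(path).read_text())
    transforms = {int(k): np.array(v, dtype=float) for k, v in payload.pop("transforms").items()}
    for k, m in transforms.items():
        if m.shape != (3, 3):
            raise ValueError(f"transform for frame {k} is not 3x3")
    return transforms, payload
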