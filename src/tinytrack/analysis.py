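"""Trajectory post-processing: smoothing, kinematics, route similarity,
search metrics, null-model walks, and oscillation spectra.

Angular sign convention: positive angular velocity is a counterclockwise
turn in a conventional y-up frame, i.e. ``atan2(cross, dot)`` of successive
step vectors.  Per-step angles live in (-180, 180] degrees, so at ``fps``
the largest resolvable angular rate is ``180 * fps`` deg/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter, welch

from .types import LabelTrack, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "KinematicSeries",
    "SpectrumResult",
    "SearchIndexRecord",
    "smooth_trajectory",
    "compute_velocities",
    "smooth_velocities",
    "straightness",
    "sspd",
    "search_index",
    "directed_random_walk",
    "angular_velocity_spectrum",
    "max_resolvable_angular_rate",
    "smoothing_window_seconds",
]


@dataclass
class KinematicSeries:
    forward: np.ndarray             # (n-1,) speed, units/s
    angular: np.ndarray             # (n-2,) signed deg/s
    fps: float
    units: str = "px"
    degenerate_steps: np.ndarray | None = None  # flags zero-length steps


@dataclass
class SpectrumResult:
    frequencies: np.ndarray         # Hz, in [0, fps/2]
    magnitude: np.ndarray           # amplitude units
    peak_frequency: float
    peak_magnitude: float


@dataclass
class SearchIndexRecord:
    kind: str                       # "in" | "between"
    start: int
    end: int
    index: float
    infinite: bool = False


def max_resolvable_angular_rate(fps: float) -> float:
    """Largest unambiguous angular rate (deg/s): a 180-degree turn per frame."""
    return 180.0 * fps


def smoothing_window_seconds(window: int, fps: float) -> float:
    """Duration in seconds spanned by a smoothing window of ``window`` samples."""
    return window / fps


def smooth_trajectory(traj: Trajectory, polyorder: int = 3, window: int = 50) -> Trajectory:
    """Savitzky-Golay smoothing of both coordinates.

    An even window is widened by one sample (the filter needs an odd
    window); the adjustment is logged.  Endpoints use polynomial fits on
    the truncated window.  Too-short trajectories are returned unsmoothed
    with a warning.
    """
    if window % 2 == 0:
        logger.info("even smoothing window %d adjusted to %d", window, window + 1)
        window += 1
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if len(traj) < window:
        logger.warning("trajectory of %d points shorter than window %d; not smoothed", len(traj), window)
        return traj
    xy = np.column_stack(
        [savgol_filter(traj.xy[:, k], window, polyorder, mode="interp") for k in (0, 1)]
    )
    out = Trajectory(frames=traj.frames.copy(), xy=xy, source_id=traj.source_id)
    if traj.cm_per_pixel is not None:
        out = out.with_scale(traj.cm_per_pixel)
    return out


def compute_velocities(traj: Trajectory, fps: float | None = None, use_cm: bool = False) -> KinematicSeries:
    """Forward and signed angular velocities from successive positions.

    Forward speed is the step length times ``fps``; angular velocity is
    the signed angle between successive step vectors (in (-180, 180])
    times ``fps``.  Steps of zero length yield angular samples of 0,
    flagged in ``degenerate_steps``.
    """
    fps = float(fps if fps is not None else 50.0)
    xy = traj.xy_cm if (use_cm and traj.xy_cm is not None) else traj.xy
    units = "cm" if (use_cm and traj.xy_cm is not None) else "px"
    if len(xy) < 2:
        raise ValueError("need at least 2 points")
    steps = np.diff(xy, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    forward = norms * fps
    angular = np.empty(0)
    degenerate = np.zeros(max(len(xy) - 2, 0), dtype=bool)
    if len(xy) >= 3:
        u, v = steps[:-1], steps[1:]
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        dot = np.einsum("ij,ij->i", u, v)
        ang = np.degrees(np.arctan2(cross, dot))   # in (-180, 180]
        ang[ang == -180.0] = 180.0
        degenerate = (norms[:-1] == 0) | (norms[1:] == 0)
        ang[degenerate] = 0.0
        angular = ang * fps
    return KinematicSeries(forward=forward, angular=angular, fps=fps, units=units,
                           degenerate_steps=degenerate)


def _roll(series: np.ndarray, window: int, how: str) -> np.ndarray:
    s = pd.Series(series).rolling(window, center=True, min_periods=1)
    return (s.median() if how == "median" else s.mean()).to_numpy()


def smooth_velocities(series: KinematicSeries, median_window: int = 10, mean_window: int = 10) -> KinematicSeries:
    """Median filter (removes aberrant samples) then moving average.

    Centered windows; edges shrink the window rather than padding.
    """
    if median_window < 1 or mean_window < 1:
        raise ValueError("windows must be >= 1")

    def run(x: np.ndarray) -> np.ndarray:
        if len(x) == 0:
            return x
        return _roll(_roll(x, median_window, "median"), mean_window, "mean")

    return KinematicSeries(
        forward=run(series.forward), angular=run(series.angular), fps=series.fps,
        units=series.units, degenerate_steps=series.degenerate_steps,
    )


def straightness(traj: Trajectory | np.ndarray) -> float:
    """Total path length divided by the start-to-end chord length (>= 1)."""
    xy = traj.xy if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least 2 points")
    chord = float(np.linalg.norm(xy[-1] - xy[0]))
    if chord == 0.0:
        raise ValueError("start equals end; trim the trajectory before computing straightness")
    path = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    return path / chord


def _point_segment_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment of polyline ``poly``."""
    a, b = poly[:-1], poly[1:]                    # (m, 2)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)         # (m,)
    ap = points[:, None, :] - a[None, :, :]       # (n, m, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nmj,mj->nm", ap, ab) / denom
    t = np.nan_to_num(t, nan=0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def sspd(A: Trajectory | np.ndarray, B: Trajectory | np.ndarray) -> float:
    """Symmetrized segment-path distance between two trajectories.

    ``SPD(A, B)`` is the mean over points of A of the distance to the
    nearest segment of B; the symmetrized value averages both directions.
    Zero for identical inputs; symmetric; not a metric.
    """
    xa = A.xy if isinstance(A, Trajectory) else np.asarray(A, dtype=float)
    xb = B.xy if isinstance(B, Trajectory) else np.asarray(B, dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("trajectories need at least 2 points")
    spd_ab = float(np.mean(_point_segment_distances(xa, xb)))
    spd_ba = float(np.mean(_point_segment_distances(xb, xa)))
    return 0.5 * (spd_ab + spd_ba)


def search_index(
    traj: Trajectory, labels: LabelTrack, tag: str, fps: float | None = None, use_cm: bool = False
) -> list[SearchIndexRecord]:
    """Dwell time divided by entry-to-exit distance, per tagged interval
    and per gap between consecutive tagged intervals."""
    fps = float(fps if fps is not None else 50.0)
    xy = traj.xy_cm if (use_cm and traj.xy_cm is not None) else traj.xy
    pos = {int(f): xy[n] for n, f in enumerate(traj.frames)}
    intervals = labels.tagged(tag)
    records = []

    def make(kind: str, f0: int, f1: int) -> SearchIndexRecord:
        if f0 not in pos or f1 not in pos:
            raise ValueError(f"label boundary frame {f0 if f0 not in pos else f1} outside trajectory")
        duration = (f1 - f0) / fps
        dist = float(np.linalg.norm(pos[f1] - pos[f0]))
        if dist == 0.0:
            return SearchIndexRecord(kind, f0, f1, float("inf"), infinite=True)
        return SearchIndexRecord(kind, f0, f1, duration / dist)

    for s, e in intervals:
        records.append(make("in", s, e))
    for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
        records.append(make("between", e0, s1))
    return records


def directed_random_walk(
    start,
    goal,
    mean_step: float,
    target_straightness: float = 1.0,
    tol: float = 0.05,
    seed: int = 0,
    max_tries: int = 60,
    max_steps: int | None = None,
) -> Trajectory:
    """Goal-directed random walk rejection-matched to a target straightness.

    Each step has length ``mean_step`` and a heading drawn from a wrapped
    normal centered on the current bearing to the goal.  Whole walks are
    resampled, bisecting the heading dispersion, until the straightness
    lands within ``tol`` of the target.  Deterministic given ``seed``.
    """
    if target_straightness < 1.0:
        raise ValueError("target straightness must be >= 1")
    if mean_step <= 0:
        raise ValueError("mean_step must be positive")
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    direct = float(np.linalg.norm(goal - start))
    if direct < mean_step:
        raise ValueError("goal closer than one step from start")
    cap = max_steps if max_steps is not None else int(50 * direct / mean_step) + 10

    def sample(dispersion: float, attempt: int) -> np.ndarray:
        rng = np.random.default_rng([seed, attempt])
        pts = [start.copy()]
        p = start.copy()
        for _ in range(cap):
            bearing = np.arctan2(goal[1] - p[1], goal[0] - p[0])
            h = bearing + (rng.normal(0.0, dispersion) if dispersion > 0 else 0.0)
            p = p + mean_step * np.array([np.cos(h), np.sin(h)])
            pts.append(p.copy())
            if np.linalg.norm(goal - p) <= mean_step:
                break
        return np.array(pts)

    lo, hi = 0.0, 1.5
    best: tuple[float, np.ndarray] | None = None
    for attempt in range(max_tries):
        dispersion = 0.0 if target_straightness <= 1.0 + 1e-12 else 0.5 * (lo + hi)
        walk = sample(dispersion, attempt)
        s = straightness(walk)
        gap = abs(s - target_straightness)
        if best is None or gap < best[0]:
            best = (gap, s)
        if gap <= tol:
            return Trajectory(frames=np.arange(len(walk)), xy=walk, source_id="directed-walk")
        if s > target_straightness:
            hi = dispersion
        else:
            lo = dispersion
            if hi - lo < 1e-6:
                hi = min(hi * 2.0, np.pi)
    raise RuntimeError(
        f"no walk within tol={tol} of straightness {target_straightness} after "
        f"{max_tries} tries; closest achieved straightness was {best[1]:.4f}"
    )


def angular_velocity_spectrum(
    series: KinematicSeries,
    segment_length_s: float = 10.0,
    band: tuple[float, float] = (0.2, 5.0),
) -> SpectrumResult:
    """Amplitude spectrum of the mean-removed angular velocity.

    Segment-averaged periodogram (Hann window, 50% overlap).  The peak is
    reported over ``band`` (Hz).
    """
    x = np.asarray(series.angular, dtype=float)
    fs = series.fps
    nperseg = int(round(segment_length_s * fs))
    if len(x) < 2 * nperseg:
        raise ValueError("series shorter than two spectrum segments")
    f, pxx = welch(x - x.mean(), fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    mag = np.sqrt(pxx)
    in_band = (f >= band[0]) & (f <= band[1])
    if not in_band.any():
        raise ValueError("band contains no frequency bins")
    k = np.flatnonzero(in_band)[np.argmax(mag[in_band])]
    return SpectrumResult(
        frequencies=f, magnitude=mag, peak_frequency=float(f[k]), peak_magnitude=float(mag[k])
    )
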