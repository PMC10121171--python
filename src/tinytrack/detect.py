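"""Camera-motion-compensated motion residuals and globally optimal chain
max-sum inference of the target path.

The per-frame state space is the unary grid (pixel resolution downsampled
by factor ``d``).  The quadratic pairwise term makes the max-sum message
update separable: each message is an exact 1D quadratic max-convolution
along rows then columns, so the result equals naive dynamic programming
at any grid size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from skimage.transform import ProjectiveTransform, warp

from .register import PairwiseTransform
from .types import AnnotationSet, Frame

logger = logging.getLogger(__name__)

__all__ = [
    "UnaryField",
    "GaussianWeight",
    "MotionModel",
    "DetectionPath",
    "compensate_and_diff",
    "compute_unary",
    "pairwise_log_potential",
    "infer_path",
    "chunked_inference",
    "build_unaries",
]

_CLAMP = -1e15  # effective -inf for annotation clamping
_LOG_FLOOR = 1e-12


@dataclass
class UnaryField:
    """Nonnegative score grid over candidate positions for one frame."""

    frame_index: int
    grid: np.ndarray                # (ceil(h/d), ceil(w/d))
    d: int = 1
    mask: np.ndarray | None = None  # False where the warped neighbor had no data

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.grid)) or self.grid.min() < 0:
            raise ValueError("unary scores must be finite and nonnegative")
        if self.mask is None:
            self.mask = np.ones_like(self.grid, dtype=bool)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Full-resolution (x, y) coordinates of each grid cell center."""
        rows = np.arange(self.grid.shape[0]) * self.d + (self.d - 1) / 2.0
        cols = np.arange(self.grid.shape[1]) * self.d + (self.d - 1) / 2.0
        return cols, rows


@dataclass
class GaussianWeight:
    """Centered Gaussian weighting of the motion residuals."""

    mean: tuple[float, float]
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class MotionModel:
    """Gaussian motion prior linking consecutive detections."""

    sigma_p: float = 10.0           # full-resolution pixels

    def __post_init__(self) -> None:
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")


@dataclass
class DetectionPath:
    positions: np.ndarray           # (T, 2) full-resolution (x, y)
    unary_scores: np.ndarray        # (T,) unary value at the chosen cell
    energy: float
    cells: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __len__(self) -> int:
        return len(self.positions)


def compensate_and_diff(
    frame: Frame, frame_next: Frame, H: PairwiseTransform, d: int = 1,
    blur_sigma: float = 1.0, pool_sigma: float = 4.0,
) -> UnaryField:
    """Warp the next frame into this frame's coordinates and take |diff|.

    ``H`` maps this frame's coordinates into the next frame's coordinates
    (the usual pairwise convention); pixels that sample outside the next
    frame are masked.  Both images are low-pass filtered (``blur_sigma``)
    before differencing: resampling residuals of textured background are
    high-frequency and shrink far more than a multi-pixel target's
    footprint.  The absolute difference is box-averaged onto the
    ``d``-downsampled grid; cells with under half their pixels valid are
    masked and carry score zero.
    """
    M = np.asarray(H.matrix, dtype=float)
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("non-invertible pairwise transform")
    h, w = frame.image.shape
    tf = ProjectiveTransform(M)
    ref = frame.image
    src = frame_next.image
    if blur_sigma > 0:
        # pre-blur so the interpolant is smooth where it is sampled
        ref = gaussian_filter(ref, blur_sigma)
        src = gaussian_filter(src, blur_sigma)
    order = 3 if blur_sigma > 0 else 1
    warped = warp(src, inverse_map=tf, output_shape=(h, w),
                  order=order, mode="constant", cval=0.0)
    footprint = warp(np.ones((h, w)), inverse_map=tf, output_shape=(h, w),
                     order=1, mode="constant", cval=0.0)
    valid = footprint > 0.999
    if blur_sigma > 0:
        # cubic support + blur bleed the border fill inward; shrink the mask
        valid = binary_erosion(valid, iterations=int(np.ceil(3 * blur_sigma)) + 2, border_value=0)
    diff = np.abs(warped - ref)
    diff[~valid] = 0.0
    if pool_sigma > 0:
        # pool residual mass at the target's spatial scale: a small target's
        # crescents integrate coherently while pixel noise averages out
        diff = gaussian_filter(diff, pool_sigma)
        diff[~valid] = 0.0
    gh, gw = -(-h // d), -(-w // d)
    pad_h, pad_w = gh * d - h, gw * d - w
    diff_p = np.pad(diff, ((0, pad_h), (0, pad_w)))
    valid_p = np.pad(valid, ((0, pad_h), (0, pad_w)))
    diff_cells = diff_p.reshape(gh, d, gw, d).mean(axis=(1, 3))
    frac_valid = valid_p.reshape(gh, d, gw, d).mean(axis=(1, 3))
    mask = frac_valid >= 0.5
    diff_cells[~mask] = 0.0
    return UnaryField(frame_index=frame.index, grid=diff_cells, d=d, mask=mask)


def compute_unary(D: UnaryField, gw: GaussianWeight) -> UnaryField:
    """Weight residuals by the centered Gaussian and normalize to sum 1.

    An all-zero residual field degenerates to a uniform distribution over
    unmasked cells, so inference falls back on the motion prior.
    """
    xs, ys = D.cell_centers()
    gx = np.exp(-((xs - gw.mean[0]) ** 2) / (2.0 * gw.sigma**2))
    gy = np.exp(-((ys - gw.mean[1]) ** 2) / (2.0 * gw.sigma**2))
    phi = D.grid * np.outer(gy, gx)
    phi[~D.mask] = 0.0
    total = phi.sum()
    if total <= 0.0:
        n_valid = int(D.mask.sum())
        if n_valid == 0:
            phi = np.full_like(phi, 1.0 / phi.size)
        else:
            phi = np.where(D.mask, 1.0 / n_valid, 0.0)
    else:
        phi = phi / total
    return UnaryField(frame_index=D.frame_index, grid=phi, d=D.d, mask=D.mask.copy())


def pairwise_log_potential(p, q, mm: MotionModel) -> float:
    """Log motion prior, up to a constant shared by all position pairs."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(-np.sum((q - p) ** 2) / (2.0 * mm.sigma_p**2))


def _max_convolve_1d(G: np.ndarray, weight: float, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1D quadratic max-convolution along ``axis``.

    Returns (values, argmax) with ``values[q] = max_p G[p] - weight*(q-p)^2``
    vectorized over the other axis; ties take the smallest ``p``.
    """
    if axis == 1:
        vals, arg = _max_convolve_1d(G.T, weight, 0)
        return vals.T, arg.T
    n = G.shape[0]
    idx = np.arange(n)
    penalty = -weight * (idx[:, None] - idx[None, :]) ** 2   # [q, p]
    scores = penalty[:, :, None] + G[None, :, :]             # [q, p, other]
    arg = scores.argmax(axis=1)
    vals = np.take_along_axis(scores, arg[:, None, :], axis=1)[:, 0, :]
    return vals, arg


def _annotation_cell(ann_xy: tuple[float, float], d: int, shape: tuple[int, int]) -> tuple[int, int]:
    col = int(ann_xy[0] // d)
    row = int(ann_xy[1] // d)
    if not (0 <= row < shape[0] and 0 <= col < shape[1]):
        raise ValueError(f"annotation {ann_xy} outside the unary grid")
    return row, col


def _subcell_offset(grid: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Quadratic fit of the 3x3 neighborhood; offset clipped to half a cell."""
    if not (0 < r < grid.shape[0] - 1 and 0 < c < grid.shape[1] - 1):
        return 0.0, 0.0
    dx = 0.5 * (grid[r, c + 1] - grid[r, c - 1])
    dxx = grid[r, c + 1] - 2 * grid[r, c] + grid[r, c - 1]
    dy = 0.5 * (grid[r + 1, c] - grid[r - 1, c])
    dyy = grid[r + 1, c] - 2 * grid[r, c] + grid[r - 1, c]
    ox = -dx / dxx if dxx < 0 else 0.0
    oy = -dy / dyy if dyy < 0 else 0.0
    return float(np.clip(ox, -0.5, 0.5)), float(np.clip(oy, -0.5, 0.5))


def infer_path(
    unaries: list[UnaryField],
    mm: MotionModel,
    annotations: AnnotationSet | None = None,
    subcell: bool = True,
) -> DetectionPath:
    """Exact MAP path over the chain by forward max-sum.

    Maximizes ``sum_i log(phi_i(p_i)) + sum_i logpsi(p_i, p_{i+1})`` over
    all per-frame grid cells.  Annotated frames are clamped by forcing all
    other cells to an effective -inf before inference, so one annotation
    can correct neighboring frames through the messages.  Ties break
    toward the smallest row-major cell index.
    """
    if not unaries:
        raise ValueError("empty unary list")
    shape = unaries[0].grid.shape
    d = unaries[0].d
    for u in unaries:
        if u.grid.shape != shape or u.d != d:
            raise ValueError("all unaries must share grid geometry")
    T = len(unaries)
    # grid-cell spacing is d full-resolution pixels
    weight = d * d / (2.0 * mm.sigma_p**2)

    def log_unary(u: UnaryField) -> np.ndarray:
        L = np.log(np.maximum(u.grid, _LOG_FLOOR))
        if annotations is not None and u.frame_index in annotations:
            r, c = _annotation_cell(annotations.entries[u.frame_index], d, shape)
            clamped = np.full_like(L, _CLAMP)
            clamped[r, c] = L[r, c]
            return clamped
        return L

    M = log_unary(unaries[0])
    back_rows: list[np.ndarray] = []
    back_cols: list[np.ndarray] = []
    for t in range(1, T):
        v_rows, arg_rows = _max_convolve_1d(M, weight, axis=0)
        v_full, arg_cols = _max_convolve_1d(v_rows, weight, axis=1)
        back_rows.append(arg_rows)
        back_cols.append(arg_cols)
        M = v_full + log_unary(unaries[t])

    flat = int(M.argmax())  # first occurrence = smallest row-major index
    r, c = divmod(flat, shape[1])
    cells = np.empty((T, 2), dtype=int)
    cells[-1] = (r, c)
    for t in range(T - 2, -1, -1):
        c_prev = int(back_cols[t][r, c])
        r_prev = int(back_rows[t][r, c_prev])
        cells[t] = (r_prev, c_prev)
        r, c = r_prev, c_prev

    energy = 0.0
    positions = np.empty((T, 2))
    scores = np.empty(T)
    logs = [log_unary(u) for u in unaries]
    for t in range(T):
        rt, ct = cells[t]
        energy += logs[t][rt, ct]
        scores[t] = unaries[t].grid[rt, ct]
        ox = oy = 0.0
        if subcell and d > 1 and not (annotations is not None and unaries[t].frame_index in annotations):
            ox, oy = _subcell_offset(unaries[t].grid, rt, ct)
        positions[t] = ((ct + ox) * d + (d - 1) / 2.0, (rt + oy) * d + (d - 1) / 2.0)
        if annotations is not None and unaries[t].frame_index in annotations:
            positions[t] = annotations.entries[unaries[t].frame_index]
    for t in range(T - 1):
        dr = (cells[t + 1] - cells[t]).astype(float)
        energy += -weight * float(dr @ dr)
    return DetectionPath(positions=positions, unary_scores=scores, energy=float(energy), cells=cells)


def chunked_inference(
    unaries: list[UnaryField],
    mm: MotionModel,
    annotations: AnnotationSet | None = None,
    chunk_size: int = 50,
    overlap: int = 10,
    subcell: bool = True,
) -> DetectionPath:
    """Solve overlapping chunks independently and stitch at agreement points.

    Chunk results do not depend on execution order; within each overlap the
    stitch point is the first frame where both chunk paths choose the same
    cell, or the overlap midpoint (with a logged discrepancy) if they never
    agree.
    """
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    if chunk_size <= 2 * overlap:
        raise ValueError("chunk_size must exceed 2*overlap")
    T = len(unaries)
    if chunk_size >= T:
        return infer_path(unaries, mm, annotations, subcell=subcell)
    starts = list(range(0, T - overlap, chunk_size - overlap))
    if starts[-1] + chunk_size < T:
        starts.append(T - chunk_size)
    solutions = {}
    for s in starts:
        e = min(s + chunk_size, T)
        sub_ann = None
        if annotations is not None:
            idx = {u.frame_index for u in unaries[s:e]}
            sub_ann = AnnotationSet(
                entries={k: v for k, v in annotations.entries.items() if k in idx}
            )
        solutions[s] = infer_path(unaries[s:e], mm, sub_ann, subcell=subcell)

    positions = np.empty((T, 2))
    scores = np.empty(T)
    cells = np.empty((T, 2), dtype=int)
    cursor_chunk = starts[0]
    cursor_sol = solutions[cursor_chunk]
    take_from = 0
    for nxt in starts[1:]:
        sol_next = solutions[nxt]
        ov_lo, ov_hi = nxt, min(cursor_chunk + chunk_size, T)
        cut = None
        for f in range(ov_lo, ov_hi):
            if np.array_equal(cursor_sol.cells[f - cursor_chunk], sol_next.cells[f - nxt]):
                cut = f
                break
        if cut is None:
            cut = (ov_lo + ov_hi) // 2
            logger.warning("chunk paths disagree across overlap [%d, %d); cutting at %d", ov_lo, ov_hi, cut)
        sl = slice(take_from, cut)
        rel = slice(take_from - cursor_chunk, cut - cursor_chunk)
        positions[sl], scores[sl], cells[sl] = (
            cursor_sol.positions[rel], cursor_sol.unary_scores[rel], cursor_sol.cells[rel],
        )
        take_from, cursor_chunk, cursor_sol = cut, nxt, sol_next
    sl = slice(take_from, T)
    rel = slice(take_from - cursor_chunk, T - cursor_chunk)
    positions[sl], scores[sl], cells[sl] = (
        cursor_sol.positions[rel], cursor_sol.unary_scores[rel], cursor_sol.cells[rel],
    )

    weight = unaries[0].d ** 2 / (2.0 * mm.sigma_p**2)
    energy = 0.0
    for t, u in enumerate(unaries):
        L = float(np.log(max(u.grid[cells[t, 0], cells[t, 1]], _LOG_FLOOR)))
        energy += L
    for t in range(T - 1):
        dr = (cells[t + 1] - cells[t]).astype(float)
        energy += -weight * float(dr @ dr)
    return DetectionPath(positions=positions, unary_scores=scores, energy=float(energy), cells=cells)


def build_unaries(
    sequence,
    homographies: list[PairwiseTransform],
    d: int = 2,
    sigma_u_frac: float = 0.25,
    mean: tuple[float, float] | None = None,
) -> list[UnaryField]:
    """Unaries for a whole sequence.

    Interior frames average the compensated residuals against both
    neighbors: the forward residual is centered between the target's
    frame-i and frame-i+1 footprints, the backward residual between
    frames i-1 and i, so the average is centered on the frame-i position
    (removing the half-step lag of one-sided differencing) and halves
    uncorrelated noise.  End frames have a single neighbor and use its
    residual alone.
    """
    n = len(sequence)
    if len(homographies) != n - 1:
        raise ValueError("need n-1 pairwise homographies")
    w, h = sequence.width, sequence.height
    gw = GaussianWeight(
        mean=mean if mean is not None else (w / 2.0, h / 2.0),
        sigma=sigma_u_frac * min(w, h),
    )
    if n == 1:
        flat = UnaryField(
            frame_index=sequence[0].index,
            grid=np.full((-(-h // d), -(-w // d)), 1.0),
            d=d,
        )
        return [compute_unary(flat, gw)]
    unaries = []
    for i in range(n):
        fwd = bwd = None
        if i < n - 1:
            fwd = compensate_and_diff(sequence[i], sequence[i + 1], homographies[i], d=d)
        if i > 0:
            bwd = compensate_and_diff(sequence[i], sequence[i - 1], homographies[i - 1].inverse(), d=d)
        if fwd is not None and bwd is not None:
            both = fwd.mask & bwd.mask
            grid = np.where(both, 0.5 * (fwd.grid + bwd.grid),
                            np.where(fwd.mask, fwd.grid, bwd.grid))
            mask = fwd.mask | bwd.mask
            grid = np.where(mask, grid, 0.0)
            D = UnaryField(frame_index=sequence[i].index, grid=grid, d=d, mask=mask)
        else:
            D = fwd if fwd is not None else bwd
        unaries.append(compute_unary(D, gw))
    return unaries
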