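"""Similarity-transform utilities.

All transforms are 3x3 homogeneous matrices acting on column vectors
``p' = M @ (x, y, 1)``, with 0-based pixel coordinates, x rightward and
y downward.  A similarity has the form::

    [[s*cos(t), -s*sin(t), tx],
     [s*sin(t),  s*cos(t), ty],
     [0,         0,         1]]

with scale ``s > 0``.  Parameter vectors are ``(theta, log_s, tx, ty)``,
the parameterization used by the global mosaic optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "similarity_from_params",
    "similarity_params",
    "is_similarity",
    "apply_transform",
    "translation_of",
    "geodesic_interpolate",
    "wrap_angle",
]


def similarity_from_params(theta: float, log_s: float, tx: float, ty: float) -> np.ndarray:
    """Build a similarity matrix from ``(theta, log_s, tx, ty)``."""
    s = float(np.exp(log_s))
    c, si = s * np.cos(theta), s * np.sin(theta)
    return np.array([[c, -si, tx], [si, c, ty], [0.0, 0.0, 1.0]])


def similarity_params(M: np.ndarray) -> tuple[float, float, float, float]:
    """Decompose a similarity matrix into ``(theta, log_s, tx, ty)``.

    Raises
    ------
    ValueError
        If ``M`` is not a valid similarity (within 1e-6).
    """
    M = np.asarray(M, dtype=float)
    if not is_similarity(M, tol=1e-6):
        raise ValueError("matrix is not a similarity transform")
    a, b = M[0, 0], M[1, 0]
    s = float(np.hypot(a, b))
    theta = float(np.arctan2(b, a))
    return theta, float(np.log(s)), float(M[0, 2]), float(M[1, 2])


def is_similarity(M: np.ndarray, tol: float = 1e-9) -> bool:
    """Check the parametric similarity form to within ``tol``."""
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or not np.all(np.isfinite(M)):
        return False
    if abs(M[2, 0]) > tol or abs(M[2, 1]) > tol or abs(M[2, 2] - 1.0) > tol:
        return False
    s = np.hypot(M[0, 0], M[1, 0])
    if not s > tol:
        return False
    scale = max(1.0, s)
    return (
        abs(M[0, 0] - M[1, 1]) <= tol * scale
        and abs(M[0, 1] + M[1, 0]) <= tol * scale
    )


def apply_transform(M: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homogeneous transform to (n, 2) or (2,) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = np.column_stack([pts, np.ones(len(pts))])
    out = h @ np.asarray(M, dtype=float).T
    with np.errstate(invalid="ignore"):
        out = out[:, :2] / out[:, 2:3]
    return out[0] if np.asarray(points).ndim == 1 else out


def translation_of(M: np.ndarray) -> np.ndarray:
    """Translation component ``(tx, ty)`` of a homogeneous transform."""
    return np.asarray(M, dtype=float)[:2, 2].copy()


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) in radians to (-pi, pi]."""
    out = -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if np.isscalar(a) else out


def geodesic_interpolate(T_a: np.ndarray, T_b: np.ndarray, u: float) -> np.ndarray:
    """Interpolate between two similarities along the group geodesic.

    Angle is interpolated linearly along the shortest arc, scale linearly
    in log-space, translation linearly.  ``u=0`` returns ``T_a`` exactly,
    ``u=1`` returns ``T_b`` exactly.
    """
    if u == 0.0:
        return np.asarray(T_a, dtype=float).copy()
    if u == 1.0:
        return np.asarray(T_b, dtype=float).copy()
    ta, la, xa, ya = similarity_params(T_a)
    tb, lb, xb, yb = similarity_params(T_b)
    dt = wrap_angle(tb - ta)
    return similarity_from_params(
        ta + u * dt,
        (1.0 - u) * la + u * lb,
        (1.0 - u) * xa + u * xb,
        (1.0 - u) * ya + u * yb,
    )
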