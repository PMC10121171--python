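import numpy as np
import pytest

from tinytrack.detect import MotionModel, UnaryField
from tinytrack.register import (
    detect_features,
    estimate_pairwise_transform,
    match_features,
)
from tinytrack.synth import default_scene, generate_background

_CLAMP = -1e15


@pytest.fixture(scope="session")
def background():
    return generate_background(seed=1, size=(512, 512))


@pytest.fixture(scope="session")
def small_scene():
    """40-frame follow-camera scene with target, shared across modules."""
    return default_scene(seed=1, n_frames=40)


@pytest.fixture(scope="session")
def small_scene_registered(small_scene):
    """Features, consecutive similarity chain and homographies for the scene."""
    seq, truth = small_scene
    feats = [detect_features(f) for f in seq.frames]
    homs = []
    sims = []
    for i in range(len(seq) - 1):
        ms = match_features(feats[i], feats[i + 1])
        homs.append(estimate_pairwise_transform(ms, "homography"))
        ms2 = match_features(feats[i], feats[i + 1])
        sims.append(estimate_pairwise_transform(ms2, "similarity"))
    return feats, sims, homs


def random_unaries(rng, T, shape, d=1):
    """Random strictly positive unary fields (normalized)."""
    out = []
    for t in range(T):
        g = rng.random(shape) + 1e-3
        out.append(UnaryField(frame_index=t, grid=g / g.sum(), d=d))
    return out


def brute_force_map(unaries, mm: MotionModel, annotations=None):
    """Exhaustive enumeration over all grid^T paths (independent oracle).

    Builds the full energy tensor over state tuples; argmax takes the
    first (row-major lexicographic) maximizer.  Returns (cells, energy).
    """
    shape = unaries[0].grid.shape
    d = unaries[0].d
    S = shape[0] * shape[1]
    weight = d * d / (2.0 * mm.sigma_p**2)
    rows, cols = np.divmod(np.arange(S), shape[1])
    pair = -weight * (
        (rows[:, None] - rows[None, :]) ** 2 + (cols[:, None] - cols[None, :]) ** 2
    )

    def log_unary(u):
        L = np.log(np.maximum(u.grid, 1e-12)).ravel()
        if annotations is not None and u.frame_index in annotations:
            x, y = annotations.entries[u.frame_index]
            cell = int(y // d) * shape[1] + int(x // d)
            out = np.full(S, _CLAMP)
            out[cell] = L[cell]
            return out
        return L

    E = log_unary(unaries[0])
    for u in unaries[1:]:
        # E over states (s_1..s_t); append axis for s_{t+1}
        E = E[..., :, None] + pair[(np.newaxis,) * (E.ndim - 1)] + log_unary(u)
    flat = int(np.argmax(E))
    states = []
    for _ in range(len(unaries)):
        states.append(flat % S)
        flat //= S
    states = states[::-1]
    cells = np.array([(s // shape[1], s % shape[1]) for s in states])
    energy = float(E.max())
    return cells, energy
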