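"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own dynamic programming / SVD
code paths: alignments are checked by exhaustive enumeration, rotations
by a dense Euler-angle grid.
"""

from itertools import combinations

import numpy as np
from scipy.spatial.transform import Rotation


def enumerate_global_alignments(S: np.ndarray, gap: float) -> float:
    """Best global alignment score by enumerating every order-preserving
    matching (gap charged per unmatched position in either sequence)."""
    n, m = S.shape
    best = gap * (n + m)  # empty matching
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in combinations(range(m), k):
                s = sum(S[i, j] for i, j in zip(rows, cols)) + gap * (n - k + m - k)
                if s > best:
                    best = s
    return best


def enumerate_matchings_zero_gap(S: np.ndarray) -> float:
    """Maximum-weight order-preserving matching score (zero gap cost)."""
    return enumerate_global_alignments(S, 0.0)


_GRID = {}


def rotation_grid(step_deg: float = 2.0) -> np.ndarray:
    """Dense proper-rotation grid from Euler angles (cached)."""
    if step_deg not in _GRID:
        a = np.arange(0.0, 360.0, step_deg)
        b = np.arange(0.0, 180.0 + step_deg / 2, step_deg)
        angles = np.stack(np.meshgrid(a, b, a, indexing="ij"), axis=-1).reshape(-1, 3)
        _GRID[step_deg] = Rotation.from_euler("zyz", angles, degrees=True).as_matrix().astype(np.float32)
    return _GRID[step_deg]


def grid_min_rmsd(X: np.ndarray, Y: np.ndarray, step_deg: float = 2.0) -> float:
    """Minimum RMSD of Y onto X over the rotation grid (translation solved
    exactly via centroids for each grid rotation)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    # |R y - x|^2 summed = c - 2 tr(R^T M), M = sum x y^T
    c = (Xc**2).sum() + (Yc**2).sum()
    M = (Xc[:, :, None] * Yc[:, None, :]).sum(axis=0)
    grid = rotation_grid(step_deg)
    tr = np.tensordot(grid, M.astype(np.float32), axes=([1, 2], [0, 1]))
    best = float(tr.max())
    return float(np.sqrt(max(c - 2.0 * best, 0.0) / len(X)))


def brute_force_knn(ids, query, k, distance, order=None):
    """Exact k-NN by direct evaluation; ties broken by database order."""
    order = order or {oid: i for i, oid in enumerate(ids)}
    d = sorted(((distance(query, oid), oid) for oid in ids), key=lambda t: (t[0], order[t[1]]))
    return [oid for _, oid in d[:k]]
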