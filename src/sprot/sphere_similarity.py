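"""Local similarity of two aa-spheres.

Five steps: (1) unique gapless alignment of the spherical backbones,
anchored at the centers; (2) least-squares (Kabsch) superposition on
that seed; (3) zero-gap Needleman-Wunsch alignment of the upstream and
downstream neighborhoods under the superposition, scoring each candidate
pair by the TM-style term 1/(1 + (d/d_s)^2); (4) SM-raw: the score sum
over the full spherical alignment, normalized by the maximal sum
attainable for these quantity characteristics; (5) SM-score: the
empirical probability (per quantity-characteristics bucket) that a
lower SM-raw occurs by chance, damped by a factor penalizing
quantity-characteristic mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nw import nw_align, nw_score
from .sphere_model import AASphere, QuantityCharacteristics

DEFAULT_DS = 2.0  # Angstroms; constant scale, aa-spheres being much smaller than whole chains


@dataclass(frozen=True)
class SphereParams:
    """Parameters of the local measure: score scale d_s and sphere radius (Å)."""

    d_s: float = DEFAULT_DS
    radius: float = 9.0

    def __post_init__(self) -> None:
        if self.d_s <= 0:
            raise ValueError("d_s must be positive")


@dataclass
class Superposition:
    """Rigid transform y -> R y + t (proper rotation) with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SphereAlignment:
    """Order-preserving residue index pairs (x, y) with per-pair distances."""

    pairs: list[tuple[int, int]]
    distances: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SphereSimilarityResult:
    sm_raw: float
    max_norm: float
    f: float
    sm_score: float
    alignment: SphereAlignment
    superposition: Superposition


def seed_backbone_alignment(x: AASphere, y: AASphere) -> list[tuple[int, int]]:
    """Unique gapless backbone alignment: centers matched, backbones
    paired outward and truncated to the shorter side in each direction."""
    k_ub = min(x.qc.q_ub, y.qc.q_ub)
    k_db = min(x.qc.q_db, y.qc.q_db)
    cx, cy = x.center_index, y.center_index
    return [(cx + o, cy + o) for o in range(-k_ub, k_db + 1)]


def kabsch_superposition(coords_x: np.ndarray, coords_y: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of y onto x (reflections excluded).

    Degenerate inputs (a single pair, or coincident point sets) fall back
    to the identity rotation with a pure translation.
    """
    X = np.asarray(coords_x, dtype=float)
    Y = np.asarray(coords_y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("kabsch needs two equal-length non-empty point sets")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    Xc = X - cx
    Yc = Y - cy
    C = Yc.T @ Xc
    if not np.any(np.abs(C) > 1e-12):
        R = np.eye(3)
    else:
        U, _, Vt = np.linalg.svd(C)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
    t = cx - R @ cy
    diff = Yc @ R.T - Xc
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return Superposition(R, t, rmsd)


def _pair_scores(dist: np.ndarray, d_s: float) -> np.ndarray:
    return 1.0 / (1.0 + (dist / d_s) ** 2)


def align_neighborhoods(
    x: AASphere, y: AASphere, superposition: Superposition, params: SphereParams
) -> SphereAlignment:
    """Zero-gap NW alignment of the two neighborhood categories under the
    backbone superposition (alpha-carbon distances)."""
    pairs: list[tuple[int, int]] = []
    dists: list[float] = []
    for xs_idx, ys_idx, xs, ys in (
        (x.upstream_neighborhood, y.upstream_neighborhood, x.up_nb_coords, y.up_nb_coords),
        (x.downstream_neighborhood, y.downstream_neighborhood, x.down_nb_coords, y.down_nb_coords),
    ):
        if len(xs_idx) == 0 or len(ys_idx) == 0:
            continue
        ys_t = superposition.apply(ys)
        D = np.sqrt(((xs[:, None, :] - ys_t[None, :, :]) ** 2).sum(axis=2))
        S = _pair_scores(D, params.d_s)
        local, _ = nw_align(S, 0.0)
        for i, j in local:
            pairs.append((xs_idx[i], ys_idx[j]))
            dists.append(D[i, j])
    return SphereAlignment(pairs, np.array(dists, dtype=float))


def _max_norm(qx: QuantityCharacteristics, qy: QuantityCharacteristics) -> float:
    return 1.0 + sum(min(a, b) for a, b in zip(qx.as_tuple(), qy.as_tuple()))


def sm_raw(x: AASphere, y: AASphere, params: SphereParams = SphereParams()) -> SphereSimilarityResult:
    """Steps 1-4: spherical alignment and the normalized raw measure.

    SM-raw = (1/max_norm) * sum over aligned pairs of 1/(1+(d_i/d_s)^2),
    where max_norm = 1 + per-category minima of the quantity
    characteristics (the maximal attainable sum).  The returned result
    has ``f`` and ``sm_score`` unset (NaN); use :func:`sm_score` for the
    calibrated measure.
    """
    seed = seed_backbone_alignment(x, y)
    k_ub = min(x.qc.q_ub, y.qc.q_ub)
    k_db = min(x.qc.q_db, y.qc.q_db)
    cx, cy = x.center_index, y.center_index
    X = x.protein_ca[cx - k_ub : cx + k_db + 1]
    Y = y.protein_ca[cy - k_ub : cy + k_db + 1]
    sup = kabsch_superposition(X, Y)
    seed_d = np.sqrt(((Y @ sup.rotation.T + sup.translation - X) ** 2).sum(axis=1))
    nb = align_neighborhoods(x, y, sup, params)
    # assemble the full spherical alignment in ascending x order
    up = [(p, d) for (p, d) in zip(nb.pairs, nb.distances) if p[0] < cx - k_ub]
    down = [(p, d) for (p, d) in zip(nb.pairs, nb.distances) if p[0] > cx + k_db]
    pairs = [p for p, _ in up] + seed + [p for p, _ in down]
    dists = np.concatenate(
        [
            np.array([d for _, d in up], dtype=float),
            seed_d,
            np.array([d for _, d in down], dtype=float),
        ]
    )
    total = float(_pair_scores(dists, params.d_s).sum())
    mn = _max_norm(x.qc, y.qc)
    return SphereSimilarityResult(
        sm_raw=total / mn,
        max_norm=mn,
        f=float("nan"),
        sm_score=float("nan"),
        alignment=SphereAlignment(pairs, dists),
        superposition=sup,
    )


def _kabsch_rt(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lean Kabsch for the hot path: rotation and translation only.

    Same math as :func:`kabsch_superposition` without the dataclass,
    validation and RMSD bookkeeping.
    """
    cx = X.sum(axis=0) / len(X)
    cy = Y.sum(axis=0) / len(Y)
    C = (Y - cy).T @ (X - cx)
    if not (np.abs(C) > 1e-12).any():
        R = np.eye(3)
    else:
        U, _, Vt = np.linalg.svd(C)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            U[:, 2] = -U[:, 2]
        R = Vt.T @ U.T
    return R, cx - R @ cy


def sm_raw_value(x: AASphere, y: AASphere, d_s: float) -> float:
    """Fast path: SM-raw value only (score-only DP, no tracebacks).

    Used by the all-pairs scoring matrix; numerically identical to
    ``sm_raw(...).sm_raw``.
    """
    k_ub = min(x.qc.q_ub, y.qc.q_ub)
    k_db = min(x.qc.q_db, y.qc.q_db)
    cx, cy = x.center_index, y.center_index
    X = x.protein_ca[cx - k_ub : cx + k_db + 1]
    Y = y.protein_ca[cy - k_ub : cy + k_db + 1]
    R, t = _kabsch_rt(X, Y)
    ds2 = d_s * d_s
    diff = Y @ R.T + t - X
    total = float((1.0 / (1.0 + (diff * diff).sum(axis=1) / ds2)).sum())
    for xs, ys in ((x.up_nb_coords, y.up_nb_coords), (x.down_nb_coords, y.down_nb_coords)):
        if len(xs) == 0 or len(ys) == 0:
            continue
        ys_t = ys @ R.T + t
        D2 = ((xs[:, None, :] - ys_t[None, :, :]) ** 2).sum(axis=2)
        S = 1.0 / (1.0 + D2 / ds2)
        total += nw_score(S, 0.0)
    return total / _max_norm(x.qc, y.qc)


def quantity_factor(qx: QuantityCharacteristics, qy: QuantityCharacteristics) -> float:
    """Penalty for differing quantity characteristics.

    f = prod over the four categories of (1+min)/(1+max); equals 1 iff
    all counts agree and strictly decreases as any category diverges.
    The algebraic form is a package choice satisfying those constraints
    and is kept in one place so it can be swapped.
    """
    f = 1.0
    for a, b in zip(qx.as_tuple(), qy.as_tuple()):
        f *= (1.0 + min(a, b)) / (1.0 + max(a, b))
    return f


def sm_score(x: AASphere, y: AASphere, params: SphereParams, ecdf_table) -> SphereSimilarityResult:
    """Step 5: calibrated sphere similarity.

    SM-score = ECDF_{bucket(x),bucket(y)}(SM-raw) * f(qc_x, qc_y), in [0, 1].
    """
    from .calibration import bucket_key, ecdf_evaluate

    if ecdf_table is None:
        raise ValueError("an ECDF calibration table is required for SM-score")
    res = sm_raw(x, y, params)
    key = bucket_key(x.qc, y.qc)
    p = ecdf_evaluate(ecdf_table, key, res.sm_raw)
    res.f = quantity_factor(x.qc, y.qc)
    res.sm_score = p * res.f
    return res
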