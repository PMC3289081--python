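"""Global structure alignment, TM-score evaluation and the SProt distance.

The calibrated sphere similarities behave like probabilities, so their
logarithms are additive evidence: a Needleman-Wunsch alignment of the
two sphere sequences under log(SM-score) scoring with a constant
(linear-model) gap penalty maximizes the probability that the resulting
pairing is significant.  The pairing is then scored with the TM-score
superposition heuristic, normalized by the query length L_T with the
standard scale d_0(L_T) = 1.24 (L_T - 15)^(1/3) - 1.8 (clamped below).
``1 - TM-score`` is the SProt quasi-distance: zero on identical
structures, asymmetric in general because L_T follows the query.

An optional iterative refinement re-runs NW with TM-style match scores
(pairs farther than 3 d_0 forbidden) and re-scores, repeating while the
TM-score improves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._nw import nw_align, nw_score
from .calibration import ECDFTable, downsample_qc, ecdf_evaluate
from .sphere_model import AASphere, build_all_spheres
from .sphere_similarity import SphereParams, Superposition, kabsch_superposition
from .structure_io import ProteinStructure

DEFAULT_GAP_PENALTY = math.log(0.75)
SCORE_FLOOR = 1e-8  # keeps log(SM-score) finite when the ECDF bottoms out


@dataclass(frozen=True)
class GlobalParams:
    """Parameters of the global stage.

    gap_penalty: log-score charged per gap position (default log 0.75).
    d0_min: lower clamp of the TM-score scale function, Å.
    max_tm_iterations / tolerance: stopping rule of the TM refinement loop.
    """

    gap_penalty: float = DEFAULT_GAP_PENALTY
    d0_min: float = 0.5
    max_tm_iterations: int = 20
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.gap_penalty >= 0:
            raise ValueError("gap_penalty must be negative")
        if self.d0_min <= 0:
            raise ValueError("d0_min must be positive")


@dataclass
class StructureAlignment:
    """A global alignment of a (query, target) pair with its evaluation.

    ``superposition`` maps query coordinates into the target frame;
    ``distances`` are per-pair CA distances under it.  ``cover`` is the
    percentage of query residues aligned, L_T the query length.
    """

    pairs: list[tuple[int, int]]
    L_T: int
    superposition: Superposition
    tm_score: float
    distances: np.ndarray = field(repr=False, default=None)

    @property
    def L_A(self) -> int:
        return len(self.pairs)

    @property
    def cover(self) -> float:
        return 100.0 * self.L_A / self.L_T

    @property
    def rmsd_aligned(self) -> float:
        if self.distances is None or len(self.distances) == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.distances**2)))


def tm_d0(L_T: int, d0_min: float = 0.5) -> float:
    """TM-score scale function of the query length, clamped at d0_min."""
    if L_T > 15:
        d0 = 1.24 * (L_T - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = d0_min
    return max(d0, d0_min)


def build_log_score_matrix(
    query_spheres: list[AASphere],
    target_spheres: list[AASphere],
    params: SphereParams,
    ecdf_table: ECDFTable,
    floor: float = SCORE_FLOOR,
) -> np.ndarray:
    """Entry (i, j) = log(max(SM-score(sphere_i, sphere_j), floor)); all <= 0.

    Numerically equivalent to evaluating :func:`sphere_similarity.sm_score`
    entry by entry; the backbone superpositions are batched (grouped by
    seed-alignment length, stacked 3x3 SVDs) because this matrix
    dominates the cost of a structure comparison.
    """
    if ecdf_table is None:
        raise ValueError("an ECDF calibration table is required")
    n, m = len(query_spheres), len(target_spheres)
    d_s2 = params.d_s**2
    qca = query_spheres[0].protein_ca
    tca = target_spheres[0].protein_ca
    qc_x = np.array([s.qc.as_tuple() for s in query_spheres])  # (n, 4)
    qc_y = np.array([s.qc.as_tuple() for s in target_spheres])  # (m, 4)
    k_ub = np.minimum.outer(qc_x[:, 0], qc_y[:, 0])
    k_db = np.minimum.outer(qc_x[:, 1], qc_y[:, 1])

    total = np.zeros((n, m))
    rot = np.empty((n, m, 3, 3))
    trans = np.empty((n, m, 3))
    ci = np.array([s.center_index for s in query_spheres])
    cj = np.array([s.center_index for s in target_spheres])
    for a, b in {(int(a), int(b)) for a, b in zip(k_ub.ravel(), k_db.ravel())}:
        ii, jj = np.nonzero((k_ub == a) & (k_db == b))
        offsets = np.arange(-a, b + 1)
        X = qca[ci[ii][:, None] + offsets]  # (G, L, 3)
        Y = tca[cj[jj][:, None] + offsets]
        cx = X.mean(axis=1)
        cy = Y.mean(axis=1)
        Xc = X - cx[:, None]
        Yc = Y - cy[:, None]
        C = np.einsum("gli,glj->gij", Yc, Xc)
        degenerate = ~(np.abs(C) > 1e-12).any(axis=(1, 2))
        U, _, Vt = np.linalg.svd(C)
        neg = np.linalg.det(U) * np.linalg.det(Vt) < 0
        U[neg, :, 2] *= -1.0
        R = np.einsum("gab,gca->gbc", Vt, U)
        if degenerate.any():
            R[degenerate] = np.eye(3)
        t = cx - np.einsum("gbc,gc->gb", R, cy)
        diff = np.einsum("gbc,glc->glb", R, Y) + t[:, None] - X
        total[ii, jj] = (1.0 / (1.0 + (diff * diff).sum(axis=2) / d_s2)).sum(axis=1)
        rot[ii, jj] = R
        trans[ii, jj] = t

    # neighborhoods: per-pair zero-gap NW where both sides are non-empty
    has_up_x = qc_x[:, 2] > 0
    has_dn_x = qc_x[:, 3] > 0
    for i in range(n):
        x = query_spheres[i]
        for j in range(m):
            y = target_spheres[j]
            acc = 0.0
            if has_up_x[i] and y.qc.q_un:
                acc += _nb_score(x.up_nb_coords, y.up_nb_coords, rot[i, j], trans[i, j], d_s2)
            if has_dn_x[i] and y.qc.q_dn:
                acc += _nb_score(x.down_nb_coords, y.down_nb_coords, rot[i, j], trans[i, j], d_s2)
            if acc:
                total[i, j] += acc

    max_norm = 1.0 + k_ub + k_db + np.minimum.outer(qc_x[:, 2], qc_y[:, 2]) + np.minimum.outer(qc_x[:, 3], qc_y[:, 3])
    raw = total / max_norm
    fmat = np.ones((n, m))
    for c in range(4):
        fmat *= (1.0 + np.minimum.outer(qc_x[:, c], qc_y[:, c])) / (1.0 + np.maximum.outer(qc_x[:, c], qc_y[:, c]))

    log_floor = math.log(floor)
    S = np.empty((n, m))
    kx = [downsample_qc(s.qc) for s in query_spheres]
    ky = [downsample_qc(s.qc) for s in target_spheres]
    for i in range(n):
        for j in range(m):
            p = ecdf_evaluate(ecdf_table, (kx[i], ky[j]), raw[i, j])
            s = p * fmat[i, j]
            S[i, j] = math.log(s) if s > floor else log_floor
    return S


def _nb_score(xs: np.ndarray, ys: np.ndarray, R: np.ndarray, t: np.ndarray, d_s2: float) -> float:
    ys_t = ys @ R.T + t
    D2 = ((xs[:, None, :] - ys_t[None, :, :]) ** 2).sum(axis=2)
    return nw_score(1.0 / (1.0 + D2 / d_s2), 0.0)


def needleman_wunsch_global(score_matrix: np.ndarray, gap_penalty: float) -> list[tuple[int, int]]:
    """Optimal global alignment under the linear gap model (deterministic
    traceback: match, then advance in the query, then in the target)."""
    if score_matrix.size == 0:
        raise ValueError("empty score matrix")
    if not np.all(np.isfinite(score_matrix)):
        raise ValueError("score matrix must be finite")
    pairs, _ = nw_align(score_matrix, gap_penalty)
    return pairs


def _tm_value(diff2: np.ndarray, d0: float, L_T: int) -> float:
    return float((1.0 / (1.0 + diff2 / (d0 * d0))).sum()) / L_T


def tm_score_superposition(
    pairs: list[tuple[int, int]],
    query: ProteinStructure,
    target: ProteinStructure,
    params: GlobalParams = GlobalParams(),
) -> StructureAlignment:
    """Best superposition for a fixed pairing, per the TM-score heuristic.

    Seeds: contiguous windows of the aligned pairs at lengths L_A,
    L_A/2 and L_A/4 (minimum 4), window starts stepped by half the
    window.  Each seed is Kabsch-superposed, then refined per distance
    cutoff (d_0 upward to 8 Å in 1 Å steps): keep pairs closer than the
    cutoff, re-superpose, repeat to a fixed point.  Every candidate
    superposition is scored on ALL pairs by
    (1/L_T) sum 1/(1+(d_i/d_0(L_T))^2) and the maximum is returned.
    """
    if not pairs:
        raise ValueError("empty pairing")
    L_T = len(query)
    d0 = tm_d0(L_T, params.d0_min)
    qi = np.fromiter((p[0] for p in pairs), dtype=int)
    ti = np.fromiter((p[1] for p in pairs), dtype=int)
    Q = query.ca_coords[qi]
    T = target.ca_coords[ti]
    L_A = len(pairs)

    cutoffs = [d0 + k for k in range(int(math.ceil(8.0 - d0)) + 1)]
    lengths = sorted({L_A, max(4, L_A // 2), max(4, L_A // 4)} & set(range(1, L_A + 1)), reverse=True)
    if not lengths:
        lengths = [L_A]

    best_score = -1.0
    best_sup: Optional[Superposition] = None
    for wlen in lengths:
        step = max(1, wlen // 2)
        starts = list(range(0, L_A - wlen + 1, step))
        if starts[-1] != L_A - wlen:
            starts.append(L_A - wlen)
        for s0 in starts:
            sel = np.arange(s0, s0 + wlen)
            sup = kabsch_superposition(T[sel], Q[sel])  # query -> target frame
            diff2 = ((Q @ sup.rotation.T + sup.translation - T) ** 2).sum(axis=1)
            score = _tm_value(diff2, d0, L_T)
            if score > best_score:
                best_score, best_sup = score, sup
            for cut in cutoffs:
                cur = sel
                cut2 = cut * cut
                for _ in range(30):
                    near = np.nonzero(diff2 < cut2)[0]
                    if len(near) < 3:
                        break
                    if len(near) == len(cur) and np.array_equal(near, cur):
                        break
                    cur = near
                    sup = kabsch_superposition(T[cur], Q[cur])
                    diff2 = ((Q @ sup.rotation.T + sup.translation - T) ** 2).sum(axis=1)
                    score = _tm_value(diff2, d0, L_T)
                    if score > best_score:
                        best_score, best_sup = score, sup

    diff = Q @ best_sup.rotation.T + best_sup.translation - T
    dists = np.sqrt((diff * diff).sum(axis=1))
    best_sup = Superposition(best_sup.rotation, best_sup.translation, float(np.sqrt(np.mean(dists**2))))
    return StructureAlignment(list(pairs), L_T, best_sup, best_score, dists)


class SProtMeasure:
    """The full measure: spheres -> log-score matrix -> NW -> TM-score.

    Holds the parameterization and the calibration table, and caches the
    aa-spheres of every structure it has seen (keyed by object identity).
    """

    def __init__(
        self,
        ecdf_table: ECDFTable,
        sphere_params: SphereParams = SphereParams(),
        global_params: GlobalParams = GlobalParams(),
    ):
        self.ecdf_table = ecdf_table
        self.sphere_params = sphere_params
        self.global_params = global_params
        self.n_alignments = 0

    def fingerprint(self) -> str:
        sp, gp = self.sphere_params, self.global_params
        return f"radius={sp.radius},d_s={sp.d_s},gap={gp.gap_penalty:.6f}"

    def spheres(self, structure: ProteinStructure) -> list[AASphere]:
        # cached on the structure itself so the cache cannot outlive it
        cache = getattr(structure, "_sphere_cache", None)
        if cache is None:
            cache = {}
            structure._sphere_cache = cache
        radius = self.sphere_params.radius
        if radius not in cache:
            cache[radius] = build_all_spheres(structure, radius)
        return cache[radius]

    def _nw_pairs(self, query: ProteinStructure, target: ProteinStructure) -> list[tuple[int, int]]:
        S = build_log_score_matrix(
            self.spheres(query), self.spheres(target), self.sphere_params, self.ecdf_table
        )
        self.n_alignments += 1
        return needleman_wunsch_global(S, self.global_params.gap_penalty)

    def align(self, query: ProteinStructure, target: ProteinStructure, refine: bool = False) -> StructureAlignment:
        pairs = self._nw_pairs(query, target)
        if not pairs:
            # no significantly similar spheres at all: degenerate alignment
            return StructureAlignment([], len(query), Superposition(np.eye(3), np.zeros(3), 0.0), 0.0, np.array([]))
        aln = tm_score_superposition(pairs, query, target, self.global_params)
        if refine:
            aln = tm_optimize(query, target, aln, self.global_params)
        return aln

    def distance(self, query: ProteinStructure, target: ProteinStructure) -> float:
        return 1.0 - self.align(query, target).tm_score

    def distance_pair(self, x: ProteinStructure, y: ProteinStructure) -> tuple[float, float]:
        """(d(x, y), d(y, x)) sharing one sphere alignment.

        The NW pairing is direction-independent up to transposition (it
        dominates the cost); only the TM evaluation, whose normalization
        follows the query, is run per direction.
        """
        pairs = self._nw_pairs(x, y)
        if not pairs:
            return 1.0, 1.0
        d_xy = 1.0 - tm_score_superposition(pairs, x, y, self.global_params).tm_score
        swapped = [(j, i) for i, j in pairs]
        d_yx = 1.0 - tm_score_superposition(swapped, y, x, self.global_params).tm_score
        return d_xy, d_yx


def sprot_distance(
    query: ProteinStructure,
    target: ProteinStructure,
    sphere_params: SphereParams,
    global_params: GlobalParams,
    ecdf_table: ECDFTable,
) -> float:
    """1 - TM-score of the SProt alignment; 0 for self-comparison, in [0, 1)."""
    return SProtMeasure(ecdf_table, sphere_params, global_params).distance(query, target)


def tm_optimize(
    query: ProteinStructure,
    target: ProteinStructure,
    initial: StructureAlignment,
    params: GlobalParams = GlobalParams(),
    score_history: Optional[list] = None,
) -> StructureAlignment:
    """Iterative TM refinement of an alignment.

    Repeats {NW with match score 1/(1+(d_ij/d_0)^2) under the current
    superposition, pairs beyond 3 d_0 forbidden, zero gap cost; then the
    TM-score heuristic on the new pairing} while the score improves by
    more than the tolerance.  The best-so-far alignment is returned, so
    the score sequence is non-decreasing.
    """
    best = initial
    if score_history is not None:
        score_history.append(best.tm_score)
    L_T = len(query)
    d0 = tm_d0(L_T, params.d0_min)
    Tc = target.ca_coords
    for _ in range(params.max_tm_iterations):
        sup = best.superposition
        Qm = query.ca_coords @ sup.rotation.T + sup.translation
        D2 = ((Qm[:, None, :] - Tc[None, :, :]) ** 2).sum(axis=2)
        S = 1.0 / (1.0 + D2 / (d0 * d0))
        S[D2 > (3.0 * d0) ** 2] = -np.inf
        pairs, _ = nw_align(S, 0.0)
        if not pairs:
            break
        cand = tm_score_superposition(pairs, query, target, params)
        if score_history is not None:
            score_history.append(max(cand.tm_score, best.tm_score))
        if cand.tm_score > best.tm_score + params.tolerance:
            best = cand
        else:
            break
    return best
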