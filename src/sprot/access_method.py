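"""Approximate k-NN search over a structure database (LAESA variant).

The SProt distance is expensive, asymmetric and mildly violates the
triangle inequality, so the classic pivot-based LAESA scheme is adapted
in three ways: (1) pivot tables are bidirectional -- both d(p, o) and
d(o, p) are precomputed, and the lower bound on d(q, o) combines the two
directed triangle bounds that remain valid without symmetry; (2) an
object is eliminated only when its estimation exceeds the current k-NN
threshold by more than v percent (*approximation error tolerance*);
(3) after the candidate set empties, eliminated objects keep being
re-examined (smallest estimation first) until the result set has stayed
unchanged for r consecutive extra iterations (*order error tolerance*).

Even one overvalued bound corrupts an estimation: with triplet-violation
probability p and n pivots the estimation is wrong with probability
1 - (1 - p)^n (about 9.5% already at p = 1e-4, n = 1000), which is why
the two tolerance factors matter.

Distances may additionally be passed through a monotone convex
*similarity-preserving modifier* (a rational quadratic Bezier map) that
tightens clusters and thereby improves the elimination rate, trading a
little exactness for speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Optional, Sequence

import numpy as np

INDEX_FORMAT_VERSION = 1


# ---------------------------------------------------------------- modifier


@dataclass(frozen=True)
class RBQModifier:
    """Rational quadratic Bezier map on [0, 1].

    Control polygon (0,0) -> (a,b) -> (1,1) with middle weight w; the
    default control point (0.7, 0.15) expands the crowded upper range of
    the SProt distance at the expense of the lower one.  w = 0
    degenerates to the identity.
    """

    a: float = 0.7
    b: float = 0.15
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("weight must be non-negative")


def rbq_apply(modifier: RBQModifier, d):
    """Evaluate the modifier at distance(s) d in [0, 1].

    Solves x(t) = d by bisection (x is strictly increasing in t) and
    returns y(t); vectorized over arrays.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("distances must lie in [0, 1]")
    if modifier is None or modifier.w == 0:
        return d if np.isscalar(d) else arr.copy()
    a, b, w = modifier.a, modifier.b, modifier.w
    lo = np.zeros_like(arr)
    hi = np.ones_like(arr)
    for _ in range(60):  # 2^-60 << 1e-9
        t = 0.5 * (lo + hi)
        mid = 2.0 * w * t * (1.0 - t)
        denom = (1.0 - t) ** 2 + mid + t * t
        x = (mid * a + t * t) / denom
        high = x > arr
        hi = np.where(high, t, hi)
        lo = np.where(high, lo, t)
    t = 0.5 * (lo + hi)
    mid = 2.0 * w * t * (1.0 - t)
    denom = (1.0 - t) ** 2 + mid + t * t
    y = (mid * b + t * t) / denom
    return float(y) if np.isscalar(d) else y


# ---------------------------------------------------------------- index


@dataclass
class PivotIndex:
    """Bidirectional pivot-to-object distance tables in modified space.

    ``d_po[r, c] = m(d(pivot_r, object_c))`` and
    ``d_op[r, c] = m(d(object_c, pivot_r))`` where m is the modifier.
    ``fingerprint`` records the measure parameterization and must match
    the query-time distance closure.
    """

    object_ids: list
    pivot_ids: list
    d_po: np.ndarray
    d_op: np.ndarray
    modifier: Optional[RBQModifier]
    fingerprint: str = ""

    def __post_init__(self) -> None:
        npiv, nobj = len(self.pivot_ids), len(self.object_ids)
        if self.d_po.shape != (npiv, nobj) or self.d_op.shape != (npiv, nobj):
            raise ValueError("distance tables do not match pivot/object counts")

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "sprot-index",
            "version": INDEX_FORMAT_VERSION,
            "fingerprint": self.fingerprint,
            "object_ids": list(self.object_ids),
            "pivot_ids": list(self.pivot_ids),
            "modifier": None if self.modifier is None else [self.modifier.a, self.modifier.b, self.modifier.w],
            "d_po": [[float(v).hex() for v in row] for row in self.d_po],
            "d_op": [[float(v).hex() for v in row] for row in self.d_op],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path, expect_fingerprint: Optional[str] = None) -> "PivotIndex":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "sprot-index" or payload.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"{path}: not a recognized index file")
        if expect_fingerprint is not None and payload["fingerprint"] != expect_fingerprint:
            raise ValueError(
                f"{path}: index fingerprint {payload['fingerprint']!r} does not match "
                f"the current measure {expect_fingerprint!r}"
            )
        mod = payload["modifier"]
        return cls(
            payload["object_ids"],
            payload["pivot_ids"],
            np.array([[float.fromhex(v) for v in row] for row in payload["d_po"]]),
            np.array([[float.fromhex(v) for v in row] for row in payload["d_op"]]),
            None if mod is None else RBQModifier(*mod),
            payload["fingerprint"],
        )


def build_pivot_index(
    object_ids: Sequence[Hashable],
    pivot_ids: Sequence[Hashable],
    distance_pair: Callable[[Hashable, Hashable], tuple[float, float]],
    modifier: Optional[RBQModifier] = None,
    fingerprint: str = "",
) -> PivotIndex:
    """Precompute both directed distances pivot<->object for the index.

    ``distance_pair(a, b)`` returns (d(a, b), d(b, a)); for the SProt
    measure the two share one alignment, so the second direction is
    nearly free.
    """
    pivot_ids = list(pivot_ids)
    object_ids = list(object_ids)
    if not pivot_ids:
        raise ValueError("empty pivot set")
    missing = set(pivot_ids) - set(object_ids)
    if missing:
        raise ValueError(f"pivots not in database: {sorted(map(str, missing))}")
    npiv, nobj = len(pivot_ids), len(object_ids)
    d_po = np.empty((npiv, nobj))
    d_op = np.empty((npiv, nobj))
    for r, p in enumerate(pivot_ids):
        for c, o in enumerate(object_ids):
            if p == o:
                d_po[r, c] = d_op[r, c] = 0.0
            else:
                d_po[r, c], d_op[r, c] = distance_pair(p, o)
    if modifier is not None and modifier.w > 0:
        d_po = rbq_apply(modifier, d_po)
        d_op = rbq_apply(modifier, d_op)
    return PivotIndex(object_ids, pivot_ids, d_po, d_op, modifier, fingerprint)


def select_pivots(
    object_ids: Sequence[Hashable],
    labels: Optional[dict] = None,
    n_pivots: Optional[int] = None,
    distance: Optional[Callable[[Hashable, Hashable], float]] = None,
    seed: int = 0,
) -> list:
    """Pivot selection: one object per family label when labels are given
    (the first id of each family in sorted order), otherwise seeded
    max-min farthest-point sampling of ``n_pivots`` objects."""
    ids = sorted(object_ids)
    if labels is not None:
        seen: dict = {}
        for oid in ids:
            fam = labels[oid]
            seen.setdefault(fam, oid)
        return sorted(seen.values())
    if n_pivots is None or distance is None:
        raise ValueError("without labels, n_pivots and a distance are required")
    rng = np.random.default_rng(seed)
    first = ids[int(rng.integers(len(ids)))]
    chosen = [first]
    mind = {oid: distance(first, oid) for oid in ids}
    while len(chosen) < n_pivots:
        far = max((d, oid) for oid, d in mind.items() if oid not in chosen)[1]
        chosen.append(far)
        for oid in ids:
            d = distance(far, oid)
            if d < mind[oid]:
                mind[oid] = d
    return sorted(chosen)


# ---------------------------------------------------------------- search


@dataclass(frozen=True)
class SearchParams:
    """k-NN search settings.

    v: approximation error tolerance, percent (elimination requires the
       estimation to exceed the threshold by more than v%).
    r: order error tolerance, count (extra iterations re-examining
       eliminated objects that must leave the result unchanged).
    protected_steps: iterations during which pivots cannot be eliminated
       (default, set at query time: half the pivot count).
    """

    k: int = 10
    v: float = 2.5
    r: int = 128
    protected_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.v < 0 or self.r < 0:
            raise ValueError("invalid search parameters")


@dataclass
class KNNResult:
    """Ranked result: (object id, modified distance) ascending, plus the
    number of full distance computations spent.  ``raw_distances`` maps
    each computed object id to its unmodified distance from the query."""

    items: list[tuple[Hashable, float]]
    n_distance_computations: int
    raw_distances: dict = field(default_factory=dict)

    @property
    def ids(self) -> list:
        return [oid for oid, _ in self.items]


def lower_bound(dq_p: float, dp_q: float, dp_o: float, do_p: float) -> float:
    """Lower bound on d(q, o) through pivot p without assuming symmetry.

    The two directed triangle bounds are d(q,o) >= d(q,p) - d(o,p) and
    d(q,o) >= d(p,o) - d(p,q); with symmetric inputs this reduces to the
    classic |d(q,p) - d(p,o)|.
    """
    return max(dq_p - do_p, dp_o - dp_q, 0.0)


def knn_search(
    index: PivotIndex,
    query,
    params: SearchParams,
    distance_pair: Callable[[object, Hashable], tuple[float, float]],
) -> KNNResult:
    """Approximate k-NN of ``query`` over the indexed database.

    ``distance_pair(query, object_id)`` returns the unmodified
    (d(query, o), d(o, query)); the index's modifier is applied here so
    thresholds and estimations live in modified space.  Deterministic:
    ties in selection and in the result are broken by object id.
    """
    ids = index.object_ids
    n = len(ids)
    k = params.k
    if n == 0:
        raise ValueError("empty database")
    if k > n:
        raise ValueError(f"k={k} exceeds database size {n}")
    protected_steps = params.protected_steps
    if protected_steps is None:
        protected_steps = (len(index.pivot_ids) + 1) // 2
    pivot_row = {oid: r for r, oid in enumerate(index.pivot_ids)}
    is_pivot = np.array([oid in pivot_row for oid in ids])
    order = {oid: c for c, oid in enumerate(ids)}

    e = np.zeros(n)
    in_s = np.ones(n, dtype=bool)
    eliminated = np.zeros(n, dtype=bool)
    processed = np.zeros(n, dtype=bool)
    R: list[tuple[float, Hashable]] = []
    raw: dict = {}
    n_computed = 0
    resel_count = 0
    step = 0

    def _argbest(mask: np.ndarray) -> int:
        cand = np.nonzero(mask)[0]
        best = cand[np.argmin(e[cand])]
        # id tie-break among equal estimations
        tied = cand[e[cand] == e[best]]
        if len(tied) > 1:
            best = min(tied, key=lambda c: ids[c])
        return int(best)

    # first selection: the pivot with the lowest id
    s = order[min(index.pivot_ids)]

    while s is not None:
        step += 1
        oid = ids[s]
        d_qs, d_sq = distance_pair(query, oid)
        raw[oid] = d_qs
        if index.modifier is not None and index.modifier.w > 0:
            d_qs = rbq_apply(index.modifier, d_qs)
            d_sq = rbq_apply(index.modifier, d_sq)
        n_computed += 1
        in_s[s] = False
        eliminated[s] = False
        processed[s] = True

        old_R = list(R)
        R.append((d_qs, oid))
        R.sort(key=lambda item: (item[0], order[item[1]]))
        del R[k:]
        if R != old_R:
            resel_count = 0

        if is_pivot[s]:
            row = pivot_row[oid]
            live = ~processed
            lb = np.maximum(np.maximum(d_qs - index.d_op[row], index.d_po[row] - d_sq), 0.0)
            e[live] = np.maximum(e[live], lb[live])

        theta = R[-1][0] if len(R) == k else np.inf
        if np.isfinite(theta):
            elim = in_s & (e > theta * (1.0 + params.v / 100.0))
            if step <= protected_steps:
                elim &= ~is_pivot
            in_s[elim] = False
            eliminated[elim] = True

        pivots_live = in_s & is_pivot
        if pivots_live.any():
            s = _argbest(pivots_live)
        elif in_s.any():
            s = _argbest(in_s)
        elif resel_count < params.r and eliminated.any():
            s = _argbest(eliminated)
            resel_count += 1
        else:
            s = None

    return KNNResult([(oid, d) for d, oid in R], n_computed, raw)


def sequential_scan(
    object_ids: Sequence[Hashable],
    query,
    k: int,
    distance_pair: Callable[[object, Hashable], tuple[float, float]],
    modifier: Optional[RBQModifier] = None,
) -> KNNResult:
    """Exact k-NN by scanning the whole database (same tie rules)."""
    ids = list(object_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds database size {len(ids)}")
    order = {oid: c for c, oid in enumerate(ids)}
    dists = []
    raw = {}
    for oid in ids:
        d, _ = distance_pair(query, oid)
        raw[oid] = d
        if modifier is not None and modifier.w > 0:
            d = rbq_apply(modifier, d)
        dists.append((d, oid))
    dists.sort(key=lambda item: (item[0], order[item[1]]))
    return KNNResult([(oid, d) for d, oid in dists[:k]], len(ids), raw)


# ---------------------------------------------------------------- errors


def retrieval_error(R: Sequence[Hashable], R_seq: Sequence[Hashable]) -> float:
    """Percent of sequential-scan results missing from the approximate result."""
    ref = set(R_seq)
    if not ref:
        raise ValueError("empty reference result")
    return 100.0 * len(ref - set(R)) / len(ref)


def scop_retrieval_error(
    R: Sequence[Hashable], R_seq: Sequence[Hashable], same_category: Sequence[Hashable]
) -> Optional[float]:
    """Retrieval error restricted to structures sharing the query's
    category; None when the reference contains no such structure."""
    relevant = set(R_seq) & set(same_category)
    if not relevant:
        return None
    return 100.0 * len(relevant - set(R)) / len(relevant)


def estimation_error_probability(p_triplet: float, n_pivots: int) -> float:
    """Percent probability that at least one of n pivot-derived lower
    bounds is overvalued, given per-triplet violation probability p."""
    return 100.0 * (1.0 - (1.0 - p_triplet) ** n_pivots)
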