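"""Effectiveness metrics: nearest-neighbor classification against a
family/superfamily/fold hierarchy, precision-recall retrieval metrics,
and per-alignment quality numbers (cover, aligned RMSD)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .structure_io import ProteinStructure

_LEVELS = {"family": 0, "superfamily": 1, "fold": 2}


@dataclass
class RankedResult:
    """One query's ranked database ids with distances and relevance flags
    (relevant = same family as the query)."""

    query_id: str
    ids: list
    distances: np.ndarray
    relevant: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.relevant = np.asarray(self.relevant, dtype=bool)
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be non-decreasing")


def rank_database(
    query: ProteinStructure,
    database: Sequence[ProteinStructure],
    distance: Callable[[ProteinStructure, ProteinStructure], float],
    exclude_self: bool = True,
) -> RankedResult:
    """Rank the database by distance to the query (ties by id); exact
    self-matches (same id) are excluded by default."""
    entries = []
    for o in database:
        if exclude_self and o.id == query.id:
            continue
        entries.append((distance(query, o), o.id, o))
    entries.sort(key=lambda t: (t[0], t[1]))
    qfam = query.label[0] if query.label else None
    return RankedResult(
        query.id,
        [oid for _, oid, _ in entries],
        np.array([d for d, _, _ in entries]),
        np.array([o.label is not None and o.label[0] == qfam for _, _, o in entries]),
    )


def nn_classify(
    query: ProteinStructure,
    database: Sequence[ProteinStructure],
    level: str,
    distance: Callable[[ProteinStructure, ProteinStructure], float],
) -> str:
    """Label of the query's nearest database structure at the given level."""
    if not database:
        raise ValueError("empty database")
    lvl = _LEVELS[level]
    best = min(database, key=lambda o: (distance(query, o), o.id))
    if best.label is None:
        raise ValueError(f"database structure {best.id} has no label")
    return best.label[lvl]


def classification_accuracy(
    queries: Sequence[ProteinStructure],
    database: Sequence[ProteinStructure],
    level: str,
    distance: Callable[[ProteinStructure, ProteinStructure], float],
) -> float:
    """Percent of queries whose 1-NN label matches their own label."""
    lvl = _LEVELS[level]
    correct = 0
    for q in queries:
        if q.label is None:
            raise ValueError(f"query {q.id} has no label")
        if nn_classify(q, database, level, distance) == q.label[lvl]:
            correct += 1
    return 100.0 * correct / len(queries)


def precision_recall(ranked: RankedResult) -> Optional[dict]:
    """Per-rank precision/recall and the derived scalars.

    ``average_precision`` is the mean of precisions at the ranks of the
    relevant items; ``ap_standard_recall`` is the mean of interpolated
    precision (max precision at recall >= level) over the 10 standard
    recall levels 10%..100%.  Returns None when nothing is relevant.
    """
    rel = ranked.relevant
    n_rel = int(rel.sum())
    if n_rel == 0:
        return None
    ranks = np.arange(1, len(rel) + 1)
    cum_rel = np.cumsum(rel)
    precision = cum_rel / ranks
    recall = cum_rel / n_rel
    ap = float(precision[rel].mean())
    interp = np.maximum.accumulate(precision[::-1])[::-1]
    levels = np.arange(0.1, 1.01, 0.1)
    at_levels = []
    for lv in levels:
        ok = recall >= lv - 1e-12
        at_levels.append(float(interp[ok][0]) if ok.any() else 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "average_precision": ap,
        "precision_at_standard_recall": np.array(at_levels),
        "ap_standard_recall": float(np.mean(at_levels)),
    }


def mean_average_precision(results: Sequence[RankedResult]) -> dict:
    """MAP and the mean precision over standard recall levels, averaged
    over the queries that have at least one relevant structure."""
    aps, std = [], []
    for r in results:
        pr = precision_recall(r)
        if pr is None:
            continue
        aps.append(pr["average_precision"])
        std.append(pr["ap_standard_recall"])
    if not aps:
        raise ValueError("no query has relevant structures")
    return {
        "mean_average_precision": float(np.mean(aps)),
        "mean_ap_standard_recall": float(np.mean(std)),
        "n_queries": len(aps),
    }


def alignment_stats(alignment) -> tuple[float, float]:
    """(cover %, aligned RMSD in Å) of a structure alignment."""
    return alignment.cover, alignment.rmsd_aligned
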