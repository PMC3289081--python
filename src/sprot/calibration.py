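"""ECDF calibration of the raw sphere measure.

An SM-raw value that occurs by chance depends strongly on how many
residues the two spheres contain: small spheres superpose well by
accident.  Per-bucket empirical cumulative distribution functions of
SM-raw, collected over cross-protein sphere pairs of a calibration set,
turn the raw value into the probability that a better value would not
arise by chance for spheres of the same quantity characteristics.

Buckets are downsampled quantity-characteristic pairs: neighborhood
counts are halved, backbone counts 0 and 1 share a bin, and every
component is capped at 7.  The (x, y) order of the bucket key is kept
(the measure is not symmetrized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .sphere_model import QuantityCharacteristics, build_all_spheres
from .sphere_similarity import SphereParams, sm_raw_value
from .structure_io import ProteinStructure

#: (x-bucket, y-bucket) of downsampled quantity characteristics
BucketKey = tuple[tuple[int, int, int, int], tuple[int, int, int, int]]

FORMAT_VERSION = 1


def downsample_qc(qc: QuantityCharacteristics | tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    """Downsample one quantity-characteristics tuple.

    Order of operations is fixed: neighborhoods are halved (floor),
    backbone counts 0 and 1 are merged (both -> 1), then every component
    is capped at 7.
    """
    if isinstance(qc, QuantityCharacteristics):
        q_ub, q_db, q_un, q_dn = qc.as_tuple()
    else:
        q_ub, q_db, q_un, q_dn = qc
    bb = lambda q: min(max(q, 1), 7)
    nb = lambda q: min(q // 2, 7)
    return (bb(q_ub), bb(q_db), nb(q_un), nb(q_dn))


def bucket_key(qx: QuantityCharacteristics, qy: QuantityCharacteristics) -> BucketKey:
    return (downsample_qc(qx), downsample_qc(qy))


@dataclass
class ECDFTable:
    """Per-bucket sorted SM-raw samples plus calibration metadata."""

    samples: dict[BucketKey, np.ndarray]
    metadata: dict = field(default_factory=dict)
    _fallback_cache: dict = field(default_factory=dict, repr=False)

    def fingerprint(self) -> str:
        m = self.metadata
        return f"radius={m.get('radius')},d_s={m.get('d_s')}"

    # -- serialization (versioned JSON; text-only, repr-exact floats) --

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "sprot-ecdf",
            "version": FORMAT_VERSION,
            "metadata": self.metadata,
            "buckets": {
                _key_to_str(k): [float(v).hex() for v in vals]
                for k, vals in sorted(self.samples.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "ECDFTable":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "sprot-ecdf" or payload.get("version") != FORMAT_VERSION:
            raise ValueError(f"{path}: not a recognized ECDF table file")
        samples = {
            _str_to_key(k): np.array([float.fromhex(v) for v in vals], dtype=float)
            for k, vals in payload["buckets"].items()
        }
        return cls(samples, payload.get("metadata", {}))


def _key_to_str(key: BucketKey) -> str:
    return ",".join(map(str, key[0])) + "|" + ",".join(map(str, key[1]))


def _str_to_key(s: str) -> BucketKey:
    a, b = s.split("|")
    return (tuple(int(x) for x in a.split(",")), tuple(int(x) for x in b.split(",")))


def build_ecdf_table(
    calibration_set: Iterable[ProteinStructure],
    params: SphereParams = SphereParams(),
    sampling: int = 50_000,
    seed: int = 0,
    max_total_pairs: int | None = None,
) -> ECDFTable:
    """Build the per-bucket SM-raw distributions from cross-protein
    sphere pairs of a calibration set.

    All ordered cross-protein sphere pairs are enumerated (optionally
    thinned to ``max_total_pairs`` by seeded uniform subsampling); within
    each bucket at most ``sampling`` values are kept by seeded reservoir
    sampling.  Deterministic given the seed.
    """
    proteins = list(calibration_set)
    if not proteins:
        raise ValueError("empty calibration set")
    rng = np.random.default_rng(seed)
    all_spheres = [build_all_spheres(p, params.radius) for p in proteins]

    pair_index = [
        (a, i, b, j)
        for a in range(len(proteins))
        for b in range(len(proteins))
        if a != b
        for i in range(len(all_spheres[a]))
        for j in range(len(all_spheres[b]))
    ]
    if max_total_pairs is not None and len(pair_index) > max_total_pairs:
        keep = rng.choice(len(pair_index), size=max_total_pairs, replace=False)
        pair_index = [pair_index[k] for k in sorted(keep)]

    reservoirs: dict[BucketKey, list[float]] = {}
    seen: dict[BucketKey, int] = {}
    n_evaluated = 0
    for a, i, b, j in pair_index:
        x = all_spheres[a][i]
        y = all_spheres[b][j]
        v = sm_raw_value(x, y, params.d_s)
        n_evaluated += 1
        key = bucket_key(x.qc, y.qc)
        cnt = seen.get(key, 0)
        res = reservoirs.setdefault(key, [])
        if cnt < sampling:
            res.append(v)
        else:
            r = int(rng.integers(0, cnt + 1))
            if r < sampling:
                res[r] = v
        seen[key] = cnt + 1

    samples = {k: np.sort(np.array(v, dtype=float)) for k, v in reservoirs.items()}
    meta = {
        "calibration_set": [p.id for p in proteins],
        "radius": params.radius,
        "d_s": params.d_s,
        "sampling_cap": sampling,
        "seed": seed,
        "n_evaluated_pairs": n_evaluated,
        "sample_counts": {_key_to_str(k): len(v) for k, v in sorted(samples.items())},
    }
    return ECDFTable(samples, meta)


def _nearest_key(table: ECDFTable, key: BucketKey) -> BucketKey:
    """Nearest populated bucket by L1 distance over the 8 components,
    ties resolved by lexicographically smallest key."""
    cached = table._fallback_cache.get("__keys__")
    if cached is None:
        keys = sorted(table.samples.keys())
        mat = np.array([k[0] + k[1] for k in keys], dtype=int)
        cached = (keys, mat)
        table._fallback_cache["__keys__"] = cached
    keys, mat = cached
    d = np.abs(mat - np.array(key[0] + key[1], dtype=int)).sum(axis=1)
    # keys are lexicographically sorted, so the first argmin wins ties
    return keys[int(np.argmin(d))]


#: tie tolerance: samples within this of the value count as <= value, so
#: that floating-point summation order cannot flip a step of the ECDF
_ECDF_EPS = 1e-9


def ecdf_evaluate(table: ECDFTable, key: BucketKey, value: float) -> float:
    """Right-continuous ECDF: fraction of stored samples <= value
    (up to a 1e-9 tie tolerance).

    A missing bucket falls back to the nearest populated one (cached).
    """
    samples = table.samples.get(key)
    if samples is None or len(samples) == 0:
        if not table.samples:
            raise ValueError("ECDF table has no populated buckets")
        alt = table._fallback_cache.get(key)
        if alt is None:
            alt = _nearest_key(table, key)
            table._fallback_cache[key] = alt
        samples = table.samples[alt]
    return float(np.searchsorted(samples, value + _ECDF_EPS, side="right")) / len(samples)
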