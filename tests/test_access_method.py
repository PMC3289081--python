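import numpy as np
import pytest

from oracles import brute_force_knn
from sprot.access_method import (
    PivotIndex,
    RBQModifier,
    SearchParams,
    build_pivot_index,
    estimation_error_probability,
    knn_search,
    lower_bound,
    rbq_apply,
    retrieval_error,
    scop_retrieval_error,
    select_pivots,
    sequential_scan,
)


# ------------------------------------------------------------------ modifier


@pytest.mark.parametrize("w", [0.0, 0.5, 1.0, 4.0])
def test_rbq_endpoints(w):
    mod = RBQModifier(w=w)
    assert rbq_apply(mod, 0.0) == pytest.approx(0.0, abs=1e-9)
    assert rbq_apply(mod, 1.0) == pytest.approx(1.0, abs=1e-9)


def test_rbq_weight_zero_is_identity():
    mod = RBQModifier(w=0.0)
    grid = np.linspace(0, 1, 1001)
    np.testing.assert_allclose(rbq_apply(mod, grid), grid, atol=1e-9)


@pytest.mark.parametrize("w", [0.5, 1.0, 4.0])
def test_rbq_strictly_increasing(w):
    mod = RBQModifier(w=w)
    grid = np.linspace(0, 1, 2001)
    vals = rbq_apply(mod, grid)
    assert np.all(np.diff(vals) > 0)
    assert np.all((vals >= -1e-12) & (vals <= 1 + 1e-12))


def test_rbq_against_curve_sampling_oracle():
    # dense parametric sampling of the rational Bezier curve
    w = 4.0
    t = np.linspace(0, 1, 1_000_001)
    mid = 2 * w * t * (1 - t)
    denom = (1 - t) ** 2 + mid + t**2
    x = (mid * 0.7 + t**2) / denom
    y = (mid * 0.15 + t**2) / denom
    for d in (0.3, 0.7, 0.95):
        expect = y[np.argmin(np.abs(x - d))]
        assert rbq_apply(RBQModifier(w=w), d) == pytest.approx(expect, abs=1e-5)


def test_rbq_rejects_out_of_range():
    with pytest.raises(ValueError):
        rbq_apply(RBQModifier(w=1.0), 1.5)
    with pytest.raises(ValueError):
        RBQModifier(w=-1.0)


# --------------------------------------------------------------- lower bound


def test_lower_bound_examples():
    assert lower_bound(5, 5, 2, 2) == 3  # symmetric case: |d(q,p) - d(p,o)|
    assert lower_bound(0.5, 0.4, 0.2, 0.1) == pytest.approx(0.4)
    assert lower_bound(0.3, 0.3, 0.3, 0.3) == 0.0  # q = o style inputs


def test_lower_bound_valid_on_metric_space():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 1, size=(50, 2))

    def d(i, j):
        return float(np.linalg.norm(pts[i] - pts[j]))

    for q in range(0, 50, 7):
        for p in range(0, 50, 11):
            for o in range(0, 50, 5):
                assert lower_bound(d(q, p), d(p, q), d(p, o), d(o, p)) <= d(q, o) + 1e-12


# --------------------------------------------------------------------- index


def _euclidean_toy(n=200, seed=2):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1, size=(n, 2))
    ids = list(range(n))

    def dist_pair(a, b):
        d = float(np.linalg.norm(pts[a] - pts[b]) / np.sqrt(2))  # scale into [0,1]
        return d, d

    return ids, pts, dist_pair


def test_build_index_shapes_and_self_distance():
    ids, _, dist_pair = _euclidean_toy(5)
    idx = build_pivot_index(ids, [0, 3], dist_pair)
    assert idx.d_po.shape == idx.d_op.shape == (2, 5)
    assert idx.d_po[0, 0] == idx.d_op[0, 0] == 0.0
    assert idx.d_po[1, 3] == 0.0
    with pytest.raises(ValueError):
        build_pivot_index(ids, [], dist_pair)
    with pytest.raises(ValueError):
        build_pivot_index(ids, [99], dist_pair)


def test_index_round_trip_and_fingerprint(tmp_path):
    ids, _, dist_pair = _euclidean_toy(8)
    idx = build_pivot_index(ids, [0, 4], dist_pair, RBQModifier(w=1.0), fingerprint="toy-v1")
    path = tmp_path / "idx.json"
    idx.save(path)
    back = PivotIndex.load(path, expect_fingerprint="toy-v1")
    np.testing.assert_array_equal(back.d_po, idx.d_po)
    np.testing.assert_array_equal(back.d_op, idx.d_op)
    assert back.modifier == idx.modifier
    with pytest.raises(ValueError):
        PivotIndex.load(path, expect_fingerprint="other")
    # determinism: rebuilding serializes byte-identically
    idx2 = build_pivot_index(ids, [0, 4], dist_pair, RBQModifier(w=1.0), fingerprint="toy-v1")
    path2 = tmp_path / "idx2.json"
    idx2.save(path2)
    assert path.read_bytes() == path2.read_bytes()


def test_select_pivots_one_per_family():
    labels = {"s1": "A", "s2": "A", "s3": "B", "s4": "C", "s5": "B"}
    pivots = select_pivots(labels.keys(), labels=labels)
    assert pivots == ["s1", "s3", "s4"]


def test_select_pivots_maxmin_without_labels():
    ids, pts, dist_pair = _euclidean_toy(30, seed=9)
    pivots = select_pivots(ids, n_pivots=4, distance=lambda a, b: dist_pair(a, b)[0], seed=3)
    assert len(set(pivots)) == 4


# -------------------------------------------------------------------- search


def test_knn_exact_on_metric_space():
    ids, pts, dist_pair = _euclidean_toy(200, seed=2)
    pivots = select_pivots(ids, n_pivots=20, distance=lambda a, b: dist_pair(a, b)[0], seed=0)
    idx = build_pivot_index(ids, pivots, dist_pair)
    rng = np.random.default_rng(7)
    for k in (1, 5, 10):
        for qseed in range(3):
            q = rng.uniform(0, 1, 2)

            def qdist(_, oid):
                d = float(np.linalg.norm(q - pts[oid]) / np.sqrt(2))
                return d, d

            res = knn_search(idx, "q", SearchParams(k=k, v=0.0, r=0), qdist)
            expect = brute_force_knn(ids, "q", k, lambda _, oid: qdist(None, oid)[0])
            assert res.ids == expect
            assert res.n_distance_computations <= len(ids)


def test_knn_whole_database():
    ids, pts, dist_pair = _euclidean_toy(30, seed=4)
    idx = build_pivot_index(ids, [0, 7, 19], dist_pair)
    res = knn_search(idx, 3, SearchParams(k=30, v=0.0, r=0), lambda q, o: dist_pair(q, o))
    assert sorted(res.ids) == ids
    dists = [d for _, d in res.items]
    assert dists == sorted(dists)
    assert res.items[0][0] == 3  # the query object itself at distance 0


def test_knn_huge_v_equals_sequential_scan():
    ids, pts, dist_pair = _euclidean_toy(60, seed=6)
    idx = build_pivot_index(ids, [0, 30], dist_pair)
    res = knn_search(idx, 5, SearchParams(k=8, v=1e9, r=0), lambda q, o: dist_pair(q, o))
    scan = sequential_scan(ids, 5, 8, lambda q, o: dist_pair(q, o))
    assert res.ids == scan.ids
    assert res.n_distance_computations == len(ids)


def test_knn_validates_k():
    ids, pts, dist_pair = _euclidean_toy(10, seed=1)
    idx = build_pivot_index(ids, [0], dist_pair)
    with pytest.raises(ValueError):
        knn_search(idx, 0, SearchParams(k=11), lambda q, o: dist_pair(q, o))


# -------------------------------------------------------------------- errors


def test_retrieval_error_cases():
    assert retrieval_error([1, 2, 3], [1, 2, 3]) == 0.0
    assert retrieval_error(list(range(8)), list(range(10))) == 20.0
    assert retrieval_error([11, 12], [1, 2]) == 100.0
    with pytest.raises(ValueError):
        retrieval_error([1], [])


def test_scop_retrieval_error_cases():
    assert scop_retrieval_error([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4]) == 0.0
    assert scop_retrieval_error([], [1, 2], [1, 2]) == 100.0
    assert scop_retrieval_error([1, 2, 3], [1, 2, 3, 4], [1, 2, 3, 4]) == 25.0
    assert scop_retrieval_error([1], [1, 2], [99]) is None  # no relevant reference


def test_estimation_error_probability_worked_example():
    # 1 - (1 - 1e-4)^1000 as a percentage
    assert estimation_error_probability(1e-4, 1000) == pytest.approx(9.5, abs=0.05)
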