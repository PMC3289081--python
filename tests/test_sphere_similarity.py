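import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_ca_chain
from oracles import enumerate_matchings_zero_gap, grid_min_rmsd
from sprot.calibration import ECDFTable, bucket_key
from sprot.fixtures import make_backbone
from sprot.sphere_model import QuantityCharacteristics, build_aa_sphere, build_all_spheres
from sprot.sphere_similarity import (
    SphereParams,
    align_neighborhoods,
    kabsch_superposition,
    quantity_factor,
    seed_backbone_alignment,
    sm_raw,
    sm_raw_value,
    sm_score,
)

PARAMS = SphereParams()


# ------------------------------------------------------------- seed alignment


def test_seed_alignment_identity():
    st = make_ca_chain([[3.8 * i, 0, 0] for i in range(9)])
    s = build_aa_sphere(st, 4, 9.0)
    pairs = seed_backbone_alignment(s, s)
    assert pairs == [(2, 2), (3, 3), (4, 4), (5, 5), (6, 6)]


def test_seed_alignment_truncates_gaplessly():
    st = make_ca_chain([[3.8 * i, 0, 0] for i in range(30)])
    spheres = build_all_spheres(st, 9.0)
    x, y = spheres[3], spheres[25]
    # x has a short upstream side, y a short downstream side
    k_ub = min(x.qc.q_ub, y.qc.q_ub)
    k_db = min(x.qc.q_db, y.qc.q_db)
    pairs = seed_backbone_alignment(x, y)
    assert len(pairs) == 1 + k_ub + k_db
    assert (x.center_index, y.center_index) in pairs
    di = [i2 - i1 for (i1, _), (i2, _) in zip(pairs, pairs[1:])]
    dj = [j2 - j1 for (_, j1), (_, j2) in zip(pairs, pairs[1:])]
    assert all(d == 1 for d in di + dj)


def test_seed_alignment_empty_backbones():
    x = build_aa_sphere(make_ca_chain([[0, 0, 0]]), 0, 9.0)
    assert seed_backbone_alignment(x, x) == [(0, 0)]


# ------------------------------------------------------------------- kabsch


def test_kabsch_identity():
    X = np.random.default_rng(0).normal(size=(6, 3))
    sup = kabsch_superposition(X, X)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(sup.translation, 0, atol=1e-12)
    assert sup.rmsd == pytest.approx(0, abs=1e-12)


def test_kabsch_recovers_exact_rigid_motion():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(8, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Y = (X - [1, 2, 3]) @ R.T  # X = R^-1 Y ... arbitrary rigid motion
    sup = kabsch_superposition(X, Y)
    np.testing.assert_allclose(sup.apply(Y), X, atol=1e-9)
    assert sup.rmsd < 1e-9
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_beats_rotation_grid_oracle():
    rng = np.random.default_rng(42)
    X = rng.normal(scale=3.0, size=(6, 3))
    Y = X + rng.normal(scale=0.3, size=(6, 3))
    sup = kabsch_superposition(X, Y)
    assert sup.rmsd <= grid_min_rmsd(X, Y, step_deg=4.0) + 1e-3


def test_kabsch_degenerate_inputs():
    sup = kabsch_superposition([[1.0, 2.0, 3.0]], [[0.0, 0.0, 1.0]])
    np.testing.assert_allclose(sup.rotation, np.eye(3))
    np.testing.assert_allclose(sup.translation, [1, 2, 2])
    with pytest.raises(ValueError):
        kabsch_superposition(np.zeros((0, 3)), np.zeros((0, 3)))


# ------------------------------------------------------- neighborhood align


def test_align_neighborhoods_empty():
    st = make_ca_chain([[3.8 * i, 0, 0] for i in range(9)])
    s = build_aa_sphere(st, 4, 9.0)
    sup = kabsch_superposition(st.ca_coords[2:7], st.ca_coords[2:7])
    assert len(align_neighborhoods(s, s, sup, PARAMS)) == 0


def test_align_neighborhoods_identity_scores_one():
    st = make_backbone("mixed", 40, seed=5)
    spheres = build_all_spheres(st, 9.0)
    s = next(s for s in spheres if s.qc.q_un > 0 or s.qc.q_dn > 0)
    sup = kabsch_superposition([[0.0, 0, 0]], [[0.0, 0, 0]])  # identity
    aln = align_neighborhoods(s, s, sup, PARAMS)
    assert len(aln) == s.qc.q_un + s.qc.q_dn
    assert all(i == j for i, j in aln.pairs)
    np.testing.assert_allclose(aln.distances, 0, atol=1e-12)


def test_neighborhood_dp_matches_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(20):
        nx, ny = rng.integers(1, 6, size=2)
        D = rng.uniform(0, 8, size=(nx, ny))
        S = 1.0 / (1.0 + (D / PARAMS.d_s) ** 2)
        from sprot._nw import nw_align

        pairs, score = nw_align(S, 0.0)
        assert score == pytest.approx(enumerate_matchings_zero_gap(S), abs=1e-12)
        assert score == pytest.approx(sum(S[i, j] for i, j in pairs), abs=1e-12)


# ------------------------------------------------------------------- sm_raw


def test_sm_raw_self_is_one(benchmark_dataset):
    st = benchmark_dataset[4]
    for s in build_all_spheres(st, 9.0)[::5]:
        r = sm_raw(s, s, PARAMS)
        assert r.sm_raw == pytest.approx(1.0, abs=1e-12)
        assert len(r.alignment) == r.max_norm


def test_sm_raw_subset_sphere_reaches_max():
    # deleting non-backbone members leaves a sphere scoring 1 against its parent
    st = make_backbone("mixed", 40, seed=8)
    spheres = build_all_spheres(st, 9.0)
    z = next(s for s in spheres if s.qc.q_un > 0)
    import copy

    w = copy.deepcopy(z)
    w.upstream_neighborhood = []
    w.up_nb_coords = w.protein_ca[[]]
    w.qc = QuantityCharacteristics(z.qc.q_ub, z.qc.q_db, 0, z.qc.q_dn)
    r = sm_raw(w, z, PARAMS)
    assert r.sm_raw == pytest.approx(1.0, abs=1e-12)
    assert quantity_factor(w.qc, z.qc) < 1.0


def test_sm_raw_rigid_invariance():
    st = make_backbone("mixed", 35, seed=2)
    rng = np.random.default_rng(9)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    moved = make_ca_chain(st.ca_coords @ R.T + t)
    orig = make_ca_chain(st.ca_coords)
    sx = build_all_spheres(orig, 9.0)
    sy = build_all_spheres(moved, 9.0)
    for i in range(0, 35, 4):
        a = sm_raw(sx[i], sy[i], PARAMS).sm_raw
        assert a == pytest.approx(1.0, abs=1e-9)


def test_sm_raw_matches_recompute_from_parts():
    st1 = make_backbone("mixed", 30, seed=13)
    st2 = make_backbone("mixed", 32, seed=14)
    s1 = build_all_spheres(st1, 9.0)
    s2 = build_all_spheres(st2, 9.0)
    for i, j in [(4, 7), (10, 20), (25, 15)]:
        r = sm_raw(s1[i], s2[j], PARAMS)
        # independent straight-line recomputation from the stored pairs
        expect = sum(1.0 / (1.0 + (d / PARAMS.d_s) ** 2) for d in r.alignment.distances) / r.max_norm
        assert r.sm_raw == pytest.approx(expect, rel=1e-12)
        assert r.sm_raw == pytest.approx(sm_raw_value(s1[i], s2[j], PARAMS.d_s), rel=1e-12)
        assert 0 < r.sm_raw <= 1


# --------------------------------------------------------------- f, sm_score


def test_quantity_factor_examples():
    q = QuantityCharacteristics
    assert quantity_factor(q(2, 2, 0, 0), q(2, 2, 0, 0)) == 1.0
    assert quantity_factor(q(2, 2, 0, 0), q(2, 2, 2, 2)) == pytest.approx(1 / 9)
    assert quantity_factor(q(0, 1, 5, 4), q(0, 1, 5, 4)) == 1.0
    # strictly decreasing as a category diverges
    assert quantity_factor(q(2, 2, 0, 0), q(2, 3, 0, 0)) > quantity_factor(q(2, 2, 0, 0), q(2, 4, 0, 0))


def test_sm_score_hand_computed_toy_table():
    st = make_ca_chain([[3.8 * i, 0, 0] for i in range(9)])
    s = build_aa_sphere(st, 4, 9.0)
    key = bucket_key(s.qc, s.qc)
    table = ECDFTable({key: np.array([0.2, 0.4, 0.4, 0.9])})
    r = sm_score(s, s, PARAMS, table)
    # sm_raw(s, s) = 1.0 -> all 4 samples below -> ECDF = 1; f = 1
    assert r.sm_score == pytest.approx(1.0)
    table2 = ECDFTable({key: np.array([0.2, 0.4, 0.4, 0.9, 1.0 + 1e-6])})
    r2 = sm_score(s, s, PARAMS, table2)
    assert r2.sm_score == pytest.approx(4 / 5)


def test_sm_score_bounded_by_quantity_factor(measure, benchmark_dataset):
    table = measure.ecdf_table
    sx = build_all_spheres(benchmark_dataset[0], 9.0)
    sy = build_all_spheres(benchmark_dataset[5], 9.0)
    for i, j in [(0, 0), (5, 9), (20, 30)]:
        r = sm_score(sx[i], sy[j], PARAMS, table)
        assert 0.0 <= r.sm_score <= quantity_factor(sx[i].qc, sy[j].qc) + 1e-12
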