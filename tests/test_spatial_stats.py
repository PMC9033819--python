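import numpy as np
import pytest

import maeeqe as m
from maeeqe.spatial_stats import ZeroVarianceError
from conftest import full_lattice, naive_global_moran, naive_local_moran


def test_resample_identity_and_mean():
    g = m.Grid(np.array([[1.0, 2.0], [3.0, 4.0]]), np.zeros((2, 2), bool),
               cell_size=100.0)
    ident = m.resample_to_units(g, 100.0)
    assert ident.values.tolist() == [1, 2, 3, 4]
    agg = m.resample_to_units(g, 200.0)
    assert agg.values.tolist() == [2.5]


def test_resample_coverage_rule():
    mask = np.array([[False, True], [True, True]])
    g = m.Grid(np.ones((2, 2)), mask, cell_size=100.0)
    with pytest.raises(ValueError):
        m.resample_to_units(g, 200.0, min_coverage=0.5)  # 1/4 valid -> dropped
    kept = m.resample_to_units(g, 200.0, min_coverage=0.25)
    assert kept.n == 1 and kept.coverage[0] == pytest.approx(0.25)


def test_resample_requires_multiple():
    g = m.Grid(np.ones((2, 2)), np.zeros((2, 2), bool), cell_size=100.0)
    with pytest.raises(ValueError):
        m.resample_to_units(g, 150.0)


def test_contiguity_neighbor_counts():
    lat = full_lattice(np.arange(9.0).reshape(3, 3))
    queen = m.build_weights(lat, "queen")
    rook = m.build_weights(lat, "rook")
    center = 4
    assert len(queen.neighbors[center]) == 8
    assert len(rook.neighbors[center]) == 4
    for W in (queen, rook):
        for i, (nb, w) in enumerate(zip(W.neighbors, W.weights)):
            assert i not in nb            # no self-neighbors
            assert w.sum() == pytest.approx(1.0)  # row standardized
            for j in nb:                  # symmetric relation
                assert i in W.neighbors[j]


def test_two_adjacent_units_give_minus_one():
    lat = full_lattice(np.array([[1.0, 5.0]]))
    W = m.build_weights(lat)
    res = m.global_moran(lat.values, W, n_perm=9, seed=0)
    assert res.I == pytest.approx(-1.0)


def test_rook_checkerboard_gives_minus_one():
    board = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
    lat = full_lattice(board)
    W = m.build_weights(lat, "rook")
    res = m.global_moran(lat.values, W, n_perm=99, seed=1)
    assert res.I == pytest.approx(-1.0)
    assert res.expected_I == pytest.approx(-1.0 / 15)


def test_global_moran_matches_naive_oracle(rng):
    for scheme in ("queen", "rook"):
        lat = full_lattice(rng.random((5, 5)))
        W = m.build_weights(lat, scheme)
        res = m.global_moran(lat.values, W, n_perm=0 + 9, seed=0)
        assert res.I == pytest.approx(naive_global_moran(lat.values, W),
                                      abs=1e-12)


def test_local_moran_matches_naive_oracle_and_mean_property(rng):
    lat = full_lattice(rng.random((5, 5)))
    W = m.build_weights(lat)
    lisa = m.local_moran(lat.values, W, n_perm=99, seed=3)
    assert np.allclose(lisa.local_i, naive_local_moran(lat.values, W),
                       atol=1e-12)
    glob = m.global_moran(lat.values, W, n_perm=9, seed=0)
    # with row-standardized weights the local statistics average to I
    assert lisa.local_i.mean() == pytest.approx(glob.I, abs=1e-12)


def test_local_moran_zero_deviation_unit():
    vals = np.array([[0.0, 1.0, 2.0]])  # middle unit sits at the mean
    lat = full_lattice(vals)
    W = m.build_weights(lat)
    lisa = m.local_moran(lat.values, W, n_perm=9, seed=0)
    assert lisa.local_i[1] == pytest.approx(0.0)


def test_checkerboard_local_all_negative_outliers():
    board = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
    lat = full_lattice(board)
    W = m.build_weights(lat, "rook")
    lisa = m.local_moran(lat.values, W, n_perm=99, seed=5)
    assert np.all(lisa.local_i < 0)
    assert set(lisa.quadrant) <= {"H-L", "L-H"}


def test_quadrant_definition():
    # high unit whose only neighbor is also high -> H-H
    vals = np.array([[5.0, 6.0, 0.0]])
    lat = full_lattice(vals)
    W = m.build_weights(lat)
    lisa = m.local_moran(lat.values, W, n_perm=9, seed=0)
    assert lisa.quadrant[0] == "H-H"


def test_permutation_reproducible_and_relabel_invariant(rng):
    vals = rng.random((4, 4))
    lat = full_lattice(vals)
    W = m.build_weights(lat)
    a = m.global_moran(lat.values, W, n_perm=199, seed=7)
    b = m.global_moran(lat.values, W, n_perm=199, seed=7)
    assert a.p_value == b.p_value and a.z_score == b.z_score
    la = m.local_moran(lat.values, W, n_perm=99, seed=7)
    lb = m.local_moran(lat.values, W, n_perm=99, seed=7)
    assert np.array_equal(la.p_value, lb.p_value)


def test_constant_surface_rejected():
    lat = full_lattice(np.ones((3, 3)))
    W = m.build_weights(lat)
    with pytest.raises(ZeroVarianceError):
        m.global_moran(lat.values, W, 9, 0)
    with pytest.raises(ZeroVarianceError):
        m.local_moran(lat.values, W, 9, seed=0)


def test_smoothed_noise_detected_as_clustered():
    """Positive spatial autocorrelation from smoothing is detected at
    n = 400 in at least 19 of 20 seeded replicates."""
    hits = 0
    for seed in range(20):
        field = m.gaussian_field((20, 20), autocorr_range=3, seed=seed)
        lat = full_lattice(field.values)
        W = m.build_weights(lat)
        res = m.global_moran(lat.values, W, n_perm=199, seed=seed)
        if res.I > 0 and res.p_value <= 0.05:
            hits += 1
    assert hits >= 19
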