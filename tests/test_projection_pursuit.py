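import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import maeeqe as m
from maeeqe.projection_pursuit import ConstraintError


def naive_objective(x, c, R):
    """Literal Eqs: S with n-1 denominator, double sum incl. i == j,
    strict step function."""
    v = x @ c
    n = len(v)
    S = v.std(ddof=1)
    D = 0.0
    for i in range(n):
        for j in range(n):
            r = abs(v[i] - v[j])
            if r < R:
                D += R - r
    return S, D, S * D


def test_projection_basis_vector_and_arithmetic():
    x = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert m.project(x, [1.0, 0.0]).tolist() == [1.0, 0.0]
    assert np.allclose(m.project(x, [0.6, 0.8]), [0.6, 0.8])


def test_projection_constraint_errors():
    x = np.ones((3, 2))
    with pytest.raises(ConstraintError):
        m.project(x, [1.0, 1.0])  # |c|^2 = 2
    with pytest.raises(ValueError):
        m.project(x, [1.0, 0.0, 0.0])


def test_objective_two_point_hand_value():
    x = np.array([[0.0], [1.0]]) @ np.array([[1.0, 0.0]])
    obj = m.objective(x, np.array([1.0, 0.0]), R=0.5)
    assert obj.S == pytest.approx(0.70711, abs=1e-5)
    assert obj.D == pytest.approx(1.0)       # only the two diagonal terms
    assert obj.Q == pytest.approx(0.70711, abs=1e-5)


def test_constant_projection_gives_zero_q():
    x = np.full((5, 2), 0.3)
    obj = m.objective(x, np.array([1.0, 0.0]), R=0.1)
    assert obj.S == 0 and obj.Q == 0


def test_invalid_radius():
    with pytest.raises(ValueError):
        m.objective(np.random.default_rng(0).random((4, 2)),
                    np.array([1.0, 0.0]), R=-1.0)


def test_density_matches_naive_double_sum(rng):
    x = rng.random((40, 3))
    c = rng.normal(size=3)
    c /= np.linalg.norm(c)
    for R in (0.05, 0.2, 1.0):
        S, D, Q = naive_objective(x, c, R)
        obj = m.objective(x, c, R)
        assert obj.S == pytest.approx(S, rel=1e-12)
        assert obj.D == pytest.approx(D, rel=1e-9)
        assert obj.Q == pytest.approx(Q, rel=1e-9)


def test_density_monotone_in_radius(rng):
    x = rng.random((30, 2))
    c = np.array([0.6, 0.8])
    ds = [m.objective(x, c, R).D for R in (0.05, 0.1, 0.2, 0.5, 1.0)]
    assert all(a <= b for a, b in zip(ds, ds[1:]))


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_q_symmetric_under_sign_flip(seed):
    rng = np.random.default_rng(seed)
    x = rng.random((15, 3))
    c = rng.normal(size=3)
    c /= np.linalg.norm(c)
    assert m.objective(x, c).Q == pytest.approx(m.objective(x, -c).Q, rel=1e-12)


def test_weights_from_direction():
    u = m.weights_from_direction([0.6, 0.8])
    assert np.allclose(u, [0.36, 0.64])
    assert np.allclose(m.weights_from_direction([-0.6, -0.8]), u)
    with pytest.raises(ConstraintError):
        m.weights_from_direction([1.0, 1.0])


def test_published_weight_table_sums_to_one():
    # the 13-indicator weight table of the source study
    table = [0.026, 0.027, 0.069, 0.076, 0.125, 0.076, 0.076,
             0.086, 0.075, 0.084, 0.089, 0.070, 0.121]
    assert sum(table) == pytest.approx(1.000, abs=1e-9)


def _bimodal_problem(seed, n=120):
    rng = np.random.default_rng(seed)
    informative = np.concatenate([rng.normal(0.1, 0.03, n // 2),
                                  rng.normal(0.9, 0.03, n // 2)])
    noise = rng.random(n) * 0.05 + 0.5
    return np.column_stack([informative, noise])


def test_ga_recovers_informative_indicator_and_matches_sweep():
    x = _bimodal_problem(3)
    params = m.GAParams(population_size=80, elite_count=20,
                        max_generations=60, seed=5)
    res = m.optimize_direction(x, params)
    assert res.weights[0] > 0.99
    sweep = m.sweep_2d(x, n_angles=10_000)
    assert res.best_Q >= 0.999 * sweep.best_Q


def test_ga_determinism_and_trace_monotone():
    x = _bimodal_problem(1, n=60)
    params = m.GAParams(population_size=40, elite_count=10,
                        max_generations=30, seed=9)
    a = m.optimize_direction(x, params)
    b = m.optimize_direction(x, params)
    assert np.array_equal(a.direction, b.direction)
    assert a.best_Q == b.best_Q
    assert np.all(np.diff(a.trace) >= 0)
    assert np.isclose(a.weights.sum(), 1.0, atol=1e-9)
    assert (a.weights >= 0).all()


def test_more_generations_never_worse():
    x = _bimodal_problem(2, n=60)
    short = m.optimize_direction(x, m.GAParams(population_size=30, elite_count=5,
                                               max_generations=5, seed=4,
                                               stall_generations=1000))
    long = m.optimize_direction(x, m.GAParams(population_size=30, elite_count=5,
                                              max_generations=25, seed=4,
                                              stall_generations=1000))
    assert long.best_Q >= short.best_Q


def test_degenerate_matrix_warns():
    x = np.full((10, 2), 0.7)
    with pytest.warns(UserWarning, match="degenerate"):
        m.optimize_direction(x, m.GAParams(population_size=10, elite_count=2,
                                           max_generations=3, seed=0))
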