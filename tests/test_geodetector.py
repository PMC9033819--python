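import itertools

import numpy as np
import pandas as pd
import pytest

import maeeqe as m


def groupby_q(y, labels):
    """Independent 1 - SSW/SST via pandas groupby."""
    df = pd.DataFrame({"y": y, "g": labels})
    sst = ((df.y - df.y.mean()) ** 2).sum()
    ssw = df.groupby("g").y.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
    return 1 - ssw / sst


def test_stratify_categorical_two_types():
    s = m.stratify(["mined", "unmined", "mined"], method="categorical")
    assert s.L == 2
    assert s.labels.tolist() == [0, 1, 0]


def test_stratify_natural_breaks_matches_jenks():
    s = m.stratify([1, 2, 3, 10, 11, 12], k=2)
    assert s.L == 2
    assert s.labels.tolist() == [0, 0, 0, 1, 1, 1]
    with pytest.raises(ValueError):
        m.stratify([1.0, 1.0, 2.0], k=3)


def test_q_hand_value():
    strat = m.Stratification(np.array([0, 0, 1, 1]), 2, "categorical")
    det = m.factor_q([1.0, 2.0, 3.0, 4.0], strat, n_perm=0)
    assert det.q == pytest.approx(0.8)    # SST = 5, SSW = 1
    assert det.SST == pytest.approx(5.0)
    assert det.SSW == pytest.approx(1.0)


def test_q_limits_pure_and_single_stratum():
    y = np.array([1.0, 1.0, 4.0, 4.0, 9.0, 9.0])
    pure = m.Stratification(np.array([0, 0, 1, 1, 2, 2]), 3, "categorical")
    assert m.factor_q(y, pure, n_perm=0).q == pytest.approx(1.0)
    single = m.Stratification(np.zeros(6, dtype=int), 1, "categorical")
    assert m.factor_q(y, single, n_perm=0).q == pytest.approx(0.0)


def test_q_zero_variance_rejected():
    strat = m.Stratification(np.array([0, 1]), 2, "categorical")
    with pytest.raises(ValueError):
        m.factor_q([2.0, 2.0], strat, n_perm=0)


def test_q_matches_groupby_oracle(rng):
    for _ in range(10):
        y = rng.normal(size=60)
        labels = rng.integers(0, 5, size=60)
        strat = m.Stratification(labels, int(labels.max()) + 1, "categorical")
        assert m.factor_q(y, strat, n_perm=0).q == pytest.approx(
            groupby_q(y, labels), abs=1e-12)


def test_q_invariant_to_relabeling_and_within_permutation(rng):
    y = rng.normal(size=50)
    labels = rng.integers(0, 4, size=50)
    strat = m.Stratification(labels, 4, "categorical")
    q0 = m.factor_q(y, strat, n_perm=0).q
    # monotone relabeling of strata
    relabeled = m.Stratification(3 - labels, 4, "categorical")
    assert m.factor_q(y, relabeled, n_perm=0).q == pytest.approx(q0, abs=1e-12)
    # permuting samples within strata
    perm = np.arange(50)
    for g in range(4):
        idx = np.nonzero(labels == g)[0]
        perm[idx] = rng.permutation(idx)
    assert m.factor_q(y[perm], strat, n_perm=0).q == pytest.approx(q0, abs=1e-12)


def test_merging_strata_never_increases_q(rng):
    for _ in range(10):
        y = rng.normal(size=40)
        labels = rng.integers(0, 4, size=40)
        strat = m.Stratification(labels, 4, "categorical")
        merged_labels = np.where(labels == 3, 2, labels)
        merged = m.Stratification(merged_labels, 3, "categorical")
        assert (m.factor_q(y, merged, n_perm=0).q
                <= m.factor_q(y, strat, n_perm=0).q + 1e-12)


def test_cross_stratification_refines_hence_q12_at_least_max(rng):
    y = rng.normal(size=80)
    a = m.Stratification(rng.integers(0, 3, 80), 3, "categorical")
    b = m.Stratification(rng.integers(0, 4, 80), 4, "categorical")
    res = m.interaction_detect(y, a, b)
    assert res.q12 >= max(res.q1, res.q2) - 1e-12


@pytest.mark.parametrize("q1,q2,q12,expected", [
    (0.3, 0.4, 0.8, "nonlinear enhancement"),
    (0.3, 0.4, 0.2, "nonlinear attenuation"),
    (0.3, 0.4, 0.65, "bilinear enhancement"),
    (0.3, 0.4, 0.35, "single-linear attenuation"),
    (0.3, 0.4, 0.7, "mutual independence"),
])
def test_interaction_classification(q1, q2, q12, expected):
    assert m.classify_interaction(q1, q2, q12) == expected


def test_exactly_one_branch_fires(rng):
    types = {"nonlinear attenuation", "single-linear attenuation",
             "bilinear enhancement", "mutual independence",
             "nonlinear enhancement"}
    for _ in range(200):
        q1, q2, q12 = rng.random(3)
        assert m.classify_interaction(q1, q2, q12) in types


def test_welch_t_hand_value():
    y = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
    strat = m.Stratification(np.array([0, 0, 0, 1, 1, 1]), 2, "categorical")
    risk = m.risk_detect(y, strat)
    pair = risk.pairs.iloc[0]
    # equal variances 1, mean gap 1, se = sqrt(2/3)
    assert pair.t == pytest.approx(-1.2247, abs=1e-4)
    assert not pair.significant


def test_welch_matches_textbook_formula(rng):
    g1, g2 = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
    y = np.concatenate([g1, g2])
    strat = m.Stratification(np.repeat([0, 1], [12, 9]), 2, "categorical")
    pair = m.risk_detect(y, strat).pairs.iloc[0]
    se = np.sqrt(g1.var(ddof=1) / 12 + g2.var(ddof=1) / 9)
    assert pair.t == pytest.approx((g1.mean() - g2.mean()) / se, rel=1e-12)


def test_identical_strata_t_zero():
    y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    strat = m.Stratification(np.repeat([0, 1], 3), 2, "categorical")
    pair = m.risk_detect(y, strat).pairs.iloc[0]
    assert pair.t == pytest.approx(0.0)


def test_separated_strata_significant(rng):
    y = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(1, 0.01, 10)])
    strat = m.Stratification(np.repeat([0, 1], 10), 2, "categorical")
    pair = m.risk_detect(y, strat).pairs.iloc[0]
    assert abs(pair.t) > 50 and pair.significant


def test_risk_skips_tiny_strata():
    y = np.array([1.0, 2.0, 3.0, 9.0])
    strat = m.Stratification(np.array([0, 0, 0, 1]), 2, "categorical")
    with pytest.warns(UserWarning, match="skipped"):
        risk = m.risk_detect(y, strat)
    assert risk.pairs.empty


def test_q_permutation_p_significant_for_strong_effect(rng):
    y, expected = m.make_stratified_response(
        m.Stratification(np.repeat([0, 1], 200), 2, "categorical"),
        means=[0.0, 2.0], sd=1.0, seed=3)
    strat = m.Stratification(np.repeat([0, 1], 200), 2, "categorical")
    det = m.factor_q(y, strat, n_perm=199, seed=1)
    assert det.p_value <= 0.01
    assert det.q == pytest.approx(expected, abs=0.1)
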