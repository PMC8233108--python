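"""Group-consensus networks and edge-weight regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myeloconn import (
    Cohort,
    WeightedConnectome,
    consensus_mask,
    consensus_weights,
    edge_regression,
)


def make_cohort(nos_list, scalar_list=None):
    nodes = np.arange(1, nos_list[0].shape[0] + 1)
    subjects = []
    for k, w in enumerate(nos_list):
        sca = (scalar_list[k] if scalar_list is not None
               else np.where(w != 0, 1.1, 0.0))
        subjects.append((
            WeightedConnectome(nodes, w, kind="nos"),
            WeightedConnectome(nodes, sca, kind="scalar"),
        ))
    return Cohort(subjects)


def edge_matrix(n, entries):
    w = np.zeros((n, n))
    for (i, j), v in entries.items():
        w[i, j] = w[j, i] = v
    return w


def test_mask_ceiling_rule_four_subjects():
    mats = [edge_matrix(3, {(0, 1): 2}), edge_matrix(3, {(0, 1): 3}),
            edge_matrix(3, {(0, 2): 1}), edge_matrix(3, {(1, 2): 1})]
    cohort = make_cohort(mats)
    mask = consensus_mask(cohort, prevalence=0.5)  # threshold ceil(2) = 2
    assert mask[0, 1] and not mask[0, 2] and not mask[1, 2]


def test_mask_threshold_for_35_subjects_is_18():
    import math
    assert math.ceil(0.5 * 35) == 18
    rng = np.random.default_rng(0)
    mats = []
    for s in range(35):
        w = np.zeros((4, 4))
        if s < 18:
            w[0, 1] = w[1, 0] = 1  # present in exactly 18 subjects
        if s < 17:
            w[2, 3] = w[3, 2] = 1  # present in 17: below threshold
        mats.append(w)
    mask = consensus_mask(make_cohort(mats), prevalence=0.5)
    assert mask[0, 1] and not mask[2, 3]


def test_edge_present_everywhere_survives_any_prevalence():
    mats = [edge_matrix(3, {(0, 1): v}) for v in (1, 2, 3)]
    cohort = make_cohort(mats)
    assert consensus_mask(cohort, prevalence=1.0)[0, 1]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_mask_monotone_in_prevalence(seed):
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(6):
        w = np.triu(rng.integers(0, 3, size=(5, 5)), 1).astype(float)
        mats.append(w + w.T)
    cohort = make_cohort(mats)
    prev = consensus_mask(cohort, prevalence=0.25)
    for p in (0.5, 0.75, 1.0):
        cur = consensus_mask(cohort, prevalence=p)
        assert not np.any(cur & ~prev)  # raising prevalence never adds edges
        prev = cur


def test_presence_only_median():
    mats = [edge_matrix(3, {(0, 1): v}) for v in (0, 3, 5, 0)]
    cohort = make_cohort(mats)
    mask = consensus_mask(cohort, prevalence=0.5)
    nos, _ = consensus_weights(cohort, mask)
    assert nos.weights[0, 1] == 4.0  # median over the present {3, 5}


def test_median_robust_to_outlier_and_identity_cases():
    mats = [edge_matrix(3, {(0, 1): v}) for v in (2, 4, 100)]
    cohort = make_cohort(mats)
    nos, _ = consensus_weights(cohort, consensus_mask(cohort))
    assert nos.weights[0, 1] == 4.0
    same = [edge_matrix(3, {(0, 1): 7, (1, 2): 2})] * 3
    cohort = make_cohort(same)
    nos, _ = consensus_weights(cohort, consensus_mask(cohort))
    assert np.array_equal(nos.weights, same[0])


def test_consensus_weight_within_subject_range(rng):
    mats = []
    for _ in range(9):
        w = np.triu(rng.integers(0, 6, (6, 6)), 1).astype(float)
        mats.append(w + w.T)
    cohort = make_cohort(mats)
    mask = consensus_mask(cohort)
    nos, _ = consensus_weights(cohort, mask)
    stack = cohort.nos_stack()
    for i, j in zip(*np.nonzero(mask)):
        present = stack[:, i, j][stack[:, i, j] != 0]
        assert present.min() <= nos.weights[i, j] <= present.max()


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        Cohort([])


class TestEdgeRegression:
    def connectomes(self, x, y):
        n = 5
        iu = np.triu_indices(n, 1)
        wa, wb = np.zeros((n, n)), np.zeros((n, n))
        wa[iu[0][:len(y)], iu[1][:len(y)]] = y
        wb[iu[0][:len(x)], iu[1][:len(x)]] = x
        wa, wb = wa + wa.T, wb + wb.T
        nodes = np.arange(1, n + 1)
        return (WeightedConnectome(nodes, wa, kind="scalar"),
                WeightedConnectome(nodes, wb, kind="scalar"))

    def test_perfect_linear_fit(self):
        x = np.array([1.0, 2, 3, 4])
        a, b = self.connectomes(x, 2 * x + 1)
        res = edge_regression(a, b)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.n_edges == 4

    def test_three_point_hand_ols(self):
        a, b = self.connectomes([1.0, 2, 3], [1.0, 2, 2])
        res = edge_regression(a, b)
        assert res.r_squared == pytest.approx(0.75)

    def test_constant_response_has_zero_r_squared(self):
        a, b = self.connectomes([1.0, 2, 3], [5.0, 5, 5])
        assert edge_regression(a, b).r_squared == pytest.approx(0.0)

    def test_constant_predictor_is_degenerate(self):
        a, b = self.connectomes([2.0, 2, 2], [1.0, 2, 3])
        with pytest.raises(ValueError):
            edge_regression(a, b)

    def test_too_few_common_edges_rejected(self):
        a, b = self.connectomes([1.0, 2], [1.0, 2])
        with pytest.raises(ValueError):
            edge_regression(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_r_squared_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(8) + 0.1
        y = rng.random(8) + 0.1
        a, b = self.connectomes(x, y)
        assert edge_regression(a, b).r_squared == pytest.approx(
            edge_regression(b, a).r_squared, rel=1e-12)
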