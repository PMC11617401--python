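import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tastedyn import (peak_entropy, rectify, sequentiality,
                      sequentiality_index, sort_by_peak,
                      split_half_reproducibility, temporal_sparsity)
from tastedyn.binning import RateTensor
from tastedyn.sequences import DegenerateMatrixError, latency_comparison
from tastedyn.session import EpochSpec

from test_screening import toy_matrix


class TestRectify:
    def test_symmetry_and_threshold(self):
        sm = toy_matrix([[0.75, 0.25, 0.55, 0.62, 0.38, 0.50]])
        R, _ = rectify(sm)
        np.testing.assert_allclose(R[0], [0.25, 0.25, 0.0, 0.12, 0.12, 0.0])

    def test_subthreshold_matrix_all_zero(self):
        sm = toy_matrix([[0.55] * 6])
        R, _ = rectify(sm)
        assert not R.any()

    def test_window_restriction(self):
        sm = toy_matrix([[0.8] * 10])
        R, centers = rectify(sm, window=(0.0, 100.0))
        assert centers.min() >= 0 and centers.max() <= 100
        assert R.shape[1] == centers.size < 10


class TestEntropies:
    def test_peak_entropy_hand_value(self):
        # peaks [bin0, bin0, bin1] over 2 bins
        R = np.array([[0.3, 0.0], [0.2, 0.1], [0.0, 0.4]])
        expected = -(2/3 * np.log(2/3) + 1/3 * np.log(1/3)) / np.log(2)
        assert peak_entropy(R) == pytest.approx(expected)

    def test_peak_entropy_extremes(self):
        assert peak_entropy(np.eye(4) * 0.2) == pytest.approx(1.0)
        allsame = np.zeros((4, 4)); allsame[:, 1] = 0.2
        assert peak_entropy(allsame) == 0.0

    def test_temporal_sparsity_hand_value(self):
        R = np.array([[0.3], [0.1]])
        h = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert temporal_sparsity(R) == pytest.approx(1 - h / np.log(2))

    def test_temporal_sparsity_extremes(self):
        assert temporal_sparsity(np.eye(4) * 0.2) == pytest.approx(1.0)
        assert temporal_sparsity(np.full((4, 6), 0.2)) == pytest.approx(0.0)

    def test_zero_columns_excluded_from_ts_average(self):
        R = np.array([[0.3, 0.0], [0.1, 0.0]])
        assert temporal_sparsity(R) == pytest.approx(temporal_sparsity(R[:, :1]))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateMatrixError):
            peak_entropy(np.zeros((3, 3)))
        with pytest.raises(DegenerateMatrixError):
            temporal_sparsity(np.zeros((3, 3)))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10**6))
    def test_bounds_and_scale_invariance(self, n, b, seed):
        rng = np.random.default_rng(seed)
        R = rng.uniform(0.01, 0.5, (n, b))
        pe, ts = peak_entropy(R), temporal_sparsity(R)
        assert 0 <= pe <= 1 and 0 <= ts <= 1
        assert 0 <= sequentiality_index(pe, ts) <= 1
        assert peak_entropy(3.7 * R) == pytest.approx(pe)
        assert temporal_sparsity(3.7 * R) == pytest.approx(ts)


class TestSqI:
    @pytest.mark.parametrize("pe, ts, printed, places", [
        (0.981, 0.571, 0.749, 3),   # aIC stimulus
        (0.939, 0.515, 0.695, 3),   # OFC stimulus
        (0.989, 0.284, 0.53, 2),    # OFC choice
        (0.983, 0.23, 0.475, 3),    # aIC outcome
    ])
    def test_combining_rule_matches_printed_triples(self, pe, ts, printed, places):
        assert sequentiality_index(pe, ts) == pytest.approx(printed, abs=10**-places)

    def test_extremes(self):
        assert sequentiality_index(1.0, 1.0) == 1.0
        assert sequentiality_index(0.0, 0.7) == 0.0

    def test_full_pipeline_on_perfect_sequence(self, sequence_population):
        """Non-overlapping staggered bumps should yield near-maximal SqI."""
        from tastedyn import screen_session, detect_encoders
        ses, _ = sequence_population
        sm = screen_session(ses, "stimulus", n_perm=300, seed=0)
        enc = detect_encoders(sm)
        assert enc.n_encoders >= 18
        res = sequentiality(sm.restrict_neurons(enc.is_encoder))
        assert res.PE > 0.9
        assert res.SqI > 0.6


class TestSortByPeak:
    def test_reversed_and_sorted(self):
        R = np.eye(5)[::-1] * 0.3
        np.testing.assert_array_equal(sort_by_peak(R), [4, 3, 2, 1, 0])
        np.testing.assert_array_equal(sort_by_peak(np.eye(5) * 0.3), np.arange(5))

    def test_matches_naive_sort(self):
        rng = np.random.default_rng(8)
        R = rng.uniform(0, 1, (5, 5))
        naive = sorted(range(5), key=lambda i: (int(np.argmax(R[i])), i))
        np.testing.assert_array_equal(sort_by_peak(R), naive)


def structured_tensor(n_neurons=10, n_trials=40, seed=0, effect=12.0):
    rng = np.random.default_rng(seed)
    b = 20
    epoch = EpochSpec("x", "stimulus_delivery_t", 0, 100 + 10 * (b - 1))
    labels = np.tile([False, True], n_trials // 2)
    rates = rng.poisson(3, (n_neurons, n_trials, b)).astype(float)
    for i in range(n_neurons):
        peak = 2 * i % b
        rates[i, labels, max(0, peak - 1):peak + 2] += effect
    return RateTensor(epoch=epoch, rates=rates, neuron_ids=np.arange(n_neurons),
                      trial_ids=np.arange(n_trials)), labels


class TestSplitHalf:
    def test_deterministic_rates_reach_floor_p(self):
        tensor, labels = structured_tensor(seed=1, effect=0.0)
        # deterministic within-class rates -> both halves' matrices identical
        tensor.rates[:] = 1.0
        for i in range(tensor.rates.shape[0]):
            tensor.rates[i, labels, 2 * i % 20] = 30.0
        res = split_half_reproducibility(tensor, labels, n_perm=500, seed=0)
        assert res.mse == 0.0
        assert res.p == pytest.approx(1 / 501, abs=1e-6)

    def test_structured_data_reproducible(self):
        tensor, labels = structured_tensor(seed=2)
        res = split_half_reproducibility(tensor, labels, n_perm=500, seed=0)
        assert res.p < 0.01

    def test_null_data_not_reproducible(self):
        tensor, labels = structured_tensor(seed=3, effect=0.0)
        res = split_half_reproducibility(tensor, labels, n_perm=500, seed=0)
        assert res.p > 0.01

    def test_too_few_trials_raises(self):
        tensor, labels = structured_tensor(n_trials=4, seed=4)
        with pytest.raises(ValueError):
            split_half_reproducibility(tensor, np.array([True, True, True, False]))


class TestLatencyComparison:
    def test_identical_sets(self):
        d, p, curves = latency_comparison([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)
        assert curves[0][1][-1] == 1.0

    def test_disjoint_shifted_sets(self):
        d, p, _ = latency_comparison([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_power_at_moderate_offset(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 400, 40)
        b = rng.uniform(200, 600, 40)
        _, p, _ = latency_comparison(a, b)
        assert p < 0.01

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            latency_comparison([1, 2], [1, 2, 3])
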