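import numpy as np
import pytest

from tastedyn import (DecodingConfig, build_pseudo_trials, confusion_vs_patterns,
                      decode, fine_pattern, gross_pattern, per_class_accuracy,
                      select_extended_population)
from tastedyn.binning import RateTensor
from tastedyn.decoding import bootstrap_difference
from tastedyn.session import EpochSpec


def make_tensor(rates):
    n, t, b = rates.shape
    epoch = EpochSpec("x", "stimulus_delivery_t", 0, 100 + 10 * (b - 1))
    return RateTensor(epoch=epoch, rates=rates, neuron_ids=np.arange(n),
                      trial_ids=np.arange(t))


def separable_binary(n_neurons=6, n_trials=60, gap=20.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.tile([0, 1], n_trials // 2)
    rates = rng.normal(5.0, noise, (n_neurons, n_trials, 3))
    rates[:, labels == 1, 1] += gap
    return np.abs(rates), labels


class TestPatterns:
    def test_rows_sum_to_one(self):
        assert np.allclose(fine_pattern().sum(axis=1), 1)
        assert np.allclose(gross_pattern().sum(axis=1), 1)

    def test_self_mse_zero(self):
        assert confusion_vs_patterns(fine_pattern())[0] == 0.0
        assert confusion_vs_patterns(gross_pattern())[1] == 0.0

    def test_fine_vs_gross_mse(self):
        mse_fine_of_gross = confusion_vs_patterns(gross_pattern())[0]
        assert mse_fine_of_gross == pytest.approx(5 * (0.8**2 + 4 * 0.2**2) / 36)
        assert mse_fine_of_gross == pytest.approx(0.1111, abs=5e-5)


class TestPseudoTrials:
    def test_single_neuron_binary_shape(self):
        rng = np.random.default_rng(0)
        rates = rng.poisson(5, (1, 30, 2)).astype(float)
        y = np.tile([0, 1], 15)
        X, yy = build_pseudo_trials(rates, y, np.array([0, 1]), 8, rng)
        assert X.shape == (16, 1, 2)
        assert (yy == 0).sum() == 8 and (yy == 1).sum() == 8

    def test_fixed_seed_reproducible(self):
        rates = np.random.default_rng(1).poisson(5, (3, 30, 2)).astype(float)
        y = np.tile([0, 1], 15)
        X1, _ = build_pseudo_trials(rates, y, np.array([0, 1]), 8,
                                    np.random.default_rng(42))
        X2, _ = build_pseudo_trials(rates, y, np.array([0, 1]), 8,
                                    np.random.default_rng(42))
        np.testing.assert_array_equal(X1, X2)

    def test_sampling_matches_trial_distribution(self):
        # with many draws the pseudo-trial values for one neuron/condition
        # reproduce the empirical distribution of that neuron's trial rates
        rng = np.random.default_rng(2)
        rates = np.zeros((1, 6, 1))
        rates[0, :, 0] = [1, 2, 3, 10, 11, 12]
        y = np.array([0, 0, 0, 1, 1, 1])
        X, yy = build_pseudo_trials(rates, y, np.array([0, 1]), 5000, rng)
        vals = X[yy == 0, 0, 0]
        for v in (1, 2, 3):
            assert abs(np.mean(vals == v) - 1 / 3) < 0.03

    def test_missing_class_rejected(self):
        rates = np.zeros((1, 4, 1))
        with pytest.raises(ValueError):
            build_pseudo_trials(rates, np.zeros(4, int), np.array([0, 1]), 4,
                                np.random.default_rng(0))


class TestDecode:
    def test_separable_population_high_accuracy(self):
        rates, y = separable_binary()
        cfg = DecodingConfig(schema="binary", kernel="linear", seed=0)
        res = decode(rates, y, cfg, np.arange(3) * 10.0, bins=np.array([1]))
        assert res.mean_accuracy[0] >= 0.95
        # off-signal bin stays near chance
        res0 = decode(rates, y, cfg, np.arange(3) * 10.0, bins=np.array([0]))
        assert abs(res0.mean_accuracy[0] - 0.5) < 0.15

    def test_permuted_binary_control_at_chance(self):
        rates, y = separable_binary()
        cfg = DecodingConfig(schema="binary", kernel="linear", seed=1,
                             permute_labels=True)
        res = decode(rates, y, cfg, np.arange(3) * 10.0, bins=np.array([1]))
        mean = res.accuracy.mean()
        sem = res.accuracy.std(ddof=1) / np.sqrt(res.accuracy.size)
        assert abs(mean - 0.5) < max(3 * sem, 0.05)

    def test_linear_not_outperformed_on_separable_data(self):
        rates, y = separable_binary()
        accs = {}
        for kernel in ("linear", "gaussian", "poly3"):
            cfg = DecodingConfig(schema="binary", kernel=kernel, seed=2,
                                 n_neuron_resamples=5, n_trial_resamples=4)
            accs[kernel] = decode(rates, y, cfg, np.arange(3) * 10.0,
                                  bins=np.array([1])).mean_accuracy[0]
        assert accs["linear"] >= accs["gaussian"] - 0.05
        assert accs["linear"] >= accs["poly3"] - 0.05

    def test_determinism(self):
        rates, y = separable_binary(seed=3)
        cfg = DecodingConfig(schema="binary", seed=7, n_neuron_resamples=3,
                             n_trial_resamples=2)
        a = decode(rates, y, cfg, np.arange(3) * 10.0, bins=np.array([1]))
        b = decode(rates, y, cfg, np.arange(3) * 10.0, bins=np.array([1]))
        np.testing.assert_array_equal(a.accuracy, b.accuracy)
        np.testing.assert_array_equal(a.confusion_counts, b.confusion_counts)

    def test_confusion_rows_normalized_and_diagonal(self):
        rng = np.random.default_rng(4)
        y = np.repeat(np.arange(6), 12)
        rates = rng.normal(5, 1, (4, y.size, 2))
        rates += y[None, :, None] * 3.0            # graded six-class signal
        cfg = DecodingConfig(schema="six_class", seed=5,
                             n_neuron_resamples=3, n_trial_resamples=2)
        res = decode(np.abs(rates), y, cfg, np.array([300.0, 400.0]))
        C = res.confusion_matrix(t_range=(250, 450))
        assert np.allclose(C.sum(axis=1), 1.0)
        np.testing.assert_allclose(per_class_accuracy(res, (250, 450)),
                                   np.diag(C))
        assert np.diag(C).mean() > 0.5


class TestExtendedPopulation:
    def test_concentration_tuned_selected_flat_mostly_not(self):
        rng = np.random.default_rng(6)
        conc = np.repeat([0.0, 0.5, 1.3, 3.2, 7.9, 20.0], 10)
        rates = rng.poisson(4, (30, 60, 5)).astype(float)
        for i in range(10):        # first 10 neurons graded by concentration
            rates[i] += np.log1p(conc)[:, None] * 4.0
        sel = select_extended_population(make_tensor(rates), conc)
        assert sel[:10].all()
        # untuned: per-neuron chance of any of 5 bins significant ~ 0.22
        assert sel[10:].mean() < 0.5

    def test_choice_encoders_excluded(self):
        rng = np.random.default_rng(7)
        conc = np.repeat([0.0, 0.5, 1.3, 3.2, 7.9, 20.0], 10)
        rates = rng.poisson(4, (5, 60, 3)).astype(float)
        rates += np.log1p(conc)[None, :, None]
        choice_mask = np.array([True, False, False, False, False])
        sel = select_extended_population(make_tensor(rates), conc,
                                         choice_encoders=choice_mask)
        assert not sel[0]


class TestBootstrap:
    def test_identical_arms_not_significant(self):
        acc = np.random.default_rng(8).normal(0.7, 0.05, (150, 2))
        p = bootstrap_difference(acc, acc.copy(), n_boot=2000, seed=0)
        assert (p > 0.5).all()

    def test_separated_arms_significant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.9, 0.03, (150, 2))
        b = rng.normal(0.55, 0.05, (150, 2))
        p = bootstrap_difference(a, b, n_boot=2000, seed=0)
        assert (p < 0.01).all()


class TestLickingControl:
    def test_outcome_neurons_beat_outcome_independent_licks(self):
        """Neural decoding of reward vs omission should dominate lick-rate
        decoding when licking does not depend on the outcome."""
        from tastedyn import BehaviorConfig, simulate_behavior, simulate_spikes
        from tastedyn.decoding import outcome_vs_licking_control
        from tastedyn.session import Session
        from tastedyn.synthetic import Bump, NeuronSpec

        trials = simulate_behavior(BehaviorConfig(n_trials=160, seed=31))
        # bump latencies stay inside the lick train (licking continues only
        # ~300 ms past feedback), where the warp is defined
        specs = [NeuronSpec(i, 2.0, "outcome",
                            (Bump("correct", 30.0, float(mu), 50.0),))
                 for i, mu in enumerate(np.linspace(50, 250, 8))]
        ses = Session("s", "aIC", trials,
                      simulate_spikes(trials, specs, seed=32)).validate()
        cfg = DecodingConfig(schema="binary", kernel="linear", seed=3,
                             n_neuron_resamples=5, n_trial_resamples=4)
        out = outcome_vs_licking_control(
            ses, np.arange(8), config=cfg,
            bins=np.array([50, 60]),        # 100-200 ms post-feedback
            n_boot=2000)
        assert out["neural"].mean_accuracy.min() > 0.8
        assert out["licking"].accuracy.mean() < 0.65
        assert (out["p_per_bin"] < 0.01).all()
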