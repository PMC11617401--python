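import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tastedyn import (auroc, detect_encoders, neuron_counts_report,
                      permutation_pvalue, proportion_ztest, selectivity_matrix)
from tastedyn.binning import RateTensor
from tastedyn.screening import SelectivityMatrix
from tastedyn.session import EpochSpec


def pair_count_auroc(x_a, x_b):
    """Exhaustive pair-counting oracle."""
    wins = ties = 0
    for a in x_a:
        for b in x_b:
            wins += b > a
            ties += b == a
    return (wins + 0.5 * ties) / (len(x_a) * len(x_b))


def toy_matrix(A, C=None, p=None, contrast="choice"):
    A = np.atleast_2d(np.asarray(A, float))
    n, b = A.shape
    epoch = EpochSpec("x", "stimulus_delivery_t", 0, 100 + 10 * (b - 1))
    assert epoch.n_bins == b
    if p is None:
        p = np.full_like(A, 0.01)
    return SelectivityMatrix(contrast=contrast, epoch=epoch, A=A,
                             p=np.asarray(p, float),
                             valid=np.ones_like(A, bool),
                             neuron_ids=np.arange(n),
                             C=None if C is None else np.atleast_2d(np.asarray(C, float)))


class TestAuroc:
    def test_worked_example(self):
        assert auroc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)

    def test_identical_samples(self):
        assert auroc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_full_separation(self):
        assert auroc([1, 2], [5, 6]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_pair_counting_oracle(self, data):
        ints = st.integers(min_value=0, max_value=6)
        x_a = data.draw(st.lists(ints, min_size=1, max_size=12))
        x_b = data.draw(st.lists(ints, min_size=1, max_size=12))
        assert auroc(x_a, x_b) == pytest.approx(pair_count_auroc(x_a, x_b))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 50), min_size=1, max_size=10),
           st.lists(st.floats(0, 50), min_size=1, max_size=10))
    def test_complement_symmetry(self, x_a, x_b):
        assert auroc(x_a, x_b) + auroc(x_b, x_a) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x_a, x_b = rng.poisson(5, 10), rng.poisson(8, 12)
        f = lambda x: np.exp(0.3 * np.asarray(x, float)) + 2
        assert auroc(x_a, x_b) == pytest.approx(auroc(f(x_a), f(x_b)))


class TestPermutationPvalue:
    def test_identical_samples_p_near_one(self):
        x = np.arange(10.0)
        assert permutation_pvalue(x, x, n_perm=500, seed=0) > 0.9

    def test_fully_separated_extreme_p(self):
        # distinct values, 8 vs 8: only 2 of C(16,8)=12870 relabelings are
        # as extreme, so p should sit near 1.6e-4
        p = permutation_pvalue(np.arange(8), np.arange(10, 18),
                               n_perm=10_000, seed=1)
        assert p < 1e-3

    def test_reproducible(self):
        rng = np.random.default_rng(2)
        a, b = rng.poisson(5, 15), rng.poisson(5, 15)
        assert (permutation_pvalue(a, b, 500, seed=7)
                == permutation_pvalue(a, b, 500, seed=7))


class TestSelectivityMatrix:
    def _tensor(self, rates):
        n, t, b = rates.shape
        epoch = EpochSpec("x", "stimulus_delivery_t", 0, 100 + 10 * (b - 1))
        return RateTensor(epoch=epoch, rates=rates,
                          neuron_ids=np.arange(n), trial_ids=np.arange(t))

    def test_single_trial_class_marked_invalid(self):
        rates = np.random.default_rng(0).poisson(5, (2, 10, 3)).astype(float)
        labels = np.zeros(10, bool)
        labels[0] = True
        sm = selectivity_matrix(self._tensor(rates), labels, "choice",
                                n_perm=100, seed=0)
        assert not sm.valid.any() and not sm.sig.any()

    def test_selective_neuron_flagged(self):
        rng = np.random.default_rng(3)
        labels = np.arange(40) < 20
        rates = rng.poisson(3, (1, 40, 8)).astype(float)
        rates[0, labels, 2:7] += 20.0
        sm = selectivity_matrix(self._tensor(rates), labels, "choice",
                                n_perm=500, seed=0)
        assert sm.sig[0, 2:7].all()
        assert (sm.A[0, 2:7] > 0.9).all()

    def test_null_calibration_per_bin(self):
        # fraction of p <= 0.05 across many null neuron-bins ~ 5%
        rng = np.random.default_rng(4)
        labels = np.arange(40) < 20
        rates = rng.poisson(5, (40, 40, 10)).astype(float)
        sm = selectivity_matrix(self._tensor(rates), labels, "choice",
                                n_perm=400, seed=0)
        frac = float((sm.p <= 0.05).mean())
        assert abs(frac - 0.05) < 0.02


class TestDetectEncoders:
    def test_four_consecutive_bins_insufficient(self):
        A = [[0.8] * 4 + [0.5] * 6]
        enc = detect_encoders(toy_matrix(A))
        assert not enc.is_encoder[0]

    def test_five_consecutive_bins_sufficient(self):
        A = [[0.8] * 5 + [0.5] * 5]
        enc = detect_encoders(toy_matrix(A))
        assert enc.is_encoder[0]
        assert enc.runs[0] == [(0, 5)]
        assert enc.preference[0] == "classB_preferring"

    def test_switching_preference(self):
        A = [[0.8] * 5 + [0.2] * 5]
        enc = detect_encoders(toy_matrix(A))
        assert enc.preference[0] == "switching"

    def test_low_preference(self):
        A = [[0.2] * 6 + [0.5] * 4]
        enc = detect_encoders(toy_matrix(A))
        assert enc.preference[0] == "classA_preferring"

    def test_best_bin_earliest_max(self):
        A = [[0.8, 0.9, 0.9, 0.8, 0.8, 0.5, 0.5, 0.5, 0.5, 0.5]]
        enc = detect_encoders(toy_matrix(A))
        assert enc.best_bin[0] == 1

    def test_nonsignificant_bins_do_not_qualify(self):
        A = [[0.8] * 10]
        p = [[0.5] * 10]
        enc = detect_encoders(toy_matrix(A, p=p))
        assert not enc.is_encoder[0]

    def test_stimulus_contrast_requires_beating_choice_probability(self):
        A = [[0.8] * 10]
        C_weak = [[0.6] * 10]
        C_strong = [[0.9] * 10]
        assert detect_encoders(toy_matrix(A, C=C_weak, contrast="stimulus")).is_encoder[0]
        assert not detect_encoders(toy_matrix(A, C=C_strong, contrast="stimulus")).is_encoder[0]

    def test_low_direction_disambiguation(self):
        A = [[0.2] * 10]
        assert detect_encoders(toy_matrix(A, C=[[0.4] * 10], contrast="stimulus")).is_encoder[0]
        assert not detect_encoders(toy_matrix(A, C=[[0.1] * 10], contrast="stimulus")).is_encoder[0]


class TestProportionZtest:
    def test_printed_stimulus_counts(self):
        z, p = proportion_ztest(45, 388, 60, 422)
        assert z == pytest.approx(-1.109, abs=5e-4)
        assert p == pytest.approx(0.267, abs=5e-3)

    def test_hand_computed_example(self):
        z, _ = proportion_ztest(8, 10, 2, 10)
        assert z == pytest.approx(0.6 / np.sqrt(0.25 * 0.2), abs=1e-9)

    def test_equal_proportions(self):
        z, p = proportion_ztest(5, 10, 10, 20)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(UserWarning):
            z, _ = proportion_ztest(0, 10, 0, 10)
        assert z == 0.0

    def test_counts_report_percentages(self):
        rep = neuron_counts_report({
            "outcome": {"aIC": (210, 388), "OFC": (231, 422)},
        })
        assert rep.loc[rep.region == "aIC", "percent"].item() == 54.12
        rep2 = neuron_counts_report({"choice": {"aIC": (117, 388),
                                                "OFC": (145, 422)}})
        assert rep2.loc[rep2.region == "OFC", "percent"].item() == 34.36
        assert rep2["z"].iloc[0] == pytest.approx(-1.278, abs=5e-4)


class TestDisambiguationEndToEnd:
    def test_pure_choice_neuron_not_a_stimulus_encoder(self):
        """A neuron driven only by the animal's response must stay out of
        the stimulus-encoder set despite the stimulus-choice correlation."""
        from tastedyn import BehaviorConfig, screen_session, simulate_behavior, simulate_spikes
        from tastedyn.session import Session
        from tastedyn.synthetic import Bump, NeuronSpec

        trials = simulate_behavior(BehaviorConfig(n_trials=240, seed=21))
        specs = [NeuronSpec(i, 3.0, "choice",
                            (Bump("sucrose", 25.0, float(mu), 60.0),))
                 for i, mu in enumerate([100.0, 300.0, 500.0])]
        ses = Session("s", "aIC", trials,
                      simulate_spikes(trials, specs, seed=22)).validate()
        # choice bumps are aligned to the last central lick, which trails
        # stimulus delivery by only ~0-300 ms, so they land in the stimulus
        # epoch; the choice-probability comparison must reject them
        sm = screen_session(ses, "stimulus", n_perm=500, seed=1)
        enc = detect_encoders(sm)
        assert enc.n_encoders == 0
        # the same neurons are found by the choice screen
        smc = screen_session(ses, "choice", n_perm=500, seed=1)
        assert detect_encoders(smc).n_encoders == 3
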