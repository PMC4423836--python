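"""Evolutionary split and feature-mask search."""

import numpy as np
import pytest

from cohortnet.datamodel import expand_indicators
from cohortnet.ga import GAConfig, evolve
from cohortnet.learners import LearnerBank
from cohortnet.synthdata import generate_cohort, recovery_config
from cohortnet.twist import (
    FeatureMask,
    SplitAssignment,
    TwistError,
    confusion_cost,
    optimize_split,
    select_features,
    stratified_split,
)


class TestConfusionCost:
    @pytest.mark.parametrize(
        "pred,obs,expected",
        [
            ([1, 1, 0, 0], [1, 0, 0, 0], 0.25),
            ([1, 0, 1], [1, 0, 1], 0.0),
            ([1, 1, 0], [0, 0, 1], 1.0),
        ],
    )
    def test_misclassification_rate(self, pred, obs, expected):
        assert confusion_cost(pred, obs) == expected

    def test_rmse_variant(self):
        assert confusion_cost([1, 0, 0, 0], [1, 1, 0, 0], "rmse") == 0.5

    def test_length_mismatch(self):
        with pytest.raises(TwistError):
            confusion_cost([1, 0], [1])


class TestGAEngine:
    def test_degenerate_singleton_is_identity(self):
        """With no mutation, crossover or immigrants and one individual,
        the population is returned unchanged."""
        cfg = GAConfig(population_size=1, generations=10, crossover_rate=0.0,
                       mutation_rate=0.0, immigrant_fraction=0.0, elitism=1, seed=0)
        start = np.array([1, 0, 1, 0], dtype=np.int8)
        calls = []

        def fitness(bits):
            calls.append(bits.copy())
            return float(bits.sum())

        res = evolve(fitness, 4, cfg, init=lambda rng: start.copy())
        np.testing.assert_array_equal(res.best, start)
        assert all((c == start).all() for c in calls)

    def test_best_ever_trace_is_monotone(self):
        rng = np.random.default_rng(0)
        target = rng.integers(0, 2, 20)

        def fitness(bits):
            return float((bits == target).mean())

        res = evolve(fitness, 20, GAConfig(population_size=20, generations=40, seed=1))
        assert np.all(np.diff(res.trace) >= 0)
        assert res.best_fitness == res.trace[-1]

    def test_fixed_seed_reproduces_search(self):
        def fitness(bits):
            return float(bits[::2].sum() - bits[1::2].sum())

        a = evolve(fitness, 16, GAConfig(population_size=12, generations=20, seed=5))
        b = evolve(fitness, 16, GAConfig(population_size=12, generations=20, seed=5))
        np.testing.assert_array_equal(a.best, b.best)
        np.testing.assert_array_equal(a.trace, b.trace)


class TestSplit:
    def test_membership_must_be_proper(self):
        with pytest.raises(TwistError):
            SplitAssignment(np.ones(5, dtype=int))
        with pytest.raises(TwistError):
            SplitAssignment(np.zeros(5, dtype=int))

    def test_each_half_needs_both_classes(self):
        split = SplitAssignment(np.array([1, 1, 0, 0]))
        with pytest.raises(TwistError):
            split.validate_classes(np.array([1, 1, 0, 0]))

    def test_optimized_split_is_representative(self):
        rng = np.random.default_rng(3)
        n = 120
        X = rng.integers(0, 2, size=(n, 6)).astype(float)
        y = (X[:, 0] + rng.random(n) > 0.9).astype(int)
        split, _ = optimize_split(
            X, y, GAConfig(population_size=12, generations=10, seed=2),
            LearnerBank(enabled=("naive_bayes",)),
        )
        full_rate = y.mean()
        for idx in (split.train_idx, split.test_idx):
            assert abs(y[idx].mean() - full_rate) <= 0.1

    def test_duplicated_dataset_split_one_copy_per_side_is_maximal(self):
        """On a dataset where every record appears twice, the split putting
        one copy of each record on each side makes both halves identical,
        so no other split of the same size can beat its fitness."""
        rng = np.random.default_rng(4)
        base = rng.integers(0, 2, size=(30, 5)).astype(float)
        yb = (base[:, 0] * base[:, 1] + rng.random(30) > 0.7).astype(int)
        X = np.vstack([base, base])
        y = np.concatenate([yb, yb])
        bank = LearnerBank(enabled=("naive_bayes",))

        from cohortnet.twist import _bank_accuracy

        def fitness(bits):
            a = bits.astype(bool)
            return min(
                _bank_accuracy(bank, X[a], y[a], X[~a], y[~a], "misclassification"),
                _bank_accuracy(bank, X[~a], y[~a], X[a], y[a], "misclassification"),
            )

        perfect = np.concatenate([np.ones(30, dtype=np.int8), np.zeros(30, dtype=np.int8)])
        f_perfect = fitness(perfect)
        for seed in range(20):
            r = np.random.default_rng(seed)
            bits = np.zeros(60, dtype=np.int8)
            bits[r.choice(60, size=30, replace=False)] = 1
            if bits.sum() in (0, 60) or len(set(y[bits == 1])) < 2 or len(set(y[bits == 0])) < 2:
                continue
            assert fitness(bits) <= f_perfect + 1e-12

    def test_seeded_split_is_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(60, 4)).astype(float)
        y = np.array([0, 1] * 30)
        cfg = GAConfig(population_size=8, generations=5, seed=9)
        bank = LearnerBank(enabled=("naive_bayes",))
        s1, _ = optimize_split(X, y, cfg, bank)
        s2, _ = optimize_split(X, y, cfg, bank)
        np.testing.assert_array_equal(s1.membership, s2.membership)


class TestSelectFeatures:
    def test_mask_requires_at_least_one_bit(self):
        with pytest.raises(TwistError):
            FeatureMask(np.zeros(3, dtype=int), ["a", "b", "c"])

    def test_outcome_columns_never_enter_the_feature_space(self):
        """Selection on an IndicatorMatrix with outcome columns included
        operates on the feature frame only — Event/No_Event cannot be
        selected even though they perfectly predict the outcome."""
        cohort, _ = generate_cohort(recovery_config(0))
        m = expand_indicators(cohort, include_outcome=True)
        split = stratified_split(cohort.outcome, seed=0)
        mask, _ = select_features(
            m, cohort.outcome, split,
            GAConfig(population_size=8, generations=4, seed=0),
            LearnerBank(enabled=("naive_bayes",)),
        )
        assert len(mask.labels) == len(m.feature_columns)
        assert "Event" not in mask.labels and "No_Event" not in mask.labels

    def test_planted_signal_recovered_quickly(self):
        cohort, truth = generate_cohort(recovery_config(2))
        m = expand_indicators(cohort)
        split = stratified_split(cohort.outcome, seed=2)
        mask, res = select_features(
            m, cohort.outcome, split,
            GAConfig(population_size=20, generations=30, seed=2),
            LearnerBank(enabled=("naive_bayes",)),
        )
        assert len(set(truth.informative_indicators) & set(mask.selected)) >= 3
        assert np.all(np.diff(res.trace) >= 0)
        assert res.best_fitness > 0.6
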