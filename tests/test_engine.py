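"""Core multilayer search: weight arithmetic, subset construction, loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlfssm.engine import (
    FeatureSubset,
    LayerState,
    RunConfig,
    build_layer_one_subsets,
    init_weights,
    run_mlfssm,
    sample_subsets,
    selection_probabilities,
    should_terminate,
    update_weights,
)


def naive_update_weights(prev, subsets, alpha, p):
    """Independent double-loop transcription of the weight revision rule."""
    m = len(prev)
    out = np.empty(m)
    for f in range(m):
        acc_sum = 0.0
        for sub in subsets:
            flag = 1 if f in set(int(i) for i in sub.members) else 0
            acc_sum += (sub.accuracy ** p) * flag
        out[f] = alpha * prev[f] + acc_sum
    return out


class TestInitWeights:
    @pytest.mark.parametrize("m, expected", [(1, [1.0]), (4, [0.25] * 4)])
    def test_uniform(self, m, expected):
        np.testing.assert_allclose(init_weights(m), expected)

    def test_large_m(self):
        w = init_weights(7129)
        assert w.shape == (7129,)
        np.testing.assert_allclose(w, 1 / 7129)

    def test_invalid(self):
        with pytest.raises(ValueError):
            init_weights(0)


class TestLayerOneSubsets:
    @given(st.integers(2, 40).flatmap(lambda m: st.tuples(st.just(m), st.integers(1, m))),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_balanced_design(self, m_ls, seed):
        """Every feature occurs exactly ls times; no within-subset repeat."""
        m, ls = m_ls
        subsets = build_layer_one_subsets(m, ls, np.random.default_rng(seed))
        assert len(subsets) == m
        counts = np.zeros(m, dtype=int)
        for sub in subsets:
            assert len(sub.members) == ls
            assert len(set(sub.members.tolist())) == ls
            counts[sub.members] += 1
        assert (counts == ls).all()

    def test_ls_equals_m_gives_permutations(self):
        subsets = build_layer_one_subsets(3, 3, np.random.default_rng(0))
        for sub in subsets:
            assert sorted(sub.members.tolist()) == [0, 1, 2]

    def test_ls_one_gives_each_feature_once(self):
        subsets = build_layer_one_subsets(5, 1, np.random.default_rng(0))
        assert sorted(int(s.members[0]) for s in subsets) == [0, 1, 2, 3, 4]

    def test_ls_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            build_layer_one_subsets(3, 4, np.random.default_rng(0))


class TestSelectionProbabilities:
    def test_uniform_weights_give_uniform_probs(self):
        np.testing.assert_allclose(selection_probabilities(init_weights(50)), 1 / 50)

    @pytest.mark.parametrize("w, expected", [
        ([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]),
        ([2.0, 1.0, 1.0], [0.5, 0.25, 0.25]),
    ])
    def test_normalization(self, w, expected):
        np.testing.assert_allclose(selection_probabilities(np.array(w)), expected)

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=30).filter(lambda w: sum(w) > 0))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_and_preserves_order(self, w):
        probs = selection_probabilities(np.array(w))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        for a in range(len(w)):
            for b in range(len(w)):
                if w[a] > w[b]:
                    assert probs[a] > probs[b]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            selection_probabilities(np.zeros(3))


class TestSampleSubsets:
    def test_degenerate_distribution(self):
        probs = np.zeros(10)
        probs[0] = 1.0
        for sub in sample_subsets(probs, 5, 4, np.random.default_rng(0)):
            assert (sub.members == 0).all()

    def test_deterministic_given_seed(self):
        probs = selection_probabilities(np.arange(1.0, 11.0))
        a = sample_subsets(probs, 8, 3, np.random.default_rng(42))
        b = sample_subsets(probs, 8, 3, np.random.default_rng(42))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.members, sb.members)

    def test_uniform_slot_frequencies(self):
        """Pooled slot frequencies under uniform probs match the multinomial
        model within 3 binomial standard errors."""
        m_feat = 50
        probs = np.full(m_feat, 1 / m_feat)
        subsets = sample_subsets(probs, 2000, 10, np.random.default_rng(3))
        counts = np.bincount(
            np.concatenate([s.members for s in subsets]), minlength=m_feat
        )
        n_slots = 2000 * 10
        se = np.sqrt(n_slots * (1 / m_feat) * (1 - 1 / m_feat))
        assert np.abs(counts - n_slots / m_feat).max() < 3 * se + 1e-9

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            sample_subsets(np.array([0.5, 0.4]), 3, 2, np.random.default_rng(0))


class TestUpdateWeights:
    def test_hand_computed_example(self):
        """alpha=0.5, p=1: two subsets at 0.8 and 0.6 -> (1.65, 0.85)."""
        subsets = [
            FeatureSubset(members=[0], accuracy=0.8),
            FeatureSubset(members=[0, 1], accuracy=0.6),
        ]
        w = update_weights(np.array([0.5, 0.5]), subsets, alpha=0.5, p=1)
        np.testing.assert_allclose(w, [1.65, 0.85])

    def test_unselected_feature_pure_decay(self):
        subsets = [FeatureSubset(members=[0, 1], accuracy=0.9)]
        w = update_weights(np.array([0.4, 0.4, 0.4]), subsets, alpha=0.2, p=32)
        assert w[2] == pytest.approx(0.2 * 0.4)

    def test_perfect_accuracy_increment_is_membership_count(self):
        """1**p == 1, so each feature gains exactly its membership count."""
        subsets = [
            FeatureSubset(members=[0, 1], accuracy=1.0),
            FeatureSubset(members=[0], accuracy=1.0),
            FeatureSubset(members=[2, 0], accuracy=1.0),
        ]
        w = update_weights(np.zeros(3), subsets, alpha=0.3, p=32)
        np.testing.assert_allclose(w, [3.0, 1.0, 1.0])

    def test_duplicate_members_count_once(self):
        """Membership flag, not occurrence count, drives the increment."""
        dup = [FeatureSubset(members=[1, 1, 1], accuracy=0.5)]
        uni = [FeatureSubset(members=[1], accuracy=0.5)]
        np.testing.assert_allclose(
            update_weights(np.ones(2), dup, 0.2, 2),
            update_weights(np.ones(2), uni, 0.2, 2),
        )

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            update_weights(np.ones(2), [FeatureSubset(members=[0], accuracy=1.5)], 0.2, 1)
        with pytest.raises(ValueError):
            update_weights(np.ones(2), [FeatureSubset(members=[0])], 0.2, 1)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_double_loop(self, data):
        """Vectorized revision equals the naive oracle on random instances."""
        m_feat = data.draw(st.integers(1, 8))
        n_sub = data.draw(st.integers(1, 8))
        prev = np.array(data.draw(st.lists(
            st.floats(0, 10), min_size=m_feat, max_size=m_feat)))
        subsets = [
            FeatureSubset(
                members=data.draw(st.lists(st.integers(0, m_feat - 1),
                                           min_size=1, max_size=6)),
                accuracy=data.draw(st.floats(0, 1)),
            )
            for _ in range(n_sub)
        ]
        alpha = data.draw(st.floats(0.01, 0.99))
        p = data.draw(st.sampled_from([1, 2, 4, 32]))
        np.testing.assert_allclose(
            update_weights(prev, subsets, alpha, p),
            naive_update_weights(prev, subsets, alpha, p),
            atol=1e-12, rtol=1e-12,
        )

    def test_relative_gain_monotonicity(self):
        """From equal starts, a larger membership-weighted accuracy sum
        yields a strictly larger revised weight."""
        subsets = [
            FeatureSubset(members=[0, 1], accuracy=0.9),
            FeatureSubset(members=[0], accuracy=0.8),
            FeatureSubset(members=[1, 2], accuracy=0.3),
        ]
        w = update_weights(np.full(3, 1 / 3), subsets, alpha=0.2, p=2)
        # sums: f0: .81+.64, f1: .81+.09, f2: .09
        assert w[0] > w[1] > w[2]


class TestShouldTerminate:
    def _layer(self, accs, index=1):
        subs = [FeatureSubset(members=[0], accuracy=a) for a in accs]
        return LayerState(layer_index=index, weights=np.ones(4), subsets=subs)

    def test_max_layers(self):
        cfg = RunConfig(ls=1, top_t=1, max_layers=20)
        assert should_terminate(self._layer([0.5], index=20), cfg) == "max_layers"

    @pytest.mark.parametrize("accs, expected", [
        ([1.0, 1.0, 0.7], "perfect_top_T"),
        ([1.0, 0.9, 0.9], "continue"),
    ])
    def test_top_t_semantics(self, accs, expected):
        cfg = RunConfig(ls=1, top_t=2, max_layers=20)
        assert should_terminate(self._layer(accs), cfg) == expected

    def test_unevaluated_rejected(self):
        cfg = RunConfig(ls=1, top_t=1)
        layer = self._layer([0.5])
        layer.subsets[0].accuracy = None
        with pytest.raises(ValueError):
            should_terminate(layer, cfg)


class TestRunLoop:
    @staticmethod
    def _oracle_evaluator(good_feature):
        """Accuracy 1.0 iff the subset contains the separating feature."""
        def ev(train, members, rng):
            return 1.0 if good_feature in set(int(i) for i in members) else 0.5
        return ev

    def test_perfect_separation_terminates_early(self, tiny_dataset):
        cfg = RunConfig(ls=1, top_t=1, max_layers=20, seed=5)
        res = run_mlfssm(tiny_dataset, cfg, self._oracle_evaluator(0))
        assert res.termination == "perfect_top_T"
        assert res.layers_run < 20
        assert res.final_subset.accuracy == 1.0
        assert set(res.final_subset.members.tolist()) == {0}

    def test_single_layer_cap(self, tiny_dataset):
        cfg = RunConfig(ls=2, top_t=4, max_layers=1, seed=5)
        res = run_mlfssm(tiny_dataset, cfg, self._oracle_evaluator(0))
        assert res.layers_run == 1 and res.termination == "max_layers"
        assert len(res.weight_history) == 1
        np.testing.assert_allclose(res.weight_history[0], 1 / 4)

    def test_bit_identical_under_same_seed(self, tiny_dataset):
        def noisy_ev(train, members, rng):
            return float(rng.integers(0, 5)) / 8.0

        cfg = RunConfig(ls=2, top_t=4, max_layers=4, seed=99)
        a = run_mlfssm(tiny_dataset, cfg, noisy_ev)
        b = run_mlfssm(tiny_dataset, cfg, noisy_ev)
        np.testing.assert_array_equal(a.final_subset.members, b.final_subset.members)
        assert a.best_accuracy_history == b.best_accuracy_history
        for wa, wb in zip(a.weight_history, b.weight_history):
            np.testing.assert_array_equal(wa, wb)

    def test_weight_history_layer_one_uniform(self, tiny_dataset):
        cfg = RunConfig(ls=2, top_t=4, max_layers=3, seed=1)
        res = run_mlfssm(tiny_dataset, cfg, self._oracle_evaluator(1))
        np.testing.assert_allclose(res.weight_history[0], 1 / 4)
        assert len(res.weight_history) == res.layers_run

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RunConfig(alpha=1.0)
        with pytest.raises(ValueError):
            RunConfig(p=0)
        cfg = RunConfig(ls=50)
        with pytest.raises(ValueError):
            cfg.validate_for(30)
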