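"""Hidden Markov journey models: training, prediction, selection, summaries."""

from itertools import product

import numpy as np
import pytest

from seekpaths.categories import CATEGORIES
from seekpaths.hmm import (
    CategoryHMM,
    holdout_prediction_error,
    loglikelihood,
    predict_next_category,
    random_hmm,
    sample_sequences,
    select_num_states,
    signature_states,
    stability_ranking,
    stationary_emission_mixture,
    train_hmm,
)
from seekpaths.synth import default_aggressive_hmm, default_indolent_hmm


def brute_force_prediction(model, prefix):
    """Next-category distribution by exhaustive hidden-path enumeration."""
    T = len(prefix)
    probs = np.zeros(10)
    total = 0.0
    for path in product(range(model.K), repeat=T + 1):
        p = model.initial[path[0]]
        for t in range(T):
            p *= model.emission[path[t], prefix[t]]
            p *= model.transition[path[t], path[t + 1]]
        probs += p * model.emission[path[-1]]
        total += p
    return probs / total


def best_of_restarts(seqs, K, n=5, seed0=0, mix_random=False):
    best, best_ll = None, -np.inf
    for s in range(n):
        m, h = train_hmm(seqs, K, seed=seed0 + s)
        if h[-1] > best_ll:
            best, best_ll = m, h[-1]
        if mix_random:
            init = random_hmm(K, np.random.default_rng(seed0 + s))
            m, h = train_hmm(seqs, K, init=init)
            if h[-1] > best_ll:
                best, best_ll = m, h[-1]
    return best


class TestTrainHMM:
    def test_single_state_fixed_point_is_pooled_frequencies(self):
        seqs = [[0, 1, 1, 3], [3, 3, 0]]
        model, _ = train_hmm(seqs, 1, seed=0)
        counts = np.array([2, 2, 0, 3] + [0] * 6, dtype=float)
        expected = (counts + 1e-3) / (counts.sum() + 1e-2)
        np.testing.assert_allclose(model.emission[0], expected, atol=1e-9)
        assert model.initial[0] == pytest.approx(1.0)

    def test_alternating_sequences_learn_cross_transitions(self):
        seqs = [[0, 1] * 8 for _ in range(30)]
        model = best_of_restarts(seqs, 2)
        off = min(model.transition[0, 1], model.transition[1, 0])
        assert off > 0.95

    def test_three_state_round_trip_recovery(self):
        truth = CategoryHMM(
            initial=[0.5, 0.3, 0.2],
            transition=[[0.7, 0.25, 0.05], [0.05, 0.7, 0.25], [0.25, 0.05, 0.7]],
            emission=np.vstack(
                [
                    np.eye(10)[0] * 0.9 + np.eye(10)[1] * 0.1,
                    np.eye(10)[3] * 0.9 + np.eye(10)[4] * 0.1,
                    np.eye(10)[6] * 0.9 + np.eye(10)[7] * 0.1,
                ]
            ),
        )
        rng = np.random.default_rng(21)
        seqs = sample_sequences(truth, np.full(1000, 15), rng)
        model = best_of_restarts(seqs, 3, n=3)
        # align states by dominant emission, then compare row-wise in TV
        order = [int(np.argmax(model.emission[:, d])) for d in (0, 3, 6)]
        assert sorted(order) == [0, 1, 2]
        perm = model.permuted(order)
        for name in ("transition", "emission"):
            tv = 0.5 * np.abs(getattr(perm, name) - getattr(truth, name)).sum(axis=1)
            assert tv.max() < 0.1

    def test_loglikelihood_monotone(self):
        rng = np.random.default_rng(3)
        seqs = [list(rng.integers(0, 10, rng.integers(3, 12))) for _ in range(40)]
        _, history = train_hmm(seqs, 3, seed=9)
        for prev, cur in zip(history, history[1:]):
            assert cur >= prev - 1e-8 * (1 + abs(prev))

    def test_rejects_oversized_k(self):
        with pytest.raises(ValueError):
            train_hmm([[0, 1]], 5)


class TestPrediction:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for K in (1, 2, 3):
            for _ in range(3):
                model = random_hmm(K, rng)
                for plen in (0, 1, 3, 5):
                    prefix = list(rng.integers(0, 10, plen))
                    fast = predict_next_category(model, prefix)
                    slow = brute_force_prediction(model, prefix)
                    np.testing.assert_allclose(fast, slow, atol=1e-12)
                    assert fast.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_single_state(self):
        e = np.zeros((1, 10))
        e[0, 3] = 1.0  # always `information`
        model = CategoryHMM(initial=[1.0], transition=[[1.0]], emission=e)
        for prefix in ([], [3], [3, 3, 3]):
            pred = predict_next_category(model, prefix)
            assert pred[3] == pytest.approx(1.0)

    def test_uniform_emissions_give_uniform_prediction(self):
        model = CategoryHMM(
            initial=[0.7, 0.3],
            transition=[[0.2, 0.8], [0.6, 0.4]],
            emission=np.full((2, 10), 0.1),
        )
        np.testing.assert_allclose(
            predict_next_category(model, [4, 2, 9]), np.full(10, 0.1), atol=1e-12
        )

    def test_unknown_token_rejected(self):
        model = random_hmm(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            predict_next_category(model, [11])


class TestHoldoutError:
    def test_deterministic_cycle_scores_zero(self):
        K = 3
        e = np.zeros((K, 10))
        for k in range(K):
            e[k, k] = 1.0
        a = np.roll(np.eye(K), 1, axis=1)
        model = CategoryHMM(initial=np.eye(K)[0], transition=a, emission=e)
        seqs = [[0, 1, 2, 0, 1, 2, 0]] * 5
        assert holdout_prediction_error(model, seqs) == 0.0

    def test_uniform_model_error_near_ninety_percent(self):
        model = CategoryHMM(
            initial=[1.0], transition=[[1.0]], emission=np.full((1, 10), 0.1)
        )
        rng = np.random.default_rng(8)
        seqs = [list(rng.integers(0, 10, 20)) for _ in range(100)]
        err = holdout_prediction_error(model, seqs)
        assert err == pytest.approx(0.9, abs=0.03)

    def test_truth_model_dominates_mismatched_model(self):
        truth = default_aggressive_hmm()
        wrong = default_indolent_hmm()
        rng = np.random.default_rng(13)
        seqs = sample_sequences(truth, rng.integers(5, 25, 500), rng)
        assert holdout_prediction_error(truth, seqs) <= holdout_prediction_error(
            wrong, seqs
        )

    def test_logloss_metric(self):
        model = CategoryHMM(
            initial=[1.0], transition=[[1.0]], emission=np.full((1, 10), 0.1)
        )
        seqs = [[0, 1, 2, 3]]
        assert holdout_prediction_error(model, seqs, metric="logloss") == pytest.approx(
            np.log(10)
        )

    def test_no_scorable_positions(self):
        model = random_hmm(1, np.random.default_rng(0))
        with pytest.raises(ValueError):
            holdout_prediction_error(model, [[1], [2]])


class TestSelection:
    def test_single_candidate(self):
        rng = np.random.default_rng(2)
        seqs = [list(rng.integers(0, 10, 6)) for _ in range(10)]
        assert select_num_states(seqs, [1], seed=0).best_K == 1

    def test_alternating_data_selects_two_states(self):
        seqs = [[0, 1] * 10 for _ in range(40)]
        res = select_num_states(seqs, [1, 2, 3], seed=4)
        # one state cannot beat 50% error on alternating symbols
        assert res.mean_error[1] == pytest.approx(0.5, abs=0.05)
        assert res.mean_error[2] < 0.05
        assert res.best_K == 2

    def test_infeasible_k_flagged(self):
        seqs = [[0, 1]] * 10
        res = select_num_states(seqs, [2, 100], seed=0)
        assert res.infeasible_Ks == [100]
        assert np.isnan(res.mean_error[100])
        assert res.best_K == 2

    def test_state_relabelling_leaves_error_and_signature_unchanged(self):
        model = default_aggressive_hmm()
        perm = model.permuted([3, 1, 4, 0, 2])
        rng = np.random.default_rng(17)
        seqs = sample_sequences(model, np.full(200, 12), rng)
        assert holdout_prediction_error(model, seqs) == pytest.approx(
            holdout_prediction_error(perm, seqs), abs=1e-12
        )
        sigs = lambda m: sorted(
            tuple(entry["signature"]) for entry in signature_states(m)
        )
        assert sigs(model) == sigs(perm)


class TestSummaries:
    def test_signature_threshold_and_order(self):
        e = np.zeros((2, 10))
        e[0, 0], e[0, 1] = 0.96, 0.04
        e[1] = 0.1
        model = CategoryHMM(
            initial=[0.5, 0.5], transition=np.full((2, 2), 0.5), emission=e
        )
        sig = signature_states(model)
        assert sig[0]["signature"] == [("causes", 0.96)]
        # uniform row: all ten listed, ties in canonical order, flagged
        assert [c for c, _ in sig[1]["signature"]] == list(CATEGORIES)
        assert sig[1]["ties"]

    def test_default_truths_signatures_mirror_severity_contrast(self):
        has_support = lambda m: any(
            c == "support" for s in signature_states(m) for c, _ in s["signature"]
        )
        assert has_support(default_indolent_hmm())
        assert not has_support(default_aggressive_hmm())

    def test_stability_ranking(self):
        model = CategoryHMM(
            initial=[0.5, 0.5],
            transition=[[0.9, 0.1], [0.5, 0.5]],
            emission=np.full((2, 10), 0.1),
        )
        rank = stability_ranking(model)
        assert rank["ranking"][0] == (0, pytest.approx(0.9))
        tied = CategoryHMM(
            initial=[0.5, 0.5],
            transition=np.full((2, 2), 0.5),
            emission=np.full((2, 10), 0.1),
        )
        assert stability_ranking(tied)["ties"]

    def test_default_truth_stability_orders(self):
        agg = stability_ranking(default_aggressive_hmm())
        assert {s for s, _ in agg["ranking"][:2]} == {0, 1}
        ind = stability_ranking(default_indolent_hmm())
        assert {s for s, _ in ind["ranking"][:3]} == {2, 3, 4}


class TestCrossCheck:
    def test_hmmlearn_reaches_comparable_likelihood(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        truth = default_aggressive_hmm()
        rng = np.random.default_rng(31)
        seqs = sample_sequences(truth, np.full(150, 12), rng)
        ours = best_of_restarts(seqs, 3, n=3, mix_random=True)
        our_ll = loglikelihood(ours, seqs)

        X = np.concatenate(seqs).reshape(-1, 1)
        lengths = [len(s) for s in seqs]
        best_ref = -np.inf
        for s in range(3):
            ref = hmmlearn.CategoricalHMM(
                n_components=3, n_iter=300, tol=1e-6, random_state=s, n_features=10
            )
            ref.fit(X, lengths)
            best_ref = max(best_ref, ref.score(X, lengths))
        # two independent EM implementations should reach similar optima
        assert our_ll >= best_ref - 0.005 * abs(best_ref)

    def test_stationary_mixture_matches_long_run_frequencies(self):
        model = default_indolent_hmm()
        rng = np.random.default_rng(19)
        seqs = sample_sequences(model, np.full(60, 400), rng)
        freq = np.bincount(np.concatenate(seqs), minlength=10) / (60 * 400)
        np.testing.assert_allclose(freq, stationary_emission_mixture(model), atol=0.02)
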