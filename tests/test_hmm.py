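"""Discrete HMM training, forward likelihood, scoring and cross-validation."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwnetdyn import (
    HmmModel,
    ValidationError,
    crossvalidate_participant,
    fit_hmm,
    forward_likelihood,
    roc_auc,
    score_fl,
)


def brute_force_loglik(model: HmmModel, seq: np.ndarray) -> float:
    """Exhaustive sum over all hidden paths."""
    total = 0.0
    n = model.n_hidden
    for path in product(range(n), repeat=len(seq)):
        p = model.pi[path[0]] * model.B[path[0], seq[0]]
        for t in range(1, len(seq)):
            p *= model.A[path[t - 1], path[t]] * model.B[path[t], seq[t]]
        total += p
    return float(np.log(total))


def random_model(rng, n_hidden=2, n_obs=4) -> HmmModel:
    A = rng.uniform(0.1, 1, (n_hidden, n_hidden)); A /= A.sum(1, keepdims=True)
    B = rng.uniform(0.1, 1, (n_hidden, n_obs)); B /= B.sum(1, keepdims=True)
    pi = rng.uniform(0.1, 1, n_hidden); pi /= pi.sum()
    return HmmModel(A=A, B=B, pi=pi)


class TestForwardLikelihood:
    def test_uniform_emissions_closed_form(self, rng):
        model = random_model(rng)
        model.B = np.full((2, 4), 0.25)
        seq = [0, 3, 2]
        assert forward_likelihood(model, seq) == pytest.approx(3 * np.log(0.25))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        for length in (1, 3, 8):
            seq = rng.integers(0, 4, length)
            assert forward_likelihood(model, seq) == pytest.approx(
                brute_force_loglik(model, seq), abs=1e-10
            )

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.lists(st.integers(0, 3), min_size=1, max_size=8))
    def test_forward_enumeration_equivalence_property(self, seed, seq):
        model = random_model(np.random.default_rng(seed))
        seq = np.array(seq)
        assert forward_likelihood(model, seq) == pytest.approx(
            brute_force_loglik(model, seq), abs=1e-10
        )

    def test_monotone_in_length(self, rng):
        model = random_model(rng)
        seq = rng.integers(0, 4, 20)
        lls = [forward_likelihood(model, seq[:t]) for t in range(1, 21)]
        assert all(b <= a + 1e-12 for a, b in zip(lls, lls[1:]))

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValidationError):
            forward_likelihood(random_model(rng), [])

    def test_symbol_outside_alphabet_rejected(self, rng):
        with pytest.raises(ValidationError):
            forward_likelihood(random_model(rng), [0, 5])

    def test_matches_hmmlearn_reference(self, rng):
        """Independent cross-check against an external implementation."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_model(rng)
        ref = hmmlearn.CategoricalHMM(n_components=2)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = model.pi, model.A, model.B
        seq = rng.integers(0, 4, 200)
        assert forward_likelihood(model, seq) == pytest.approx(
            ref.score(seq.reshape(-1, 1)), abs=1e-8
        )


class TestFitHmm:
    def test_loglik_trace_non_decreasing(self, rng):
        seq = rng.integers(0, 4, 500)
        model = fit_hmm(seq, seed=0)
        trace = np.array(model.train_log_likelihood_trace)
        assert trace.size >= 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_rows_stochastic(self, rng):
        model = fit_hmm(rng.integers(0, 4, 300), seed=1)
        np.testing.assert_allclose(model.A.sum(1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.B.sum(1), 1.0, atol=1e-9)
        assert model.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_emission_recovery(self):
        from mwnetdyn.benchmarks import hmm_parameter_recovery

        res = hmm_parameter_recovery(n_seeds=3, seed=0)
        assert res["frac_recovered"] >= 2 / 3
        assert res["all_traces_monotone"]

    def test_uniform_init_is_symmetric_fixed_point(self, rng):
        seq = rng.integers(0, 4, 300)
        model = fit_hmm(seq, seed=0, perturb=False, max_iter=20)
        np.testing.assert_allclose(model.A[0], model.A[1], atol=1e-12)
        np.testing.assert_allclose(model.B[0], model.B[1], atol=1e-12)

    def test_unseen_symbol_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_hmm(rng.integers(0, 4, 100), n_obs=3)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            fit_hmm([0, 1, 2], seed=0)


class TestScoreFl:
    def test_identical_models_give_half(self, rng):
        m = random_model(rng)
        assert score_fl(rng.integers(0, 4, 50), m, m) == pytest.approx(0.5)

    def test_posterior_arithmetic(self):
        # P(Y|FL) = 0.02, P(Y|MW) = 0.01 -> 2/3, via loglik difference
        m1 = HmmModel(np.eye(1), np.array([[1.0]]), np.array([1.0]))
        m2 = HmmModel(np.eye(1), np.array([[1.0]]), np.array([1.0]))
        d = np.log(0.01) - np.log(0.02)
        assert 1 / (1 + np.exp(d)) == pytest.approx(2 / 3)

    def test_complementarity(self, rng):
        m1, m2 = random_model(rng), random_model(rng)
        seq = rng.integers(0, 4, 30)
        assert score_fl(seq, m1, m2) + score_fl(seq, m2, m1) == pytest.approx(1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_missing(self):
        assert np.isnan(roc_auc([0.1, 0.9], [1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], 30)  # ties included
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == wins / (pos.size * neg.size)


class TestCrossvalidation:
    def make_sequences(self, rng, a_fl, a_mw, n=400):
        def gen(A):
            s = [0]
            for _ in range(n - 1):
                s.append(int(rng.choice(4, p=A[s[-1]])))
            return np.array(s)

        return {
            "alpha": {"FL": [gen(a_fl), gen(a_fl)], "MW": [gen(a_mw), gen(a_mw)]}
        }

    @staticmethod
    def benchmark_chains():
        from mwnetdyn import benchmark_condition_specs

        fl, mw = benchmark_condition_specs()
        return fl.state_transition_matrix, mw.state_transition_matrix

    def test_distinct_dynamics_detected(self, rng):
        fl, mw = self.benchmark_chains()  # same states, different switching
        res = crossvalidate_participant(self.make_sequences(rng, fl, mw), k=8, seed=0)
        assert res.auc_mean >= 0.8

    def test_identical_dynamics_near_chance(self):
        fl, _ = self.benchmark_chains()
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            res = crossvalidate_participant(
                self.make_sequences(rng, fl, fl, n=300), k=8, seed=seed
            )
            aucs.append(res.auc_mean)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_deterministic_under_seed(self, rng):
        fl, mw = self.benchmark_chains()
        seqs = self.make_sequences(rng, fl, mw)
        r1 = crossvalidate_participant(seqs, k=8, seed=11)
        r2 = crossvalidate_participant(seqs, k=8, seed=11)
        assert r1.auc_mean == r2.auc_mean
        assert [f.band for f in r1.folds] == [f.band for f in r2.folds]
        for f1, f2 in zip(r1.folds, r2.folds):
            np.testing.assert_array_equal(f1.scores, f2.scores)

    def test_band_choice_recorded_and_train_only(self, rng):
        fl, mw = self.benchmark_chains()
        seqs = self.make_sequences(rng, fl, mw)
        seqs["delta"] = {  # uninformative band
            "FL": [rng.integers(0, 4, 400)], "MW": [rng.integers(0, 4, 400)]
        }
        res = crossvalidate_participant(seqs, k=4, seed=2)
        for fold in res.folds:
            assert fold.band in ("delta", "alpha")
            assert fold.fold not in fold.train_blocks
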