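import itertools

import numpy as np
import pytest

from hmmtutor import (
    InfeasibleSequenceError,
    ModelValidationError,
    ObservedSequence,
    backward,
    enumerate_paths,
    forward,
    joint_probability,
    posterior_by_enumeration,
    posterior_decoding,
    viterbi,
)
from conftest import make_model, random_instance

SEQ_AA = ObservedSequence.from_string("aa")
SEQ_ABA = ObservedSequence.from_string("aba")


class TestForward:
    def test_single_state_product_of_emissions(self, one_state_model):
        # prior 1, self-transition 1: P(O) = e(a)^2 = 0.25
        assert forward(one_state_model, SEQ_AA, mode="plain").total == pytest.approx(0.25)

    def test_length_one_is_prior_weighted_emission(self, two_state_model):
        seq = ObservedSequence.from_string("a")
        expected = 0.6 * 0.9 + 0.4 * 0.2
        assert forward(two_state_model, seq, mode="plain").total == pytest.approx(expected)

    def test_matches_brute_force_enumeration(self, two_state_model):
        res = forward(two_state_model, SEQ_ABA, mode="plain")
        enum = enumerate_paths(two_state_model, SEQ_ABA)
        assert len(enum.pairs) == 8
        assert res.total == pytest.approx(enum.aggregate, rel=1e-9)

    def test_total_is_sum_of_last_row(self, two_state_model):
        res = forward(two_state_model, SEQ_ABA, mode="plain")
        assert res.total == pytest.approx(res.table[-1].sum(), rel=1e-12)

    def test_log_and_plain_agree(self, two_state_model):
        plain = forward(two_state_model, SEQ_ABA, mode="plain")
        log = forward(two_state_model, SEQ_ABA, mode="log")
        assert log.probability == pytest.approx(plain.total, rel=1e-9)

    def test_foreign_symbol_rejected_with_position(self, two_state_model):
        with pytest.raises(ModelValidationError, match="position 2"):
            forward(two_state_model, ObservedSequence.from_string("axa"))

    def test_cross_check_against_hmmlearn(self, two_state_model):
        hmm = pytest.importorskip("hmmlearn.hmm")
        m = hmm.CategoricalHMM(n_components=2)
        m.startprob_ = np.array([0.6, 0.4])
        m.transmat_ = np.array([[0.7, 0.3], [0.4, 0.6]])
        m.emissionprob_ = np.array([[0.9, 0.1], [0.2, 0.8]])
        obs = np.array([[0], [1], [0]])  # "aba"
        expected = m.score(obs)
        assert forward(two_state_model, SEQ_ABA, mode="log").total == pytest.approx(
            expected, rel=1e-9
        )


class TestBackward:
    def test_last_row_all_ones(self, two_state_model):
        res = backward(two_state_model, SEQ_ABA, mode="plain")
        np.testing.assert_array_equal(res.table[-1], [1.0, 1.0])

    def test_single_state_total_matches_forward(self, one_state_model):
        assert backward(one_state_model, SEQ_AA, mode="plain").total == pytest.approx(0.25)

    def test_beta_equals_suffix_path_sums(self, two_state_model):
        # beta[j,k] = sum over all state suffixes of the path probability
        # from state k at position j onward
        res = backward(two_state_model, SEQ_ABA, mode="plain")
        m = two_state_model
        obs = SEQ_ABA.indices(m.alphabet)
        L, K = len(obs), m.n_states
        for j in range(L):
            for k in range(K):
                total = 0.0
                for suffix in itertools.product(range(K), repeat=L - 1 - j):
                    p, prev = 1.0, k
                    for step, l in enumerate(suffix):
                        p *= m.transitions[prev, l] * m.emissions[l, obs[j + 1 + step]]
                        prev = l
                    total += p
                assert res.table[j, k] == pytest.approx(total, rel=1e-9)

    def test_forward_backward_totals_agree(self, two_state_model):
        f = forward(two_state_model, SEQ_ABA, mode="plain")
        b = backward(two_state_model, SEQ_ABA, mode="plain")
        assert f.total == pytest.approx(b.total, rel=1e-9)

    def test_alpha_beta_product_is_total_at_every_position(self, two_state_model):
        f = forward(two_state_model, SEQ_ABA, mode="plain")
        b = backward(two_state_model, SEQ_ABA, mode="plain")
        for j in range(3):
            assert (f.table[j] * b.table[j]).sum() == pytest.approx(f.total, rel=1e-9)


class TestViterbi:
    def test_single_state_path_is_constant(self, one_state_model):
        res = viterbi(one_state_model, SEQ_AA)
        assert res.path == ("S", "S")
        assert res.conditional == pytest.approx(1.0)

    def test_matches_enumeration_argmax(self, two_state_model):
        res = viterbi(two_state_model, SEQ_ABA, mode="plain")
        enum = enumerate_paths(two_state_model, SEQ_ABA)
        assert res.path == enum.best_path
        assert res.joint == pytest.approx(enum.best_probability, rel=1e-9)

    def test_joint_never_exceeds_total(self, two_state_model):
        res = viterbi(two_state_model, SEQ_ABA, mode="plain")
        assert res.joint <= forward(two_state_model, SEQ_ABA, mode="plain").total

    def test_conditional_is_joint_over_total(self, two_state_model):
        res = viterbi(two_state_model, SEQ_ABA, mode="plain")
        total = forward(two_state_model, SEQ_ABA, mode="plain").total
        assert res.conditional == pytest.approx(res.joint / total, rel=1e-9)

    def test_symmetric_tie_broken_toward_earliest_state(self):
        # fully symmetric model: every path ties; earliest state must win
        m = make_model(
            [0.5, 0.5],
            [[0.5, 0.5], [0.5, 0.5]],
            [[0.5, 0.5], [0.5, 0.5]],
            labels=("A1", "A2"),
        )
        for mode in ("plain", "log"):
            res = viterbi(m, SEQ_ABA, mode=mode)
            assert res.path == ("A1", "A1", "A1")

    def test_infeasible_sequence_raises(self):
        m = make_model([1.0], [[1.0]], [[1.0, 0.0]])
        with pytest.raises(InfeasibleSequenceError):
            viterbi(m, ObservedSequence.from_string("ab"))

    def test_rerun_invariance(self, two_state_model):
        first = viterbi(two_state_model, SEQ_ABA)
        for _ in range(3):
            assert viterbi(two_state_model, SEQ_ABA).path == first.path


class TestPosteriorDecoding:
    def test_single_state_all_ones(self, one_state_model):
        post = posterior_decoding(one_state_model, SEQ_AA)
        np.testing.assert_allclose(post.gamma, 1.0)

    def test_rows_sum_to_one(self, two_state_model):
        post = posterior_decoding(two_state_model, SEQ_ABA)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_enumeration(self, two_state_model):
        post = posterior_decoding(two_state_model, SEQ_ABA)
        ref = posterior_by_enumeration(two_state_model, SEQ_ABA)
        np.testing.assert_allclose(post.gamma, ref.gamma, rtol=1e-9)

    def test_zero_probability_sequence_rejected(self):
        m = make_model([1.0], [[1.0]], [[1.0, 0.0]])
        with pytest.raises(InfeasibleSequenceError):
            posterior_decoding(m, ObservedSequence.from_string("b"))


class TestJointProbability:
    def test_single_state_two_steps(self, one_state_model):
        assert joint_probability(one_state_model, SEQ_AA, ("S", "S")) == pytest.approx(0.25)

    def test_zero_transition_path_has_zero_probability(self):
        m = make_model(
            [0.5, 0.0, 0.5],
            [[0.98, 0.02, 0.0], [0.05, 0.9, 0.05], [0.0, 0.03, 0.97]],
            np.full((3, 2), 0.5),
            labels=("I", "M", "O"),
        )
        assert joint_probability(m, SEQ_AA, ("I", "O")) == 0.0
        assert joint_probability(m, SEQ_AA, ("I", "O"), mode="log") == -np.inf

    def test_sum_over_all_paths_equals_forward_total(self, two_state_model):
        labels = two_state_model.states.labels
        total = sum(
            joint_probability(two_state_model, SEQ_ABA, path)
            for path in itertools.product(labels, repeat=3)
        )
        assert total == pytest.approx(
            forward(two_state_model, SEQ_ABA, mode="plain").total, rel=1e-9
        )

    def test_length_mismatch_rejected(self, one_state_model):
        with pytest.raises(ModelValidationError):
            joint_probability(one_state_model, SEQ_AA, ("S",))

    def test_unknown_label_rejected(self, one_state_model):
        with pytest.raises(ModelValidationError):
            joint_probability(one_state_model, SEQ_AA, ("S", "Z"))


class TestLogPlainAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_algorithms_agree_across_modes(self, seed):
        rng = np.random.default_rng(seed)
        model, seq = random_instance(rng, n_states=3, n_symbols=4, length=8)
        f_plain = forward(model, seq, mode="plain")
        f_log = forward(model, seq, mode="log")
        assert f_log.probability == pytest.approx(f_plain.total, rel=1e-9)
        b_plain = backward(model, seq, mode="plain")
        b_log = backward(model, seq, mode="log")
        assert b_log.probability == pytest.approx(b_plain.total, rel=1e-9)
        v_plain = viterbi(model, seq, mode="plain")
        v_log = viterbi(model, seq, mode="log")
        assert v_plain.path == v_log.path
        assert np.exp(v_log.joint) == pytest.approx(v_plain.joint, rel=1e-9)
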