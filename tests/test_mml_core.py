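import math

import numpy as np
import pytest

from alnzone.align_distance import Alignment
from alnzone.errors import InferenceError
from alnzone.mml_core import (
    ComparisonResult,
    SequencePair,
    alignment_length,
    count_alignments,
    forward_matrices,
    infer_time,
    landscape,
    log_star,
    marginal_bits,
    marginal_compare,
    null_length,
    optimal_compare,
    significance,
)

from oracles import all_joint_probabilities, enumerate_alignments


class TestNullLength:
    def test_single_residue_uniform_model(self, model):
        # forced by definition: len-code(1) + -log2 p(residue), per sequence
        pair = SequencePair("A", "A")
        pa = model.stationary[0]
        expect = 2 * (log_star(1) - math.log2(pa))
        assert null_length(pair, model) == pytest.approx(expect, abs=1e-12)

    def test_additivity(self, model):
        # NULL(<S,T>) = NULL(S) + NULL(T), where NULL of a single sequence
        # is half the null length of the pair <S, S>
        s, t = "ACDEF", "WYKLHMN"
        null_s = null_length(SequencePair(s, s), model) / 2
        null_t = null_length(SequencePair(t, t), model) / 2
        both = null_length(SequencePair(s, t), model)
        assert both == pytest.approx(null_s + null_t, abs=1e-9)
        direct = log_star(len(s)) - sum(
            math.log2(model.stationary[i]) for i in SequencePair(s, s).s_idx)
        assert null_s == pytest.approx(direct, abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequencePair("", "ACD")


class TestCountAlignments:
    @pytest.mark.parametrize("m,n,expect", [(1, 1, 3), (2, 2, 13), (0, 5, 1),
                                            (5, 0, 1), (0, 0, 1)])
    def test_known_counts(self, m, n, expect):
        assert count_alignments(m, n) == expect

    def test_matches_enumeration(self):
        for m in range(6):
            for n in range(6):
                assert count_alignments(m, n) == len(enumerate_alignments(m, n))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_alignments(-1, 3)


class TestOptimalCompare:
    def test_identical_sequences_all_match(self, model, machine):
        pair = SequencePair("ACDEFGHIKL", "ACDEFGHIKL")
        res = optimal_compare(pair, model, machine)
        assert res.optimal_alignment.states == "m" * 10

    def test_matches_enumeration_minimum(self, model, machine, random_pair_factory):
        rng = np.random.default_rng(11)
        for _ in range(25):
            pair = random_pair_factory(rng, max_len=4)
            t = float(rng.uniform(2, 400))
            res = optimal_compare(pair, model, machine, t=t)
            _, probs = all_joint_probabilities(pair, model, machine, t)
            assert res.i_optimal_bits == pytest.approx(
                -math.log2(probs.max()), abs=1e-9)

    def test_returned_alignment_cost_recomputes(self, model, machine,
                                                random_pair_factory):
        rng = np.random.default_rng(12)
        for _ in range(10):
            pair = random_pair_factory(rng, max_len=6)
            res = optimal_compare(pair, model, machine, t=120.0)
            recomputed = alignment_length(pair, res.optimal_alignment, model,
                                          machine, 120.0)
            assert recomputed == pytest.approx(res.i_optimal_bits, abs=1e-9)


class TestMarginalCompare:
    def test_one_by_one_hand_computation(self, model, machine):
        pair = SequencePair("A", "W")
        t = 75.0
        alns, probs = all_joint_probabilities(pair, model, machine, t)
        assert set(alns) == {"m", "id", "di"}
        expect = -math.log2(probs.sum())
        assert marginal_bits(pair, model, machine, t) == pytest.approx(expect, abs=1e-9)

    def test_matches_enumeration_sum(self, model, machine, random_pair_factory):
        rng = np.random.default_rng(13)
        for _ in range(25):
            pair = random_pair_factory(rng)
            t = float(rng.uniform(2, 400))
            _, probs = all_joint_probabilities(pair, model, machine, t)
            got = marginal_bits(pair, model, machine, t)
            assert got == pytest.approx(-math.log2(probs.sum()), rel=1e-12, abs=1e-9)

    def test_marginal_below_optimal(self, model, machine, random_pair_factory):
        rng = np.random.default_rng(14)
        for _ in range(10):
            pair = random_pair_factory(rng)
            t = float(rng.uniform(2, 400))
            marg = marginal_bits(pair, model, machine, t)
            opt = optimal_compare(pair, model, machine, t=t)
            assert marg <= opt.i_optimal_bits + 1e-9

    def test_posterior_normalization(self, model, machine, random_pair_factory):
        rng = np.random.default_rng(15)
        pair = random_pair_factory(rng)
        t = 90.0
        _, probs = all_joint_probabilities(pair, model, machine, t)
        post = probs / probs.sum()
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_forward_matrices_reproduce_marginal(self, model, machine):
        pair = SequencePair("ACDEFG", "ACDWFG")
        t = 60.0
        fwd = forward_matrices(pair, model, machine, t)
        total = fwd.total_bits() - math.log2(machine.stop)
        assert total == pytest.approx(marginal_bits(pair, model, machine, t), abs=1e-9)

    def test_reversal_symmetry(self, model, machine):
        # machine reversibility makes the marginal invariant under
        # reversing both sequences
        pair = SequencePair("ACDEFGHIKLMN", "AWDEFGHKKL")
        for t in (10.0, 150.0, 350.0):
            assert marginal_bits(pair, model, machine, t) == pytest.approx(
                marginal_bits(pair.reversed(), model, machine, t), abs=1e-9)

    def test_swap_symmetry_for_reversible_model(self, model, machine):
        # the bundled models satisfy detailed balance, so swapping S and T
        # leaves the marginal unchanged
        pair = SequencePair("ACDEFGHIKL", "AWDEFGHKK")
        for t in (25.0, 200.0):
            assert marginal_bits(pair, model, machine, t) == pytest.approx(
                marginal_bits(pair.swapped(), model, machine, t), abs=1e-9)


class TestInferTime:
    def test_convex_toy_objective(self):
        assert infer_time(lambda t: (t - 100.0) ** 2) == pytest.approx(100.0, abs=1e-3)

    def test_constant_objective_tie_break(self):
        assert infer_time(lambda t: 5.0) == 1.0

    def test_nonfinite_objective_rejected(self):
        with pytest.raises(InferenceError):
            infer_time(lambda t: float("nan"))


class TestLandscape:
    def test_corners_equal_marginal(self, model, machine):
        pair = SequencePair("ACDEFGHIK", "ACWEFGHIK")
        t = 80.0
        ls = landscape(pair, model, machine, t)
        i_marg = marginal_bits(pair, model, machine, t)
        assert ls.matrix[0, 0] == pytest.approx(i_marg, abs=1e-6)
        assert ls.matrix[-1, -1] == pytest.approx(i_marg, abs=1e-6)

    def test_minimum_not_below_marginal(self, model, machine):
        pair = SequencePair("ACDEFGHIK", "ACWEFGHIK")
        t = 80.0
        ls = landscape(pair, model, machine, t)
        i_marg = marginal_bits(pair, model, machine, t)
        assert np.isfinite(ls.matrix).all()
        assert ls.matrix.min() >= i_marg - 1e-6

    def test_identity_ridge_on_diagonal(self, model, machine):
        pair = SequencePair("ACDEFGHIKL", "ACDEFGHIKL")
        ls = landscape(pair, model, machine, 5.0)
        # on-diagonal cells beat their off-diagonal row neighbours
        for i in range(1, 10):
            assert ls.matrix[i, i] < ls.matrix[i, i - 1]
            assert ls.matrix[i, i] < ls.matrix[i, i + 1]

    def test_small_instance_against_enumeration(self, model, machine):
        # every interior cell is -log2(prefix-marginal * suffix-marginal),
        # both sums obtained by exhaustive enumeration
        pair = SequencePair("ACD", "AWD")
        t = 50.0
        ls = landscape(pair, model, machine, t)
        m, n = pair.shape
        for i in range(1, m):
            for j in range(1, n):
                _, pp = all_joint_probabilities(
                    SequencePair(pair.s[:i], pair.t[:j]), model, machine, t)
                _, ps = all_joint_probabilities(
                    SequencePair(pair.s[i:][::-1], pair.t[j:][::-1]),
                    model, machine, t)
                expect = -math.log2(pp.sum()) - math.log2(ps.sum())
                assert ls.matrix[i, j] == pytest.approx(expect, abs=1e-8)


class TestSignificance:
    def test_flags_follow_delta_signs(self):
        res = ComparisonResult(null_bits=1186.9, i_optimal_bits=940.7,
                               i_marginal_bits=940.4)
        sig = significance(res)
        assert sig == {"optimal_significant": True, "marginal_significant": True}

    def test_marginal_loss_to_null(self):
        res = ComparisonResult(null_bits=1277.3, i_optimal_bits=1299.8,
                               i_marginal_bits=1277.9)
        sig = significance(res)
        assert not sig["optimal_significant"]
        assert not sig["marginal_significant"]

    def test_exact_zero_rejected(self):
        res = ComparisonResult(null_bits=100.0, i_optimal_bits=100.0)
        assert significance(res)["optimal_significant"] is False


class TestComparisonResultInvariants:
    def test_deltas_are_exact_differences(self):
        res = ComparisonResult(null_bits=50.0, i_optimal_bits=45.0,
                               i_marginal_bits=44.0)
        assert res.delta_optimal_bits == 5.0
        assert res.delta_marginal_bits == 6.0

    def test_full_compare_orders_lengths(self, model, machine):
        pair = SequencePair("ACDEFGHIKLMNPQ", "ACDWFGHIKLMNPQ")
        res, _ = marginal_compare(pair, model, machine)
        opt = optimal_compare(pair, model, machine)
        assert res.i_marginal_bits <= opt.i_optimal_bits + 1e-9
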