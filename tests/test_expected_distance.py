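import numpy as np
import pytest

from alnzone.align_distance import Alignment, alignment_distance
from alnzone.errors import ConsistencyError
from alnzone.expected_distance import (
    expected_alignment_distance,
    expected_distance_profile,
)
from alnzone.mml_core import SequencePair
from alnzone.models import AlignmentMachine, MachineParameters

from oracles import (
    all_joint_probabilities,
    brute_expected_distance,
    enumerate_alignments,
    walk_distance,
)


def random_reference(rng, m, n):
    alns = enumerate_alignments(m, n)
    return alns[int(rng.integers(len(alns)))]


class TestExactExpectation:
    def test_matches_enumeration(self, model, machine, random_pair_factory):
        rng = np.random.default_rng(21)
        for _ in range(40):
            pair = random_pair_factory(rng)
            t = float(rng.uniform(2, 400))
            ref = random_reference(rng, *pair.shape)
            exact = brute_expected_distance(pair, ref, model, machine, t)
            res = expected_alignment_distance(pair, Alignment(ref), model,
                                              machine, t=t)
            assert res.raw == pytest.approx(exact, rel=1e-9, abs=1e-12)
            assert res.normalized == pytest.approx(exact / sum(pair.shape),
                                                   rel=1e-9, abs=1e-12)

    def test_concentrated_posterior_gives_near_zero(self, model, machine):
        # identical sequences at tiny Markov time: essentially all posterior
        # mass sits on the all-match path
        pair = SequencePair("ACDEFGHIKL", "ACDEFGHIKL")
        ref = Alignment("m" * 10)
        res = expected_alignment_distance(pair, ref, model, machine, t=0.5)
        assert res.raw < 1e-3

    def test_expectation_within_distance_bounds(self, model, machine,
                                                random_pair_factory):
        rng = np.random.default_rng(22)
        for _ in range(15):
            pair = random_pair_factory(rng, max_len=4)
            t = float(rng.uniform(5, 300))
            ref = random_reference(rng, *pair.shape)
            dists = [walk_distance(a, ref)
                     for a in enumerate_alignments(*pair.shape)]
            res = expected_alignment_distance(pair, Alignment(ref), model,
                                              machine, t=t)
            assert min(dists) - 1e-9 <= res.raw <= max(dists) + 1e-9

    def test_shifting_reference_off_mode_increases_expectation(self, model,
                                                               machine):
        # posterior mode of an identical pair is the main diagonal; a
        # corner-hugging reference must sit farther in expectation
        pair = SequencePair("ACDE", "ACDE")
        on_mode = expected_alignment_distance(
            pair, Alignment("mmmm"), model, machine, t=10.0)
        off_mode = expected_alignment_distance(
            pair, Alignment("iiiidddd"), model, machine, t=10.0)
        assert off_mode.raw > on_mode.raw

    def test_optimal_reference_expectation_nonnegative(self, model, machine):
        pair = SequencePair("ACDWF", "ACEWF")
        from alnzone.mml_core import optimal_compare
        opt = optimal_compare(pair, model, machine, t=80.0)
        res = expected_alignment_distance(pair, opt.optimal_alignment, model,
                                          machine, t=80.0)
        assert res.raw >= 0

    def test_inconsistent_reference_rejected(self, model, machine):
        pair = SequencePair("ACD", "WY")
        with pytest.raises(ConsistencyError):
            expected_alignment_distance(pair, Alignment("mmm"), model,
                                        machine, t=50.0)

    def test_default_time_is_inferred_marginal_time(self, model, machine):
        from alnzone.mml_core import marginal_compare
        pair = SequencePair("ACDEFGHIK", "ACWEFGHIK")
        marg, _ = marginal_compare(pair, model, machine)
        ref = Alignment("m" * 9)
        res = expected_alignment_distance(pair, ref, model, machine)
        assert res.t == pytest.approx(marg.time_marginal)

    def test_long_pair_no_underflow(self, model, machine):
        # anti-diagonal rescaling keeps a 150x150 problem finite
        rng = np.random.default_rng(23)
        from alnzone.models import AA_ORDER
        aas = np.array(list(AA_ORDER))
        s = "".join(rng.choice(aas, 150))
        t = "".join(rng.choice(aas, 150))
        pair = SequencePair(s, t)
        res = expected_alignment_distance(pair, Alignment("m" * 150), model,
                                          machine, t=200.0)
        assert np.isfinite(res.raw) and res.raw >= 0


class TestEadMatrices:
    def test_shapes_initialization_and_nonnegativity(self, model, machine):
        pair = SequencePair("ACDEF", "AWDE")
        res, mats = expected_alignment_distance(
            pair, Alignment("mmmmi"), model, machine, t=120.0,
            return_matrices=True)
        for M in (mats.ead_m, mats.ead_i, mats.ead_d,
                  mats.g_m, mats.g_i, mats.g_d):
            assert M.shape == (6, 5)
            assert np.isfinite(M).all()
            assert (M >= 0).all()
            assert M[0, 0] == 0.0
        assert np.isfinite(res.raw)


class TestProfileDecomposition:
    def test_sums_to_raw_expectation(self, model, machine, random_pair_factory):
        rng = np.random.default_rng(24)
        for _ in range(10):
            pair = random_pair_factory(rng)
            t = float(rng.uniform(5, 300))
            ref = random_reference(rng, *pair.shape)
            res = expected_alignment_distance(pair, Alignment(ref), model,
                                              machine, t=t)
            prof = expected_distance_profile(pair, Alignment(ref), model,
                                             machine, t=t)
            assert prof.shape == (sum(pair.shape) + 1,)
            assert prof.sum() == pytest.approx(res.raw, rel=1e-9, abs=1e-12)

    def test_matches_enumeration_per_diagonal(self, model, machine):
        from alnzone.align_distance import diagonal_profile
        pair = SequencePair("ACW", "AD")
        t = 140.0
        ref = "mmi"
        alns, probs = all_joint_probabilities(pair, model, machine, t)
        post = probs / probs.sum()
        pi_ref = diagonal_profile(Alignment(ref)).pi
        expect = np.zeros(6)
        for a, p in zip(alns, post):
            pa = diagonal_profile(Alignment(a)).pi
            expect += p * np.abs(pa - pi_ref)
        prof = expected_distance_profile(pair, Alignment(ref), model,
                                         machine, t=t)
        assert np.allclose(prof, expect, rtol=1e-9, atol=1e-12)

    def test_identical_pair_diagonal_reference_near_zero(self, model, machine):
        pair = SequencePair("ACDEF", "ACDEF")
        prof = expected_distance_profile(pair, Alignment("mmmmm"), model,
                                         machine, t=0.5)
        assert prof.max() < 1e-3
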