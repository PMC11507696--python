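"""Folding engine: partition function vs brute force, MEA, scoring."""

import math

import numpy as np
import pytest

from rnadecoy.core import SecondaryStructure, SequenceRecord
from rnadecoy.foldengine import (
    EnergyModel,
    brute_force_probabilities,
    ensemble_free_energy,
    enumerate_structures,
    mea_structure,
    partition_probabilities,
    score_structure,
    structure_weight,
)

from conftest import random_sequence


class TestPartitionFunction:
    def test_no_canonical_pairs_all_unpaired(self):
        probs = partition_probabilities(SequenceRecord("a", "AAAAAA"))
        assert np.all(probs.P == 0)
        assert np.allclose(probs.p_unpaired, 1.0)

    def test_two_state_closed_form(self, energy_model):
        # GAAAC has exactly two structures: empty and the single G-C pair
        probs = partition_probabilities(SequenceRecord("a", "GAAAC"), energy_model)
        w = energy_model.pair_weight("G", "C")
        assert probs.P[0, 4] == pytest.approx(w / (1 + w), abs=1e-12)

    def test_matches_brute_force_on_random_sequences(self, energy_model):
        rng = np.random.default_rng(12345)
        for _ in range(40):
            seq = random_sequence(rng, int(rng.integers(5, 13)))
            dp = partition_probabilities(seq, energy_model).P
            bf = brute_force_probabilities(seq, energy_model).P
            assert np.abs(dp - bf).max() < 1e-9

    def test_marginals_sum_to_one(self, energy_model):
        rng = np.random.default_rng(99)
        for length in (5, 20, 60):
            seq = random_sequence(rng, length)
            probs = partition_probabilities(seq, energy_model)
            assert np.abs(probs.marginals().sum(axis=1) - 1.0).max() < 1e-9

    def test_zero_extrinsic_is_identity(self, energy_model):
        seq = SequenceRecord("a", "GGGAAACCCAUGC")
        base = partition_probabilities(seq, energy_model)
        with_e = partition_probabilities(seq, energy_model,
                                         extrinsic=np.zeros((13, 13)))
        assert np.array_equal(base.P, with_e.P)

    def test_extrinsic_monotonicity(self, energy_model):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = random_sequence(rng, 15)
            base = partition_probabilities(seq, energy_model)
            nz = np.argwhere(np.triu(base.P, 1) > 0)
            if nz.size == 0:
                continue
            i, j = nz[0]
            bonus = np.zeros((15, 15))
            bonus[i, j] = bonus[j, i] = 1.0
            boosted = partition_probabilities(seq, energy_model,
                                              extrinsic=bonus, gamma=5.0)
            assert boosted.P[i, j] >= base.P[i, j]

    def test_negative_extrinsic_rejected(self, energy_model):
        seq = SequenceRecord("a", "GAAAC")
        bad = np.full((5, 5), -0.5)
        with pytest.raises(ValueError, match="nonnegative"):
            partition_probabilities(seq, energy_model, extrinsic=bad)

    def test_long_sequence_stays_finite(self, energy_model):
        # stability of the rescaled partition function on a GC-rich sequence
        seq = SequenceRecord("a", "G" * 60 + "AAAA" + "C" * 60)
        probs = partition_probabilities(seq, energy_model)
        assert np.all(np.isfinite(probs.P))
        assert probs.P.max() > 0.5


class TestBruteForce:
    def test_min_hairpin_forbids_all_pairs(self, energy_model):
        probs = brute_force_probabilities(SequenceRecord("a", "ACGU"), energy_model)
        assert np.all(probs.P == 0)

    def test_refuses_long_sequences(self, energy_model):
        with pytest.raises(ValueError, match="capped"):
            brute_force_probabilities(random_sequence(np.random.default_rng(0), 25),
                                      energy_model)

    def test_stacking_bonus_counted(self):
        model = EnergyModel(stack_energy=-2.0)
        s = "GGAAACC"
        pairs = frozenset({(0, 6), (1, 5)})
        w = structure_weight(pairs, s, model)
        expected = model.pair_weight("G", "C") ** 2 * model.stack_bonus
        assert w == pytest.approx(expected)


class TestFreeEnergy:
    def test_unpairable_sequence_is_zero(self, energy_model):
        assert ensemble_free_energy(SequenceRecord("a", "AAAA"), energy_model) == pytest.approx(0.0)

    def test_two_state_closed_form(self, energy_model):
        w = energy_model.pair_weight("G", "C")
        expected = -math.log(1 + w) / energy_model.temperature_scale
        got = ensemble_free_energy(SequenceRecord("a", "GAAAC"), energy_model)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_never_positive(self, energy_model):
        # Q >= 1 because the empty structure always contributes weight 1
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = random_sequence(rng, int(rng.integers(4, 40)))
            assert ensemble_free_energy(seq, energy_model) <= 1e-9


class TestMea:
    def test_all_zero_probabilities_give_empty_structure(self):
        probs = partition_probabilities(SequenceRecord("a", "AAAAAA"))
        assert len(mea_structure(probs)) == 0

    def test_dominant_pair_included(self):
        from rnadecoy.core import PairProbabilityMatrix
        P = np.zeros((10, 10))
        P[0, 8] = P[8, 0] = 0.9
        st = mea_structure(PairProbabilityMatrix(P), gamma_mea=1.0)
        assert (0, 8) in st.pairs

    def test_matches_exhaustive_objective(self, energy_model):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            seq = random_sequence(rng, int(rng.integers(8, 13)))
            probs = partition_probabilities(seq, energy_model)
            st = mea_structure(probs, gamma_mea=1.0)

            def objective(pairs):
                paired = {i for p in pairs for i in p}
                return (sum(2.0 * probs.P[i, j] for i, j in pairs)
                        + sum(po for i, po in enumerate(probs.p_unpaired)
                              if i not in paired))

            def pairable(i, j):
                return probs.P[i, j] > 0

            best = max(objective(p) for p in
                       enumerate_structures(len(seq), pairable, 3))
            assert objective(st.pairs) == pytest.approx(best, abs=1e-9)

    def test_result_satisfies_structure_invariants(self, energy_model):
        rng = np.random.default_rng(77)
        for _ in range(10):
            seq = random_sequence(rng, 50)
            probs = partition_probabilities(seq, energy_model)
            st = mea_structure(probs)  # constructor validates invariants
            assert st.length == 50


class TestScoreStructure:
    @pytest.mark.parametrize("pred,acc,expected", [
        ({(0, 9), (1, 8)}, {(0, 9), (1, 8), (2, 7)}, (2 / 3, 1.0)),
        ({(0, 9), (1, 8)}, {(0, 9), (1, 8)}, (1.0, 1.0)),
        (set(), {(0, 9)}, (0.0, 1.0)),
        ({(0, 9)}, set(), (1.0, 0.0)),
    ])
    def test_sensitivity_and_ppv(self, pred, acc, expected):
        p = SecondaryStructure(frozenset(pred), 10)
        a = SecondaryStructure(frozenset(acc), 10)
        assert score_structure(p, a) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_structure(SecondaryStructure(frozenset(), 10),
                            SecondaryStructure(frozenset(), 11))


class TestStructureInvariants:
    def test_pseudoknot_rejected(self):
        with pytest.raises(ValueError, match="pseudoknot"):
            SecondaryStructure(frozenset({(0, 10), (5, 15)}), 20)

    def test_shared_index_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            SecondaryStructure(frozenset({(0, 10), (0, 15)}), 20)

    def test_short_hairpin_rejected(self):
        with pytest.raises(ValueError, match="hairpin"):
            SecondaryStructure(frozenset({(0, 3)}), 10)

    def test_dot_bracket_round_trip(self):
        db = "((((...))))..((...))"
        st = SecondaryStructure.from_dot_bracket(db)
        assert st.to_dot_bracket() == db
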