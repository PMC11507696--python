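"""Feature extraction: PS/US scores, the triangular histogram, KL score,
Z-score, and the two Shannon entropies."""

import math

import numpy as np
import pytest

from rnadecoy.consensus import MultipleAlignment, run_turbo
from rnadecoy.core import PairProbabilityMatrix, SequenceGroup, SequenceRecord
from rnadecoy.features import (
    N_HISTOGRAM_BINS,
    PsUsHistogram,
    PsUsScores,
    build_histogram,
    feature_table,
    feature_vector,
    kl_score,
    ps_us_scores,
    sequence_entropy,
    structural_entropy,
    z_score,
)


class TestPsUs:
    def _two_seq_setup(self, p_first):
        # Two 10-mers pairing end to end: position 0 pairs 9 with prob p
        L = 10
        P = np.zeros((L, L))
        P[0, 9] = P[9, 0] = p_first
        probs = PairProbabilityMatrix(P)
        msa = MultipleAlignment(["GGGAAAACCC", "GGGAAAACCC"], ["a", "b"])
        return msa, [probs, probs]

    def test_downstream_paired_column_scores_one(self):
        msa, probs = self._two_seq_setup(1.0)
        scores = ps_us_scores(0, msa, probs)
        assert scores.ps[0] == pytest.approx(1.0)
        assert scores.us[0] == pytest.approx(0.0)

    def test_unpaired_column_scores_one_in_us(self):
        msa, probs = self._two_seq_setup(1.0)
        scores = ps_us_scores(0, msa, probs)
        assert scores.us[5] == pytest.approx(1.0)  # middle stays unpaired

    def test_gap_column_scores_zero(self):
        L = 5
        probs = PairProbabilityMatrix(np.zeros((L, L)))
        probs4 = PairProbabilityMatrix(np.zeros((4, 4)))
        msa = MultipleAlignment(["AC-GU", "ACAGU"], ["a", "b"])
        scores = ps_us_scores(0, msa, [probs4, probs])
        assert scores.ps[2] == 0.0 and scores.us[2] == 0.0
        assert scores.gap_mask[2]

    def test_three_sequences_average_over_others(self):
        L = 6
        flat = PairProbabilityMatrix(np.zeros((L, L)))  # all unpaired
        msa = MultipleAlignment(["AAAAAA"] * 3, list("abc"))
        scores = ps_us_scores(0, msa, [flat] * 3)
        assert np.allclose(scores.us, 1.0)

    def test_single_sequence_rejected(self):
        msa = MultipleAlignment(["ACGUA"], ["a"])
        with pytest.raises(ValueError):
            ps_us_scores(0, msa, [PairProbabilityMatrix(np.zeros((5, 5)))])


class TestHistogram:
    def test_bin_count_is_465(self):
        scores = PsUsScores(ps=np.zeros(3), us=np.zeros(3),
                            gap_mask=np.zeros(3, dtype=bool))
        hist = build_histogram(scores)
        assert hist.n_bins == 465
        assert N_HISTOGRAM_BINS == 465

    def test_single_zero_column_fills_origin_bin(self):
        scores = PsUsScores(ps=np.array([0.0]), us=np.array([0.0]),
                            gap_mask=np.array([False]))
        hist = build_histogram(scores)
        assert hist.bins[0] == pytest.approx(1.0)
        assert hist.bins.sum() == pytest.approx(1.0)

    def test_boundary_value_clamps_into_last_bin(self):
        scores = PsUsScores(ps=np.array([1.0]), us=np.array([0.0]),
                            gap_mask=np.array([False]))
        hist = build_histogram(scores)
        # bin (29, 0) is the last x index at y = 0
        from rnadecoy.features import _TRI_INDEX
        assert hist.bins[_TRI_INDEX[(29, 0)]] == pytest.approx(1.0)

    def test_all_gap_columns_warn_and_zero(self):
        scores = PsUsScores(ps=np.zeros(2), us=np.zeros(2),
                            gap_mask=np.ones(2, dtype=bool))
        with pytest.warns(UserWarning, match="gap"):
            hist = build_histogram(scores)
        assert hist.bins.sum() == 0

    def test_normalized_over_multiple_columns(self):
        scores = PsUsScores(ps=np.array([0.0, 0.5, 0.96]),
                            us=np.array([0.0, 0.4, 0.0]),
                            gap_mask=np.zeros(3, dtype=bool))
        hist = build_histogram(scores)
        assert hist.bins.sum() == pytest.approx(1.0)
        assert np.count_nonzero(hist.bins) == 3


class TestKlScore:
    def _hist(self, index, mass=1.0):
        bins = np.zeros(N_HISTOGRAM_BINS)
        bins[index] = mass
        return PsUsHistogram(bins=bins)

    def test_identical_histograms_give_zero(self):
        h = self._hist(10)
        assert kl_score(h, [h, h, h]) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.dirichlet(np.ones(N_HISTOGRAM_BINS))
            r = rng.dirichlet(np.ones(N_HISTOGRAM_BINS))
            val = kl_score(PsUsHistogram(bins=q), [PsUsHistogram(bins=r)])
            assert val >= 0

    def test_two_bin_hand_computation(self):
        # target mass in bin 0, single other histogram with mass in bin 1:
        # after pseudocounts both distributions are explicit two-level vectors
        q = np.full(N_HISTOGRAM_BINS, 1.0 / N_HISTOGRAM_BINS)
        r = q.copy()
        q[0] += 1.0
        r[1] += 1.0
        q /= 2.0
        r /= 2.0
        expected = float(np.sum(q * np.log(q / r)))
        got = kl_score(self._hist(0), [self._hist(1)])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_requires_other_histograms(self):
        with pytest.raises(ValueError):
            kl_score(self._hist(0), [])


class TestZScore:
    def test_target_at_mean_is_zero(self):
        assert z_score(-11.0, [-10.0, -12.0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # others mean -11, population sigma 1
        assert z_score(-13.0, [-10.0, -12.0]) == pytest.approx(-2.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        others = list(rng.normal(size=6))
        base = z_score(0.7, others)
        shifted = z_score(0.7 + 5.0, [o + 5.0 for o in others])
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_zero_spread_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="spread"):
            assert z_score(-5.0, [-1.0, -1.0]) == 0.0

    def test_needs_two_others(self):
        with pytest.raises(ValueError):
            z_score(0.0, [1.0])


class TestSequenceEntropy:
    def test_identical_rows_give_zero(self):
        msa = MultipleAlignment(["ACGU", "ACGU", "ACGU"])
        assert sequence_entropy(0, msa) == pytest.approx(0.0)

    def test_single_mismatched_column(self):
        msa = MultipleAlignment(["A", "C"])
        assert sequence_entropy(0, msa) == pytest.approx(0.5 * math.log10(0.5))

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            rows = ["".join(rng.choice(list("ACGU-"), size=12)) for _ in range(4)]
            val = sequence_entropy(0, MultipleAlignment(rows))
            assert -math.log10(5) <= val <= 0


class TestStructuralEntropy:
    def test_deterministic_matrix_gives_zero(self):
        P = np.zeros((10, 10))
        P[0, 9] = P[9, 0] = 1.0
        assert structural_entropy(PairProbabilityMatrix(P)) == pytest.approx(0.0)

    def test_half_probability_single_pair(self):
        P = np.zeros((10, 10))
        P[0, 9] = P[9, 0] = 0.5
        expected = -(0.5 * math.log10(0.5)) / 10
        assert structural_entropy(PairProbabilityMatrix(P)) == pytest.approx(expected)

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            from conftest import random_sequence
            from rnadecoy.foldengine import partition_probabilities
            probs = partition_probabilities(random_sequence(rng, 30))
            assert structural_entropy(probs) >= 0


class TestFeatureVector:
    def test_identical_sequences_have_flat_features(self):
        group = SequenceGroup([SequenceRecord(f"s{i}", "GGGAAAACCCAAAGGGAAACCC")
                               for i in range(4)])
        res = run_turbo(group)
        with pytest.warns(UserWarning, match="spread"):
            fv = feature_vector(0, res)
        assert fv.seq_entropy == pytest.approx(0.0)
        assert fv.kl_score == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self):
        group = SequenceGroup([SequenceRecord("a", "GGGAAACCC"),
                               SequenceRecord("b", "GGGAAACCC")])
        res = run_turbo(group)
        with pytest.raises(ValueError, match="at least 3"):
            feature_vector(0, res)

    def test_table_matches_single_vector(self, turbo_result):
        table = feature_table(turbo_result)
        fv = feature_vector(2, turbo_result)
        row = table.iloc[2]
        assert row["kl_score"] == pytest.approx(fv.kl_score)
        assert row["ss_delta"] == pytest.approx(fv.ss_delta)

    def test_decoy_has_largest_kl_in_demo_group(self, group_with_decoy, turbo_result):
        table = feature_table(turbo_result)
        decoy_idx = group_with_decoy.labels.index("decoy:shuffled")
        assert table["kl_score"].idxmax() == decoy_idx

    def test_deterministic(self, turbo_result):
        t1 = feature_table(turbo_result)
        t2 = feature_table(turbo_result)
        assert t1.equals(t2)

    def test_histogram_table_shape(self, turbo_result):
        from rnadecoy.features import histogram_table

        table = histogram_table(turbo_result)
        assert table.shape == (len(turbo_result.group), 1 + 465)
        bins = table.drop(columns="id").to_numpy()
        assert np.allclose(bins.sum(axis=1), 1.0)


class TestFeatureSeparation:
    def test_decoys_stand_out_across_seeded_trials(self):
        """Across 50 synthetic groups the mean decoy KL score exceeds the
        mean homolog KL score, and decoys' structural-entropy drop
        (initial - final) is positive in the majority of trials."""
        from rnadecoy.decoygen import ShuffleSpec, shuffle_decoy
        from rnadecoy.synthetic import FamilySpec, family_identity, generate_family

        kl_decoy, kl_homolog, ss_delta_decoy = [], [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fam = generate_family(FamilySpec(seed=int(rng.integers(2 ** 31)),
                                             n_members=8, length=60,
                                             target_identity=0.65,
                                             name=f"f{seed}"))
            keep = family_identity(fam)
            if seed % 2 == 0:
                decoy = shuffle_decoy(fam.members[7],
                                      ShuffleSpec(keep_fraction=keep,
                                                  seed=int(rng.integers(2 ** 31))))
            else:
                other = generate_family(FamilySpec(seed=int(rng.integers(2 ** 31)) + 1,
                                                   n_members=3, length=70,
                                                   target_identity=0.65,
                                                   name=f"o{seed}"))
                decoy = other.members[0]
            group = SequenceGroup(list(fam.members[:6]) + [decoy])
            table = feature_table(run_turbo(group))
            kl_decoy.append(table.kl_score.iloc[6])
            kl_homolog.extend(table.kl_score.iloc[:6])
            ss_delta_decoy.append(table.ss_delta.iloc[6])
        assert np.mean(kl_decoy) > np.mean(kl_homolog)
        assert np.mean(np.asarray(ss_delta_decoy) > 0) > 0.5
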