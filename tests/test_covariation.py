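import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micov import (
    Alignment,
    Measure,
    SimulationSpec,
    column_distribution,
    group_distribution,
    group_joint_distribution,
    joint_distribution,
    joint_entropy,
    mi_scores,
    mib_scores,
    mibp_scores,
    mip_scores,
    modified_marginal,
    score_all_pairs,
    simulate_msa,
    uniform_background,
)
from micov.background import group_background, taylor_groups
from conftest import random_alignment
import oracles


class TestColumnDistribution:
    def test_fully_conserved_column(self, toy):
        dist = column_distribution(toy, 0)
        assert dist.frequency("D") == 1.0
        assert dist.frequencies.sum() == pytest.approx(1.0)
        assert dist.effective_count == 6

    def test_mixed_column_frequencies(self, toy):
        dist = column_distribution(toy, 5)  # E,F,D,D,T,T
        assert dist.frequency("E") == pytest.approx(1 / 6)
        assert dist.frequency("F") == pytest.approx(1 / 6)
        assert dist.frequency("D") == pytest.approx(2 / 6)
        assert dist.frequency("T") == pytest.approx(2 / 6)

    def test_gaps_excluded_from_counts(self):
        aln = Alignment(("a", "b", "c", "d"), ("A", "-", "A", "-"))
        dist = column_distribution(aln, 0)
        assert dist.frequency("A") == 1.0
        assert dist.effective_count == 2

    def test_all_gap_column_is_degenerate(self):
        aln = Alignment(("a", "b"), ("-A", "-C"))
        assert column_distribution(aln, 0).degenerate


class TestJointDistribution:
    def test_bijectively_covarying_pair(self, toy):
        joint = joint_distribution(toy, 2, 3)  # W/Y vs A/C
        W, A = "ACDEFGHIKLMNPQRSTVWY".index("W"), 0
        Y, C = "ACDEFGHIKLMNPQRSTVWY".index("Y"), 1
        assert joint.frequencies[W, A] == pytest.approx(0.5)
        assert joint.frequencies[Y, C] == pytest.approx(0.5)
        assert joint.frequencies.sum() == pytest.approx(1.0)

    def test_conserved_pair_is_a_point_mass(self, toy):
        joint = joint_distribution(toy, 0, 1)
        assert joint.frequencies.max() == pytest.approx(1.0)

    def test_marginalization_recovers_column_distribution_when_gap_free(self, toy):
        joint = joint_distribution(toy, 2, 5)
        np.testing.assert_allclose(
            joint.frequencies.sum(axis=1), column_distribution(toy, 2).frequencies
        )

    def test_same_column_rejected(self, toy):
        with pytest.raises(ValueError):
            joint_distribution(toy, 1, 1)


class TestGroupDistributions:
    def test_group_profile_of_mixed_column(self, toy, scheme):
        dist = group_distribution(toy, 3, scheme)  # A/C column
        by_name = dict(zip(scheme.names, dist.frequencies))
        assert by_name["hydrophobic"] == pytest.approx(1.0)
        assert by_name["tiny"] == pytest.approx(1.0)
        assert by_name["small"] == pytest.approx(1.0)
        assert by_name["polar"] == pytest.approx(0.5)  # C only
        assert by_name["charged"] == 0.0

    def test_entries_can_sum_above_one(self, toy, scheme):
        dist = group_distribution(toy, 0, scheme)  # conserved D
        assert dist.frequencies.sum() == pytest.approx(4.0)  # 4 groups contain D
        assert (dist.frequencies <= 1.0).all()

    def test_joint_table_matches_brute_force(self, toy, scheme):
        joint = group_joint_distribution(toy, 4, 5, scheme)
        rows = oracles.pair_rows(toy.column(4), toy.column(5))
        _, _, expected = oracles._group_tables(rows)
        names = scheme.names
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert joint.frequencies[i, j] == pytest.approx(
                    expected.get((a, b), 0.0)
                ), (a, b)


class TestEntropyAndModifiedMarginal:
    def test_point_mass_and_two_outcome_entropies(self, toy):
        assert joint_entropy(joint_distribution(toy, 0, 1)) == 0.0
        assert joint_entropy(joint_distribution(toy, 2, 3)) == pytest.approx(
            math.log(2)
        )

    def test_joint_entropy_dominates_column_entropies(self, toy):
        from itertools import combinations

        for k, l in combinations(range(6), 2):
            h_joint = joint_entropy(joint_distribution(toy, k, l))
            h_k = oracles.column_entropy(toy.column(k))
            h_l = oracles.column_entropy(toy.column(l))
            assert h_joint >= max(h_k, h_l) - 1e-12

    def test_uniform_background_leaves_marginal_unchanged(self, toy):
        col = column_distribution(toy, 5)
        out = modified_marginal(col, uniform_background())
        np.testing.assert_allclose(out.frequencies, col.frequencies)

    def test_conserved_column_maps_to_point_mass_for_any_background(self, toy, q):
        for k in (0, 1):  # conserved D and conserved A
            out = modified_marginal(column_distribution(toy, k), q)
            assert out.frequencies.max() == pytest.approx(1.0)

    def test_background_division_shifts_mass_to_rare_residues(self, toy, q):
        col = column_distribution(toy, 2)  # W/Y half-half; W is rarer
        out = modified_marginal(col, q)
        assert out.frequency("W") > out.frequency("Y")
        assert out.frequencies.sum() == pytest.approx(1.0)

    def test_degenerate_column_rejected(self):
        aln = Alignment(("a", "b"), ("-A", "-C"))
        with pytest.raises(ValueError):
            modified_marginal(column_distribution(aln, 0))


class TestMeasureExamples:
    """Spot checks against the reference alignment's known scores."""

    def test_mi_prime_examples(self, toy):
        assert mi_scores(toy, 2, 3).normalized == pytest.approx(1.0)
        assert mi_scores(toy, 2, 5).normalized == pytest.approx(0.296, abs=5e-4)
        assert mi_scores(toy, 0, 2).normalized == 0.0  # conserved column

    def test_mib_prime_examples(self, toy, q):
        assert mib_scores(toy, 0, 3, q).normalized == pytest.approx(0.237, abs=5e-4)
        assert mib_scores(toy, 3, 4, q).normalized == pytest.approx(1.378, abs=1e-3)

    def test_mib_prime_can_exceed_one_without_clamping(self, toy, q):
        assert mib_scores(toy, 3, 4, q).normalized > 1.0

    def test_mip_prime_examples(self, toy, scheme):
        assert mip_scores(toy, 3, 4, scheme).normalized == pytest.approx(
            0.077, abs=5e-4
        )
        assert mip_scores(toy, 4, 5, scheme).normalized == pytest.approx(
            0.053, abs=5e-4
        )

    def test_property_conserved_column_silences_mip(self, toy, scheme):
        # W and Y share every Taylor group, so column 3 is property-conserved
        for other in (0, 1, 3, 4, 5):
            assert mip_scores(toy, 2, other, scheme).normalized == pytest.approx(
                0.0, abs=1e-12
            )

    def test_mibp_prime_examples(self, toy, scheme, qp):
        assert mibp_scores(toy, 0, 1, scheme, qp).normalized == pytest.approx(
            33.425, abs=1e-3
        )
        assert mibp_scores(toy, 3, 5, scheme, qp).normalized == pytest.approx(
            4.476, abs=1e-3
        )

    def test_mibp_scores_doubly_conserved_pairs_nonzero(self, toy, scheme, qp):
        # unlike MI'/MIB'/MIP', the property-background measure separates
        # conserved pairs instead of flattening them to 0
        assert mibp_scores(toy, 0, 1, scheme, qp).normalized > 0


class TestMeasureProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_entropy_identity_for_raw_mi(self, seed):
        aln = random_alignment(seed=seed, n_sequences=25, n_columns=5)
        for k in range(4):
            score = mi_scores(aln, k, k + 1)
            expected = (
                oracles.column_entropy(aln.column(k))
                + oracles.column_entropy(aln.column(k + 1))
                - oracles.joint_entropy(aln.column(k), aln.column(k + 1))
            )
            assert score.raw == pytest.approx(expected, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_mi_prime_bounded_between_zero_and_one(self, seed):
        aln = random_alignment(seed=seed, n_sequences=12, n_columns=4)
        for k in range(3):
            value = mi_scores(aln, k, k + 1).normalized
            assert -1e-12 <= value <= 1 + 1e-12

    def test_mi_prime_is_one_exactly_for_bijective_covariation(self):
        aln = simulate_msa(
            SimulationSpec(
                n_sequences=200, n_columns=4, coevolving_pairs=((0, 1, 1.0),), seed=7
            )
        )
        assert mi_scores(aln, 0, 1).normalized == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_all_measures_symmetric_under_column_swap(self, seed, q, scheme, qp):
        aln = random_alignment(seed=seed, n_sequences=20, n_columns=4)
        for k in range(3):
            assert mi_scores(aln, k, k + 1).normalized == pytest.approx(
                mi_scores(aln, k + 1, k).normalized
            )
            assert mib_scores(aln, k, k + 1, q).normalized == pytest.approx(
                mib_scores(aln, k + 1, k, q).normalized
            )
            assert mip_scores(aln, k, k + 1, scheme).normalized == pytest.approx(
                mip_scores(aln, k + 1, k, scheme).normalized
            )
            assert mibp_scores(aln, k, k + 1, scheme, qp).normalized == pytest.approx(
                mibp_scores(aln, k + 1, k, scheme, qp).normalized
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_normalized_scores_agree_with_base_two_oracle(self, seed, q, scheme, qp):
        """Dual-route check: independent base-2 implementation, same values."""
        aln = random_alignment(seed=seed, n_sequences=25, n_columns=4)
        bg = dict(q.probabilities)
        for k in range(3):
            ck, cl = aln.column(k), aln.column(k + 1)
            assert mi_scores(aln, k, k + 1).normalized == pytest.approx(
                oracles.mi_normalized(ck, cl, base=2), abs=1e-9
            )
            assert mib_scores(aln, k, k + 1, q).normalized == pytest.approx(
                oracles.mib_normalized(ck, cl, bg, base=2), abs=1e-9
            )
            assert mip_scores(aln, k, k + 1, scheme).normalized == pytest.approx(
                oracles.mip_normalized(ck, cl, base=2), abs=1e-9
            )
            assert mibp_scores(aln, k, k + 1, scheme, qp).normalized == pytest.approx(
                oracles.mibp_normalized(ck, cl, bg, base=2), abs=1e-9
            )

    def test_uniform_background_reduces_mib_to_mi(self, toy):
        uniform = uniform_background()
        for k in range(5):
            for l in range(k + 1, 6):
                assert mib_scores(toy, k, l, uniform).normalized == pytest.approx(
                    mi_scores(toy, k, l).normalized, abs=1e-12
                )

    def test_property_identical_alphabet_columns_silence_mip(self, scheme):
        # columns over {G,A} or {I,L} are property-conserved just like W/Y
        aln = Alignment(
            ("a", "b", "c", "d"),
            ("GIAC", "AIAD", "GLCC", "ALCD"),
        )
        assert mip_scores(aln, 0, 3, scheme).normalized == pytest.approx(0, abs=1e-12)
        assert mip_scores(aln, 1, 3, scheme).normalized == pytest.approx(0, abs=1e-12)


class TestScoreAllPairs:
    def test_matrix_matches_per_pair_calls_and_is_symmetric(self, toy, q):
        matrix = score_all_pairs(toy, Measure.MIB)
        np.testing.assert_allclose(matrix.normalized, matrix.normalized.T)
        np.testing.assert_allclose(np.diag(matrix.normalized), 0.0)
        assert matrix.value(1, 4) == pytest.approx(
            mib_scores(toy, 0, 3, q).normalized
        )

    def test_two_column_alignment_yields_single_pair(self):
        aln = Alignment(("a", "b", "c"), ("AC", "AD", "CC"))
        matrix = score_all_pairs(aln, "MI")
        assert len(list(matrix.pairs())) == 1

    def test_degenerate_pairs_flagged_not_fatal(self):
        # columns 1 and 2 share no jointly non-gap row
        aln = Alignment(("a", "b"), ("A-C", "-AC"))
        matrix = score_all_pairs(aln, Measure.MI)
        assert bool(matrix.degenerate[0, 1])
        assert math.isnan(matrix.normalized[0, 1])
        assert not matrix.degenerate[0, 2]

    def test_single_column_rejected(self):
        aln = Alignment(("a",), ("A",))
        with pytest.raises(ValueError):
            score_all_pairs(aln, Measure.MI)

    def test_long_frame_layout(self, toy):
        frame = score_all_pairs(toy, Measure.MI).to_long_frame()
        assert list(frame.columns) == ["col_k", "col_l", "raw", "normalized", "measure"]
        assert len(frame) == 15
        assert (frame["measure"] == "MI").all()
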