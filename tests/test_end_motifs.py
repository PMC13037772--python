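"""Fragment-end base composition, background bias, and group differences."""

import numpy as np
import pytest

from cffrag.core_io import Fragment, Genome, revcomp
from cffrag.end_motifs import (
    BASES,
    bias_vs_background,
    end_context_frequencies,
    group_difference,
    total_bias_per_position,
)
from cffrag.synthetic_cohort import (
    CANINE_HEALTHY,
    CANINE_TUMOR,
    SubjectTruth,
    sample_fragments,
)


def _matrix_from_hand_read(seq, start, end, k):
    """Independent oracle: build the expected matrix by string slicing."""
    left = seq[start - k : start + k]
    right = revcomp(seq[end - k : end + k])
    counts = np.zeros((2 * k, 4))
    for window in (left, right):
        for i, base in enumerate(window):
            counts[i, BASES.index(base)] += 1
    return counts / 2


class TestEndContextFrequencies:
    def test_all_a_genome_is_deterministic_a_t_split(self):
        # left 5' ends read A; right 5' ends are read on the reverse strand,
        # so an all-A genome yields exactly half A and half T at every position
        g = Genome({"c": "A" * 1_000})
        frags = [Fragment("c", 100, 300), Fragment("c", 400, 560)]
        mat = end_context_frequencies(frags, g, k=5)
        np.testing.assert_allclose(mat.values[:, 0], 0.5)
        np.testing.assert_allclose(mat.values[:, 3], 0.5)
        np.testing.assert_allclose(mat.values[:, 1:3], 0.0)
        assert mat.n_ends == 4

    def test_single_fragment_matches_hand_read(self):
        seq = "AACGTTACGTAACCGGTTGACATG"
        g = Genome({"c": seq})
        k, start, end = 3, 5, 15
        mat = end_context_frequencies([Fragment("c", start, end)], g, k=k)
        np.testing.assert_allclose(mat.values, _matrix_from_hand_read(seq, start, end, k))

    def test_reverse_complement_symmetry_on_palindrome(self):
        seq = "ACGT" * 50  # revcomp(seq) == seq
        g = Genome({"c": seq})
        L = len(seq)
        a = end_context_frequencies([Fragment("c", 20, 60)], g, k=4)
        b = end_context_frequencies([Fragment("c", L - 60, L - 20)], g, k=4)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_window_off_contig_skipped_and_counted(self):
        g = Genome({"c": "ACGT" * 30})
        mat = end_context_frequencies(
            [Fragment("c", 2, 50), Fragment("c", 30, 70)], g, k=5
        )
        assert mat.n_skipped == 1  # left window of the first fragment runs off
        assert mat.n_ends == 3

    def test_length_range_restricts_fragments(self):
        g = Genome({"c": "A" * 500 + "C" * 500})
        short = Fragment("c", 100, 180)
        long_ = Fragment("c", 520, 900)
        mat = end_context_frequencies([short, long_], g, k=2, length_range=(50, 200))
        # only the A-side fragment survives: A forward plus T on the reverse strand
        np.testing.assert_allclose(mat.values[:, [0, 3]], 0.5)
        np.testing.assert_allclose(mat.values[:, 1:3], 0.0)

    def test_frequencies_normalized_per_position(self, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=200,
                                    genome=toy_genome, seed=2)
        mat = end_context_frequencies(frags, toy_genome)
        np.testing.assert_allclose(mat.values.sum(axis=1), 1.0, atol=1e-9)


class TestBiasVsBackground:
    def test_all_a_genome_zero_bias(self):
        g = Genome({"c": "A" * 2_000})
        mat = end_context_frequencies([Fragment("c", 500, 700)], g, k=4)
        bias = bias_vs_background(mat, g, n_background=2_000, seed=0)
        np.testing.assert_allclose(bias.values, 0.0, atol=1e-12)

    def test_unbiased_placement_gives_null_bias(self, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=400,
                                    genome=toy_genome, seed=3, apply_end_bias=False)
        mat = end_context_frequencies(frags, toy_genome)
        bias = bias_vs_background(mat, toy_genome, n_background=100_000, seed=1)
        se = np.sqrt(0.25 * 0.75 / mat.n_ends)
        assert np.abs(bias.values).max() < 4 * se

    def test_planted_t_enrichment_recovered_every_seed(self, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        for seed in range(10):
            frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR,
                                        depth=400, genome=toy_genome, seed=seed,
                                        apply_end_bias=True)
            mat = end_context_frequencies(frags, toy_genome)
            bias = bias_vs_background(mat, toy_genome, n_background=50_000, seed=seed)
            flat = np.abs(bias.values).ravel()
            top2 = {(int(i // 4) - mat.k, BASES[i % 4]) for i in np.argsort(flat)[-2:]}
            assert top2 == {(-1, "T"), (-2, "T")}

    def test_bias_rows_sum_to_zero(self, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=100,
                                    genome=toy_genome, seed=4)
        mat = end_context_frequencies(frags, toy_genome)
        bias = bias_vs_background(mat, toy_genome, n_background=20_000, seed=2)
        np.testing.assert_allclose(bias.values.sum(axis=1), 0.0, atol=1e-9)

    def test_length_restricted_bias_lower_when_planted_on_long_only(self, toy_genome):
        # bias applied only to long fragments: the short stratum shows less
        subj = SubjectTruth("H1", "healthy", 0.0)
        biased, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=2_000,
                                     genome=toy_genome, seed=5, apply_end_bias=True)
        unbiased, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=2_000,
                                       genome=toy_genome, seed=6, apply_end_bias=False)
        frags = [f for f in biased if f.length > 125] + \
                [f for f in unbiased if f.length <= 125]
        short_mat = end_context_frequencies(frags, toy_genome, length_range=(50, 125))
        long_mat = end_context_frequencies(frags, toy_genome, length_range=(126, 10_000))
        short_bias = bias_vs_background(short_mat, toy_genome, 50_000, seed=7)
        long_bias = bias_vs_background(long_mat, toy_genome, 50_000, seed=7)
        k = short_mat.k
        upstream = slice(k - 2, k)  # the planted positions -2, -1
        assert total_bias_per_position(short_bias)[upstream].sum() < \
            total_bias_per_position(long_bias)[upstream].sum()


class TestGroupDifference:
    def _matrices(self, genome, preset, seeds, tumor=CANINE_TUMOR):
        out = []
        for seed in seeds:
            subj = SubjectTruth("S", "healthy", 0.0)
            frags, _ = sample_fragments(subj, preset, tumor, depth=150,
                                        genome=genome, seed=seed)
            out.append(end_context_frequencies(frags, genome))
        return out

    def test_identical_groups_give_zero(self, toy_genome):
        mats = self._matrices(toy_genome, CANINE_HEALTHY, (0, 1))
        np.testing.assert_allclose(group_difference(mats, mats), 0.0, atol=1e-12)

    def test_antisymmetric_under_swap(self, toy_genome):
        a = self._matrices(toy_genome, CANINE_HEALTHY, (0, 1))
        b = self._matrices(toy_genome, CANINE_TUMOR, (2, 3))
        np.testing.assert_allclose(group_difference(a, b), -group_difference(b, a),
                                   atol=1e-12)

    def test_healthy_vs_tumor_sign_matches_planted_pwms(self, toy_genome):
        # healthy canine plants stronger T at -1/-2 than the tumor preset
        a = self._matrices(toy_genome, CANINE_HEALTHY, (0, 1, 2))
        b = self._matrices(toy_genome, CANINE_TUMOR, (3, 4, 5))
        diff = group_difference(a, b)
        k = a[0].k
        t_col = BASES.index("T")
        assert diff[k - 1, t_col] > 0 and diff[k - 2, t_col] > 0

    def test_empty_group_rejected(self, toy_genome):
        mats = self._matrices(toy_genome, CANINE_HEALTHY, (0,))
        with pytest.raises(ValueError, match="at least one"):
            group_difference(mats, [])


class TestTotalBias:
    def test_zero_and_arithmetic(self, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=100,
                                    genome=toy_genome, seed=8)
        mat = end_context_frequencies(frags, toy_genome)
        bias = bias_vs_background(mat, toy_genome, 20_000, seed=3)
        bias.values[:] = 0.0
        assert total_bias_per_position(bias).tolist() == [0.0] * (2 * mat.k)
        bias.values[0, 3] = 0.1
        bias.values[0, 0] = -0.1
        assert total_bias_per_position(bias)[0] == pytest.approx(0.2)
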