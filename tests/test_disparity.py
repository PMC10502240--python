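from itertools import combinations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from epimodal.disparity import (
    SamplePair,
    label_similarity_spearman,
    percentile_partition,
    profile_similarity,
    rank_sum_one_sided,
    run_disparity_test,
    sequence_similarity,
)
from epimodal.genome_io import GenomeAssembly
from epimodal.hic_io import BinGrid, InteractionMatrix


class TestSimilarityMetrics:
    def test_sequence_identity_examples(self):
        assert sequence_similarity("ACGT", "ACGT") == 1.0
        assert sequence_similarity("AAAA", "AAAT") == 0.75
        # N positions are masked: 3 comparable positions, all matching
        assert sequence_similarity("ANAA", "ATAA") == 1.0

    def test_sequence_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            sequence_similarity("AA", "AAA")

    def test_all_n_pair_scores_zero(self):
        assert sequence_similarity("NN", "NN") == 0.0

    def test_profile_jaccard_examples(self):
        assert profile_similarity([1, 0, 1], [1, 0, 1]) == 1.0
        assert profile_similarity([1, 0, 1], [1, 1, 0]) == pytest.approx(1 / 3)
        assert profile_similarity([1, 0, 0], [0, 0, 1]) == 0.0

    def test_profile_both_empty_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            profile_similarity([0, 0], [0, 0])


def _pair(i, seq, prof, freq=1.0):
    return SamplePair(i=i, j=i + 100, seq_sim=seq, prof_sim=prof, freq=freq)


class TestPercentilePartition:
    def test_identical_similarities_all_consistent(self):
        pairs = [_pair(i, 0.5, 0.5) for i in range(4)]
        part = percentile_partition(pairs, margin=10)
        assert len(part.consistent) == 4 and not part.over and not part.under

    def test_rank_arithmetic_example(self):
        # seq percentiles (25,50,75,100), prof percentiles reversed
        seqs = [0.1, 0.4, 0.6, 0.9]
        profs = [0.9, 0.6, 0.4, 0.1]
        pairs = [_pair(i, s, p) for i, (s, p) in enumerate(zip(seqs, profs))]
        part = percentile_partition(pairs, margin=10)
        assert {p.i for p in part.under} == {0, 1}
        assert {p.i for p in part.over} == {2, 3}

    def test_extreme_margin_all_consistent(self):
        pairs = [_pair(i, s, 1 - s) for i, s in enumerate([0.1, 0.5, 0.9])]
        part = percentile_partition(pairs, margin=99.9)
        assert len(part.consistent) == 3

    @pytest.mark.parametrize("margin", [0, 100, -5])
    def test_margin_bounds(self, margin):
        with pytest.raises(ValueError, match="margin"):
            percentile_partition([_pair(0, 0.1, 0.2), _pair(1, 0.3, 0.4)], margin)

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=2, max_size=30))
    def test_cells_disjoint_and_exhaustive(self, sims):
        pairs = [_pair(i, s, p) for i, (s, p) in enumerate(sims)]
        part = percentile_partition(pairs, margin=10)
        cells = part.cells()
        assert sum(len(c) for c in cells.values()) == len(pairs)
        ids = [p.i for c in cells.values() for p in c]
        assert len(set(ids)) == len(ids)


def brute_force_p(x, y, alternative):
    """Independent oracle: enumerate every assignment of the pooled values
    to the x positions and count assignments at least as extreme in the
    Mann-Whitney U statistic (computed by direct pairwise comparison)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(x, y)
    count = total = 0
    for subset in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        u = u_stat(xs, ys)
        total += 1
        if alternative == "greater":
            count += u >= u_obs - 1e-12
        else:
            count += u <= u_obs + 1e-12
    return count / total


class TestRankSumOneSided:
    def test_worked_examples(self):
        assert rank_sum_one_sided([1, 2], [3, 4], "greater") == 1.0
        assert rank_sum_one_sided([1, 2], [3, 4], "less") == pytest.approx(1 / 6)
        assert rank_sum_one_sided([5], [1, 2, 3], "greater") == pytest.approx(1 / 4)

    def test_identical_samples_not_significant(self):
        for alt in ("less", "greater"):
            assert rank_sum_one_sided([1, 2, 3], [1, 2, 3], alt) >= 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_one_sided([], [1], "less")

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(1, 5), rng.integers(1, 5)
        # small integer support induces heavy ties
        x = rng.integers(0, 4, nx).astype(float)
        y = rng.integers(0, 4, ny).astype(float)
        for alt in ("less", "greater"):
            assert rank_sum_one_sided(x, y, alt) == pytest.approx(
                brute_force_p(x, y, alt))

    def test_normal_branch_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 30)
        for alt in ("less", "greater"):
            ours = rank_sum_one_sided(x, y, alt)
            ref = mannwhitneyu(x, y, alternative=alt, method="asymptotic").pvalue
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_monotone_in_location_shift(self):
        # inflating every x value never increases the "greater" p-value
        rng = np.random.default_rng(3)
        x = rng.normal(1, 1, 8)
        y = rng.normal(0, 1, 9)
        p0 = rank_sum_one_sided(x, y, "greater")
        p1 = rank_sum_one_sided(x + 2.0, y, "greater")
        assert p1 <= p0


def _toy_dataset(n_events=4, n_windows=30, seed=0):
    rng = np.random.default_rng(seed)
    sequences = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(n_windows)]
    profiles = (rng.random((n_windows, n_events)) < 0.4).astype(int)
    profiles[:, 0] = 1  # avoid undefined all-zero pairs
    asm = GenomeAssembly(["c1"], {"c1": "A" * (n_windows * 100)})
    grid = BinGrid.from_assembly(asm, resolution=100)
    bins = np.arange(n_windows)
    return sequences, profiles, bins, grid


class TestRunDisparityTest:
    def test_all_equal_frequencies_not_significant(self):
        sequences, profiles, bins, grid = _toy_dataset()
        matrix = InteractionMatrix(grid, sp.csr_matrix(np.ones((30, 30))))
        report = run_disparity_test(sequences, profiles, bins, matrix,
                                    frac=0.5, repeats=3, seed=1)
        for p in report.under_p + report.over_p:
            assert np.isnan(p) or p >= 0.5

    def test_planted_under_pairs_detected(self):
        # hand-planted composition: the partition is driven by similarity
        # percentiles; give high-profile-similarity (under) pairs strictly
        # larger frequencies via a community block in the matrix
        sequences, profiles, bins, grid = _toy_dataset(seed=2)
        community = bins % 2 == 0
        profiles[community] = [1, 1, 1, 0]
        profiles[~community] = np.array(
            [[1, 0, 0, 0]] * (len(bins) - community.sum()))
        profiles[~community, 3] = (np.arange((~community).sum()) % 2)
        freq = np.where(np.logical_and.outer(community, community), 50.0, 1.0)
        rng = np.random.default_rng(4)
        freq = freq + rng.random((30, 30))
        freq = np.maximum(freq, freq.T)
        matrix = InteractionMatrix(grid, sp.csr_matrix(freq))
        report = run_disparity_test(sequences, profiles, bins, matrix,
                                    frac=0.9, repeats=3, margin=10, seed=0)
        assert all(p < 0.05 for p in report.under_p)

    def test_too_small_fraction_instructs_larger(self):
        sequences, profiles, bins, grid = _toy_dataset()
        matrix = InteractionMatrix(grid, sp.csr_matrix(np.ones((30, 30))))
        with pytest.raises(ValueError, match="increase frac"):
            run_disparity_test(sequences, profiles, bins, matrix, frac=0.01)

    def test_empty_cell_records_nan_not_exception(self):
        sequences, profiles, bins, grid = _toy_dataset()
        # only two windows drawn -> one pair -> partition impossible
        matrix = InteractionMatrix(grid, sp.csr_matrix(np.ones((30, 30))))
        report = run_disparity_test(sequences, profiles, bins, matrix,
                                    frac=0.07, repeats=2, seed=0)
        assert len(report.under_p) == 2  # NaNs allowed, no exception


class TestLabelSimilaritySpearman:
    def test_perfect_predictions_give_rho_one(self):
        rng = np.random.default_rng(0)
        profiles = (rng.random((50, 6)) < 0.5).astype(float)
        profiles[:, 0] = 1
        out = label_similarity_spearman(profiles, profiles, n_pairs=300, seed=1)
        assert out["all"] == pytest.approx(1.0)

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(0)
        profiles = (rng.random((200, 8)) < 0.5).astype(float)
        profiles[:, 0] = 1
        preds = rng.random((200, 8))
        out = label_similarity_spearman(profiles, preds, n_pairs=1000, seed=2)
        assert abs(out["all"]) < 0.1

    def test_partition_cells_when_sequences_given(self):
        rng = np.random.default_rng(0)
        profiles = (rng.random((60, 6)) < 0.5).astype(float)
        profiles[:, 0] = 1
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(60)]
        out = label_similarity_spearman(profiles, profiles, n_pairs=400,
                                        seed=3, sequences=seqs)
        assert set(out) == {"over", "consistent", "under"}
        for rho in out.values():
            assert np.isnan(rho) or rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            label_similarity_spearman(np.ones((5, 2)), np.ones((5, 2)), n_pairs=2)
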