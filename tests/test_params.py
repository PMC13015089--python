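"""Counting-lemma thresholds, FNR/FPR model and parameter deduction."""

import itertools
import math

import numpy as np
import pytest

from epsalign.params import (
    EpsilonSpec,
    KmerStatsModel,
    deduce_params,
    distinct_kmer_stats,
    expected_occurrences,
    fnr,
    fpr,
    lemma_threshold,
    max_lossless_word_size,
    spurious_kmer_prob,
)
from epsalign.shapes import SeedShape, parse_shape


def surviving_kmers(l: int, error_positions, k: int) -> int:
    """Independent oracle: count error-free k-windows from an error layout."""
    runs, prev = [], -1
    for p in sorted(error_positions):
        runs.append(p - prev - 1)
        prev = p
    runs.append(l - 1 - prev)
    return sum(max(0, r - k + 1) for r in runs)


def fnr_bruteforce(l: int, e: int, k: int, t: int) -> float:
    if t == 0:
        return 0.0
    below = sum(
        surviving_kmers(l, pos, k) < t
        for pos in itertools.combinations(range(l), e)
    )
    return below / math.comb(l, e)


class TestLemmaThreshold:
    @pytest.mark.parametrize(
        "l,e,k,expected", [(50, 0, 12, 39), (50, 2, 16, 3), (50, 5, 12, 0)]
    )
    def test_values(self, l, e, k, expected):
        assert lemma_threshold(l, e, k) == expected

    def test_matches_worst_case_enumeration(self):
        """The bound equals the worst case over all C(50,2) error layouts."""
        worst = min(
            surviving_kmers(50, pos, 16)
            for pos in itertools.combinations(range(50), 2)
        )
        assert lemma_threshold(50, 2, 16) == worst == 3

    def test_is_lower_bound_small_cases(self):
        for l, e, k in [(15, 2, 4), (18, 3, 5), (12, 1, 6)]:
            bound = lemma_threshold(l, e, k)
            for pos in itertools.combinations(range(l), e):
                assert surviving_kmers(l, pos, k) >= bound

    def test_rejects_word_longer_than_alignment(self):
        with pytest.raises(ValueError):
            lemma_threshold(10, 1, 11)


def test_max_lossless_word_sizes():
    """Largest word size guaranteed to find all length-50 matches: 25, 16,
    12, 10, 8 for 1-5 errors (the error-free case gives the trivial 50)."""
    assert [max_lossless_word_size(50, e) for e in range(1, 6)] == \
        [25, 16, 12, 10, 8]
    assert max_lossless_word_size(50, 0) == 50


class TestOccurrenceModel:
    def test_fly_genome_scale(self):
        e = expected_occurrences(143_000_000, 11)
        assert math.ceil(e) == 69
        assert e == pytest.approx(68.19, abs=0.01)

    def test_single_window(self):
        assert expected_occurrences(7, 7) == pytest.approx(2 / 4**7)

    def test_monotone_in_k(self):
        vals = [expected_occurrences(10_000, k) for k in range(4, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_spurious_prob_saturates(self):
        model = KmerStatsModel(143_000_000, 143_000_000,
                               effective_size_coeff=1.0)
        assert spurious_kmer_prob(model, 11) == 1.0

    def test_effective_size_correction(self):
        # E(x)=0.13 with s_e=0.65 doubles the estimate to 0.2
        L = 11 - 1 + round(0.13 * 4**11 / 2)
        model = KmerStatsModel(L, L)
        assert spurious_kmer_prob(model, 11) == pytest.approx(0.2, rel=1e-2)
        ident = KmerStatsModel(L, L, effective_size_coeff=1.0)
        assert spurious_kmer_prob(ident, 11) == pytest.approx(0.13, rel=1e-2)


class TestFnr:
    def test_zero_threshold(self):
        assert fnr(50, 5, 12, 0) == 0.0

    def test_error_free(self):
        assert fnr(30, 0, 8, 23) == 0.0   # t <= l-k+1: always enough
        assert fnr(30, 0, 8, 24) == 1.0   # t > l-k+1: never enough

    def test_equals_bruteforce_spot_checks(self):
        for l, e, k, t in [(12, 2, 4, 2), (15, 3, 5, 3), (20, 4, 6, 4),
                           (18, 2, 7, 5), (22, 4, 10, 6)]:
            assert fnr(l, e, k, t) == pytest.approx(
                fnr_bruteforce(l, e, k, t), abs=1e-12
            )

    def test_monotone_in_threshold_and_word_size(self):
        vals_t = [fnr(50, 5, 12, t) for t in range(0, 10)]
        assert all(a <= b for a, b in zip(vals_t, vals_t[1:]))
        vals_k = [fnr(50, 5, k, 5) for k in range(8, 20)]
        assert all(a <= b + 1e-12 for a, b in zip(vals_k, vals_k[1:]))


class TestFpr:
    def test_edge_cases(self):
        assert fpr(10, 0.3, 0) == 1.0
        assert fpr(10, 0.0, 1) == 0.0
        assert fpr(2, 0.5, 2) == pytest.approx(0.25)

    def test_monotone(self):
        vals = [fpr(39, 0.1, t) for t in range(0, 10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestDeduceParams:
    def test_tiny_reference_takes_lossless_path(self):
        """With a small bin no 25-mer occurs by chance: the counting lemma
        path applies for one allowed error."""
        model = KmerStatsModel(10_000, 10_000)
        params, grid = deduce_params(model, EpsilonSpec(50, 1))
        assert params.lossless
        assert params.shape.weight == 25
        assert params.threshold == lemma_threshold(50, 1, 25)
        assert np.all(grid.cost >= 0) and np.all(grid.cost <= 2)

    def test_high_error_large_reference_heuristic(self):
        """For epsilon(50,5) on a 50 Mb reference every lossless word size is
        saturated by chance matches; the cost grid decides."""
        model = KmerStatsModel(50_000_000, 50_000_000 // 64)
        params, grid = deduce_params(model, EpsilonSpec(50, 5))
        assert not params.lossless
        k, t = grid.argmin
        assert params.shape.weight == k
        assert params.threshold == t

    def test_singleton_grid(self):
        model = KmerStatsModel(50_000_000, 50_000_000 // 64)
        params, grid = deduce_params(model, EpsilonSpec(50, 5),
                                     k_range=[12], t_range=[5])
        assert (params.shape.weight, params.threshold) == (12, 5)

    def test_empty_grid_rejected(self):
        model = KmerStatsModel(1000, 1000)
        with pytest.raises(ValueError):
            deduce_params(model, EpsilonSpec(50, 1), k_range=[], t_range=[])

    def test_grid_frame(self):
        model = KmerStatsModel(1_000_000, 20_000)
        _, grid = deduce_params(model, EpsilonSpec(50, 2),
                                k_range=range(10, 13), t_range=range(1, 4))
        df = grid.to_frame()
        assert len(df) == 9
        assert set(df.columns) == {"k", "t", "fnr", "fpr", "cost"}


class TestDistinctKmerStats:
    def test_homopolymer(self):
        stats = distinct_kmer_stats("A" * 100, parse_shape("11011"))
        assert stats.distinct_count == 1

    def test_single_window(self):
        stats = distinct_kmer_stats("ACGTACG", SeedShape.ungapped(7))
        assert (stats.distinct_count, stats.max_possible) == (1, 1)
        assert stats.effective_fraction == 1.0

    def test_random_sequence_matches_birthday_model(self, dna_factory):
        """Distinct canonical k-mer counts of a uniform random 1 Mb sequence
        follow the birthday-style expectation; for a word size whose halved
        value space is much smaller than the window count the census
        saturates its bound."""
        seq = dna_factory(1_000_000)
        n_win = len(seq) - 11 + 1
        half_space = 4**11 / 2
        expected = half_space * (1 - (1 - 1 / half_space) ** n_win)
        stats11 = distinct_kmer_stats(seq, SeedShape.ungapped(11))
        assert stats11.distinct_count == pytest.approx(expected, rel=0.01)
        stats9 = distinct_kmer_stats(seq, SeedShape.ungapped(9))
        assert stats9.effective_fraction > 0.95
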