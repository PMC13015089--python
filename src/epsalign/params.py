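"""Filter parameter deduction: counting-lemma thresholds, FNR/FPR model.

The prefilter declares a reference bin a candidate for a query window when
they share at least ``t`` k-mers.  Two regimes exist:

* lossless — the k-mer counting lemma guarantees that an alignment of length
  ``l`` with ``e`` edits preserves at least ``l + 1 - k(e + 1)`` ungapped
  k-mers; whenever some word size yields a positive threshold *and* a k-mer of
  that size is unlikely to occur by chance in a bin, filtering misses nothing.
* heuristic — for high error allowances no such word size exists, and (k, t)
  are chosen by minimising Cost(k, t) = FNR(k, t) + FPR(k, t) over a grid,
  where FNR is the exact fraction of error configurations that preserve fewer
  than t k-mers (a run-composition dynamic program) and FPR is the binomial
  tail probability of t spurious k-mer matches in a query window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .shapes import (
    SeedShape,
    canonical_kmer_stream,
    symmetric_shape_for_weight,
)


@dataclass(frozen=True)
class EpsilonSpec:
    """An (l_min, e_max) match specification.

    A local alignment of length ``n`` with ``e`` edit columns qualifies iff
    ``n >= l_min`` and ``e / n <= e_max / l_min``.
    """

    l_min: int
    e_max: int

    def __post_init__(self) -> None:
        if self.l_min < 1:
            raise ValueError("l_min must be positive")
        if not 0 <= self.e_max < self.l_min:
            raise ValueError("e_max must satisfy 0 <= e_max < l_min")

    @property
    def rate(self) -> float:
        """Maximum tolerated error rate e_max / l_min."""
        return self.e_max / self.l_min


@dataclass(frozen=True)
class FilterParams:
    """Chosen k-mer shape and shared-count threshold for prefiltering."""

    shape: SeedShape
    threshold: int
    lossless: bool

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


@dataclass(frozen=True)
class KmerStatsModel:
    """Random-sequence model of the reference used for the FPR estimate.

    ``bin_length`` is the length of one reference segment (the unit over
    which shared k-mers are counted).  ``effective_size_coeff`` (s_e) corrects
    for real genomes holding fewer distinct k-mers than a random sequence of
    equal length, which makes each k-mer more frequent and hence raises the
    spurious-match probability; 1.0 leaves the random model uncorrected.
    """

    reference_length: int
    bin_length: int
    alphabet_size: int = 4
    effective_size_coeff: float = 0.65

    def __post_init__(self) -> None:
        if not 0 < self.bin_length <= self.reference_length:
            raise ValueError("need 0 < bin_length <= reference_length")
        if not 0 < self.effective_size_coeff <= 1:
            raise ValueError("effective_size_coeff must be in (0, 1]")


def lemma_threshold(l: int, e: int, k: int) -> int:
    """Counting-lemma lower bound on shared ungapped k-mers, clamped at 0.

    An alignment of length ``l`` with ``e`` edits preserves at least
    ``l - k + 1 - k*e`` error-free k-mer windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > l:
        raise ValueError(f"word size k={k} exceeds alignment length l={l}")
    if e < 0:
        raise ValueError("e must be >= 0")
    return max(0, (l - k + 1) - k * e)


def max_lossless_word_size(l: int, e: int) -> int:
    """Largest k with a positive counting-lemma threshold: floor(l / (e+1))."""
    if l < 1 or e < 0:
        raise ValueError("need l >= 1 and e >= 0")
    return max(1, l // (e + 1))


def expected_occurrences(L: int, k: int, alphabet_size: int = 4) -> float:
    """Expected count of one canonical k-mer in a random length-L sequence.

    E(x) = 2 (L - k + 1) / sigma^k: the sequence holds L - k + 1 windows and
    either of a k-mer's two orientations matches the canonical value.
    """
    if L < k:
        raise ValueError("need L >= k")
    return 2.0 * (L - k + 1) / alphabet_size**k


def spurious_kmer_prob(model: KmerStatsModel, k: int) -> float:
    """Probability that a random query k-mer matches a bin by chance.

    min(1, E(x) / s_e): dividing the expectation by the effective-size
    coefficient raises the estimate for repeat-rich references.
    """
    e = expected_occurrences(model.bin_length, k, model.alphabet_size)
    return min(1.0, e / model.effective_size_coeff)


def fnr(l: int, e: int, k: int, t: int) -> float:
    """Fraction of error configurations preserving fewer than t k-mers.

    An error configuration is a choice of ``e`` error columns among ``l``.
    An ungapped k-mer window survives iff its k columns are error-free, so the
    surviving count is the sum of max(0, run - k + 1) over the e + 1
    error-free runs.  Computed exactly by a dynamic program over
    (run index, error-free columns used, surviving-count budget); counts stay
    below 2^53 for desk-scale (l, e) so float64 arithmetic is exact.
    """
    if not 1 <= k <= l:
        raise ValueError("need 1 <= k <= l")
    if not 0 <= e <= l:
        raise ValueError("need 0 <= e <= l")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    m = l - e  # error-free columns to distribute over e + 1 runs
    cap = t    # survivor counts are capped at t ("already enough")
    # f[c, s]: number of ways to fill the runs so far using c error-free
    # columns with a (capped) survivor total of s
    f = np.zeros((m + 1, cap + 1))
    f[0, 0] = 1.0
    surv = np.array([min(cap, max(0, r - k + 1)) for r in range(m + 1)])
    for _run in range(e + 1):
        g = np.zeros_like(f)
        for r in range(m + 1):
            s_add = surv[r]
            src = f[: m + 1 - r, :]
            if s_add == 0:
                g[r:, :] += src
            else:
                dest = np.minimum(np.arange(cap + 1) + s_add, cap)
                for s in range(cap + 1):
                    g[r:, dest[s]] += src[:, s]
        f = g
    below = float(f[m, :cap].sum())
    total = float(math.comb(l, e))
    return below / total


def fpr(window_kmers: int, p: float, t: int) -> float:
    """P(X >= t) for X ~ Binomial(window_kmers, p): spurious window hit rate."""
    if window_kmers < 0 or not 0 <= p <= 1 or t < 0:
        raise ValueError("invalid fpr arguments")
    if t == 0:
        return 1.0
    if t > window_kmers:
        return 0.0
    return float(stats.binom.sf(t - 1, window_kmers, p))


@dataclass
class CostGrid:
    """FNR/FPR/Cost surfaces over (k-mer weight, threshold) for inspection."""

    weights: np.ndarray
    thresholds: np.ndarray
    fnr: np.ndarray  # (len(weights), len(thresholds))
    fpr: np.ndarray
    cost: np.ndarray

    @property
    def argmin(self) -> tuple[int, int]:
        """(k, t) of the minimal cost cell; ties toward smaller k then t."""
        i, j = np.unravel_index(np.argmin(self.cost), self.cost.shape)
        return int(self.weights[i]), int(self.thresholds[j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, k in enumerate(self.weights):
            for j, t in enumerate(self.thresholds):
                rows.append(
                    dict(k=int(k), t=int(t), fnr=self.fnr[i, j],
                         fpr=self.fpr[i, j], cost=self.cost[i, j])
                )
        return pd.DataFrame(rows)


def deduce_params(
    model: KmerStatsModel,
    spec: EpsilonSpec,
    k_range: Sequence[int] = range(7, 24),
    t_range: Sequence[int] = range(1, 26),
    gapped: bool = True,
    max_word_size: int = 32,
    ibf_fpr: float = 0.0,
) -> tuple[FilterParams, CostGrid]:
    """Pick (shape, threshold) for the IBF prefilter.

    Lossless path: take the largest lemma-positive word size whose chance of
    a spurious candidate stays below one half per segment (spurious k-mer
    matches from the sequence model plus, if given, the IBF's own per-query
    false positive rate ``ibf_fpr``); smaller word sizes in the lossless
    range are tried when the largest is too noisy, since a shorter word has
    a much higher lemma threshold.  If no lossless word size is specific
    enough, minimise Cost(k, t) = FNR + FPR over the grid; the chosen weight
    is realised as a symmetric gapped shape when ``gapped`` (pessimistic
    estimate — the grid itself models ungapped k-mers of each weight).
    """
    k_range = list(k_range)
    t_range = list(t_range)
    if not k_range or not t_range:
        raise ValueError("empty parameter grid")
    l, e = spec.l_min, spec.e_max

    # a segment-vs-bin pair is a false candidate if ANY of its query windows
    # reaches the threshold by chance; with ~bin_length/l_min effectively
    # independent window trials per segment the per-window tail must be
    # deflated accordingly, else small-k cells look deceptively cheap
    n_trials = max(1, model.bin_length // l)
    grid_fnr = np.zeros((len(k_range), len(t_range)))
    grid_fpr = np.zeros_like(grid_fnr)
    for i, k in enumerate(k_range):
        if k > l:
            grid_fnr[i, :] = 1.0
            grid_fpr[i, :] = 0.0
            continue
        p = min(1.0, spurious_kmer_prob(model, k) + ibf_fpr)
        w = l - k + 1
        for j, t in enumerate(t_range):
            grid_fnr[i, j] = fnr(l, e, k, t)
            win = fpr(w, p, t)
            grid_fpr[i, j] = 1.0 - (1.0 - win) ** n_trials
    grid = CostGrid(
        np.array(k_range), np.array(t_range),
        grid_fnr, grid_fpr, grid_fnr + grid_fpr,
    )

    k_star = min(max_lossless_word_size(l, e), max_word_size, l)
    for k in range(k_star, 3, -1):
        t_k = lemma_threshold(l, e, k)
        if t_k < 1:
            break
        p = min(1.0, spurious_kmer_prob(model, k) + ibf_fpr)
        seg_fpr = 1.0 - (1.0 - fpr(l - k + 1, p, t_k)) ** n_trials
        if seg_fpr < 0.5:
            return FilterParams(SeedShape.ungapped(k), t_k, lossless=True), grid

    k_best, t_best = grid.argmin
    shape = symmetric_shape_for_weight(k_best) if gapped else SeedShape.ungapped(k_best)
    return FilterParams(shape=shape, threshold=max(1, t_best), lossless=False), grid


@dataclass(frozen=True)
class DistinctKmerStats:
    """Distinct-k-mer census of one sequence."""

    distinct_count: int
    max_possible: int
    effective_fraction: float


def distinct_kmer_stats(seq: str | np.ndarray, shape: SeedShape) -> DistinctKmerStats:
    """Distinct canonical k-mer count C, bound C_max and ratio L_e = C / C_max.

    C_max = min(L - span + 1, sigma^weight / 2): the window count caps C, as
    does the number of canonical values (half the value space).
    """
    stream = canonical_kmer_stream(seq, shape)
    if len(stream) == 0:
        raise ValueError("sequence shorter than the shape span")
    c = int(np.unique(stream.valid_values).size)
    c_max = int(min(len(stream), 4**shape.weight // 2))
    c_max = max(1, c_max)
    return DistinctKmerStats(c, c_max, c / c_max)
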