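"""Interleaved Bloom Filter over reference-segment k-mer sets.

One Bloom filter per reference bin, with the bit layout interleaved: for each
hash position ``p`` the ``b`` bin bits occupy the contiguous slice
``[p*b, (p+1)*b)``.  A single membership lookup therefore gathers ``h``
contiguous b-bit slices and ANDs them into a bin-membership bit vector.
Queries have one-sided error: an inserted value always reports membership in
its bin (no false negatives); absent values hit a bin with probability
bounded by the target FPR chosen at construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .shapes import mix64

# fixed per-hash seeds: multiples of the 64-bit golden ratio constant
_GOLDEN = 0x9E3779B97F4A7C15


def _hash_seeds(h: int) -> np.ndarray:
    return (np.arange(1, h + 1, dtype=np.uint64) * np.uint64(_GOLDEN))


def bits_per_bin(n_max: int, target_fpr: float, hash_count: int) -> int:
    """Bloom sizing: m = ceil(-h*n / ln(1 - f^(1/h))), floor of 64 bits."""
    if n_max <= 0:
        return 64
    f = target_fpr ** (1.0 / hash_count)
    return max(64, ceil(-hash_count * n_max / log(1.0 - f)))


@dataclass
class InterleavedBloomFilter:
    bin_count: int
    bits_per_bin: int
    hash_count: int
    target_fpr: float
    bits: np.ndarray  # bool, length bits_per_bin * bin_count, interleaved

    MAGIC = "EPSIBF1"

    @classmethod
    def empty(cls, bin_count: int, bits_per_bin_: int, hash_count: int,
              target_fpr: float) -> "InterleavedBloomFilter":
        if bin_count < 1:
            raise ValueError("need at least one bin")
        if hash_count < 1:
            raise ValueError("need at least one hash function")
        if not 0 < target_fpr <= 0.5:
            raise ValueError("target_fpr must be in (0, 0.5]")
        return cls(bin_count, bits_per_bin_, hash_count, target_fpr,
                   np.zeros(bits_per_bin_ * bin_count, dtype=bool))

    def _positions(self, values: np.ndarray) -> np.ndarray:
        """(h, n) array of hash positions in [0, bits_per_bin)."""
        v = np.asarray(values, dtype=np.uint64).reshape(-1)
        seeds = _hash_seeds(self.hash_count)
        pos = mix64(v[None, :] ^ seeds[:, None]) % np.uint64(self.bits_per_bin)
        return pos.astype(np.int64)

    def insert(self, bin_id: int, values: np.ndarray) -> None:
        if not 0 <= bin_id < self.bin_count:
            raise IndexError(f"bin {bin_id} out of range")
        values = np.asarray(values, dtype=np.uint64)
        if values.size == 0:
            return
        pos = self._positions(values)
        self.bits[pos * self.bin_count + bin_id] = True

    def query_membership(self, value: int) -> np.ndarray:
        """Bin bit vector for one value: bit i set iff all h positions set."""
        return self.bulk_contains(np.array([value], dtype=np.uint64))[0]

    def bulk_contains(self, values: np.ndarray) -> np.ndarray:
        """(n, b) bool membership matrix for an array of values."""
        values = np.asarray(values, dtype=np.uint64)
        if values.size == 0:
            return np.empty((0, self.bin_count), dtype=bool)
        pos = self._positions(values)  # (h, n)
        b = self.bin_count
        # each hash position selects a contiguous b-bit slice of the store
        base = pos[:, :, None] * b + np.arange(b)[None, None, :]
        return self.bits[base].all(axis=0)

    def count_in_window(self, values: np.ndarray,
                        valid: np.ndarray | None = None) -> np.ndarray:
        """Per-bin count of window values reporting membership."""
        values = np.asarray(values, dtype=np.uint64)
        if valid is not None:
            values = values[np.asarray(valid, dtype=bool)]
        if values.size == 0:
            return np.zeros(self.bin_count, dtype=np.int64)
        return self.bulk_contains(values).sum(axis=0, dtype=np.int64)

    def sliding_window_counts(self, values: np.ndarray, valid: np.ndarray,
                              window: int) -> np.ndarray:
        """Per-bin shared-k-mer counts for every window of ``window`` k-mer slots.

        Exact sliding window (stride 1) via cumulative sums; invalid k-mers
        contribute nothing.  Returns an (n_windows, bin_count) int matrix.
        """
        n = len(values)
        if n == 0 or window < 1:
            return np.zeros((0, self.bin_count), dtype=np.int64)
        member = self.bulk_contains(values)
        member[~np.asarray(valid, dtype=bool)] = False
        window = min(window, n)
        cs = np.zeros((n + 1, self.bin_count), dtype=np.int64)
        np.cumsum(member, axis=0, out=cs[1:])
        return cs[window:] - cs[: n - window + 1]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            magic=np.array(self.MAGIC),
            bin_count=self.bin_count,
            bits_per_bin=self.bits_per_bin,
            hash_count=self.hash_count,
            target_fpr=self.target_fpr,
            bits=np.packbits(self.bits),
        )

    @classmethod
    def load(cls, path: str | Path) -> "InterleavedBloomFilter":
        with np.load(path, allow_pickle=False) as z:
            if str(z["magic"]) != cls.MAGIC:
                raise ValueError(f"{path}: not an {cls.MAGIC} index")
            b = int(z["bin_count"])
            m = int(z["bits_per_bin"])
            bits = np.unpackbits(z["bits"])[: m * b].astype(bool)
            return cls(b, m, int(z["hash_count"]), float(z["target_fpr"]), bits)


def build_ibf(
    bin_kmer_sets: Sequence[np.ndarray] | Sequence[Iterable[int]],
    target_fpr: float = 0.05,
    hash_count: int = 2,
) -> InterleavedBloomFilter:
    """Build an IBF sized for the largest per-bin k-mer set.

    The bit count per bin is chosen so that after inserting ``n_max`` distinct
    values the per-query false positive rate stays at or below ``target_fpr``.
    """
    if not 0 < target_fpr <= 0.5:
        raise ValueError("target_fpr must be in (0, 0.5]")
    sets = [np.unique(np.asarray(list(s) if not isinstance(s, np.ndarray) else s,
                                 dtype=np.uint64)) for s in bin_kmer_sets]
    if not sets:
        raise ValueError("need at least one bin")
    n_max = max((len(s) for s in sets), default=0)
    m = bits_per_bin(n_max, target_fpr, hash_count)
    ibf = InterleavedBloomFilter.empty(len(sets), m, hash_count, target_fpr)
    for i, s in enumerate(sets):
        ibf.insert(i, s)
    return ibf
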