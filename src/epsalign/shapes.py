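"""Seed shapes and canonical gapped k-mer extraction.

A seed shape is a pattern of care (1) and do-not-care (0) positions over a
window of DNA.  Only the care positions contribute to the k-mer value, so a
gapped shape of weight ``w`` and span ``s > w`` tolerates edits falling into
its gap columns.  The default shape ``111010101101010111`` is a symmetric
weight-12 variant of the classic PatternHunter seed: because it equals its own
reversal, the gap columns coincide on both strands and adjacent *canonical*
k-mers share only 5 care positions in the worst case over strand orientation.

K-mer values are canonical: each window is 2-bit packed along the care
positions, the same is done for the reverse-complemented window under the
reversed shape, the smaller of the two integers is kept, and a fixed 64-bit
avalanche mixer (the splitmix64 finalizer) is applied.  This makes the value
of a window and of its reverse complement identical, so all downstream
filtering is strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

DEFAULT_SHAPE = "111010101101010111"

# 2-bit DNA encoding; anything that is not ACGT (upper or lower case) maps to
# the sentinel 255 and poisons every window that covers it.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
               "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; invalid codes stay invalid."""
    out = codes[::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def mix64(x: np.ndarray | int) -> np.ndarray | int:
    """Fixed 64-bit avalanche mixer (splitmix64 finalizer), vectorised."""
    z = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z


class ShapeError(ValueError):
    """Raised for malformed seed-shape strings."""


@dataclass(frozen=True)
class SeedShape:
    """A gapped seed: care(1)/do-not-care(0) flags over a window.

    Invariants: the first and last flags are care positions (a shape with a
    do-not-care border is just a shorter shape), ``weight`` counts the care
    positions and ``span`` is the window length.
    """

    pattern: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ShapeError("empty seed shape")
        if any(p not in (0, 1) for p in self.pattern):
            raise ShapeError("seed shape flags must be 0 or 1")
        if self.pattern[0] != 1 or self.pattern[-1] != 1:
            raise ShapeError(
                "seed shape must start and end with a care position (1); "
                "a shape with a 0 border is a shorter shape"
            )
        if self.weight > 32:
            raise ShapeError("seed weight above 32 does not fit 2-bit packing")

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return sum(self.pattern)

    @property
    def care_positions(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pattern))

    @property
    def is_gapped(self) -> bool:
        return self.span != self.weight

    def __str__(self) -> str:
        return "".join(str(p) for p in self.pattern)

    def reversed(self) -> "SeedShape":
        return SeedShape(self.pattern[::-1])

    @classmethod
    def ungapped(cls, k: int) -> "SeedShape":
        if k < 1:
            raise ShapeError("ungapped seed length must be >= 1")
        return cls((1,) * k)


def parse_shape(text: str) -> SeedShape:
    """Parse a 1/0 string such as ``"111010101101010111"`` into a SeedShape."""
    if not text:
        raise ShapeError("empty seed shape")
    if set(text) - {"0", "1"}:
        raise ShapeError(f"invalid characters in seed shape {text!r}")
    return SeedShape(tuple(int(c) for c in text))


def is_symmetric(shape: SeedShape) -> bool:
    """True iff the pattern equals its reversal (gaps coincide on both strands)."""
    return shape.pattern == shape.pattern[::-1]


def adjacent_shared_positions(shape: SeedShape, mode: str = "canonical_worst_case") -> int:
    """Number of care positions shared by adjacent k-mers (bitwise AND).

    ``same_strand``: AND of the pattern at window offsets 0 and +1.
    ``canonical_worst_case``: maximum over {pattern, reversed pattern} at
    offset 0 ANDed with the pattern at offset +1 — the worst case when the
    canonical orientation of the first k-mer is unknown.
    """
    p = np.asarray(shape.pattern)
    s = shape.span

    def overlap(a: np.ndarray, b: np.ndarray) -> int:
        if s < 2:
            return 0
        # a occupies columns [0, s), b occupies [1, s+1); overlap is s-1 wide
        return int(np.sum(a[1:] & b[: s - 1]))

    if mode == "same_strand":
        return overlap(p, p)
    if mode == "canonical_worst_case":
        r = p[::-1]
        return max(overlap(p, p), overlap(r, p), overlap(p, r), overlap(r, r))
    raise ValueError(f"unknown mode {mode!r}")


def symmetric_shape_for_weight(weight: int, base: str = DEFAULT_SHAPE) -> SeedShape:
    """A symmetric gapped shape of the requested weight.

    Grows the default weight-12 shape by appending care positions at both ends
    (pairs keep the palindrome; an odd leftover goes into the exact centre).
    Weights below the base weight fall back to an ungapped seed.
    """
    shape = parse_shape(base)
    if weight <= shape.weight:
        return SeedShape.ungapped(weight)
    extra = weight - shape.weight
    pat = list(shape.pattern)
    if extra % 2:
        pat.insert(len(pat) // 2, 1)
        extra -= 1
    pat = [1] * (extra // 2) + pat + [1] * (extra // 2)
    return SeedShape(tuple(pat))


class KmerRecord(NamedTuple):
    """One k-mer window: start offset, canonical hashed value, validity flag."""

    position: int
    value: int
    valid: bool


@dataclass
class KmerStream:
    """Vectorised canonical k-mer stream: one record per window of a sequence."""

    values: np.ndarray  # uint64, length max(0, L - span + 1)
    valid: np.ndarray   # bool, same length

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[KmerRecord]:
        for i in range(len(self.values)):
            yield KmerRecord(i, int(self.values[i]), bool(self.valid[i]))

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def canonical_kmer_stream(seq: str | np.ndarray, shape: SeedShape) -> KmerStream:
    """Canonical gapped k-mer values for every window of ``seq``.

    Windows covering any non-ACGT residue are flagged invalid; their values
    are arbitrary and must not be counted or inserted downstream.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    L = len(codes)
    span, weight = shape.span, shape.weight
    n = L - span + 1
    if n <= 0:
        return KmerStream(np.empty(0, np.uint64), np.empty(0, bool))

    bad = (codes >= 4)
    safe = np.where(bad, 0, codes).astype(np.uint64)

    care = shape.care_positions
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j, p in enumerate(care):
        sh = np.uint64(2 * (weight - 1 - j))
        fwd |= safe[p : p + n] << sh
        # reverse-complemented window under the reversed shape: the j-th care
        # position reads residue span-1-p of the window, complemented
        rc |= (np.uint64(3) - safe[span - 1 - p : span - 1 - p + n]) << sh

    canonical = np.minimum(fwd, rc)
    values = mix64(canonical)

    # a window [i, i+span) is valid iff it covers no invalid residue
    cs = np.concatenate(([0], np.cumsum(bad.astype(np.int64))))
    valid = (cs[span:] - cs[:-span]) == 0
    return KmerStream(values, valid)


def ungapped_qgram_values(codes: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain (non-canonical) 2-bit packed q-gram values and validity flags.

    Used by the exact SWIFT-level q-gram index, which is strand-specific.
    """
    L = len(codes)
    n = L - q + 1
    if n <= 0 or q < 1 or q > 32:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = (codes >= 4)
    safe = np.where(bad, 0, codes).astype(np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(q):
        vals |= safe[j : j + n] << np.uint64(2 * (q - 1 - j))
    cs = np.concatenate(([0], np.cumsum(bad.astype(np.int64))))
    valid = (cs[q:] - cs[:-q]) == 0
    return vals, valid
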