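"""Seeded benchmark generator with implanted local alignments, plus scoring.

The generator emulates a random-sequence benchmark: two i.i.d. uniform DNA
sequences of length L; every ~``density`` bp one substring of A (length drawn
uniformly from ``length_range``, default 50-250 bp) is copied, mutated with
exactly ``floor(error_rate * length)`` edits (substitutions, insertions and
deletions equiprobable, positions uniform), and written over a random
non-overlapping position of B.  The truth table records both intervals, so a
search between A (reference) and B (queries) can be scored: a truth record
counts as found iff some reported match overlaps its implant interval in B
by at least ``min_overlap`` bp (default 10).

What this emulates — and does not: uniformly placed edits are the worst case
for seed filters (real edits cluster, preserving more shared k-mers), while
uniform random background contains none of the repeat structure of real
genomes; repeat handling is exercised separately via the repetitiveness
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthRecord:
    """One implanted alignment: source interval in A, implant interval in B."""

    source_start: int
    source_end: int
    implant_start: int
    implant_end: int
    length: int   # planned (pre-mutation) length
    errors: int   # planned edit count

    def __post_init__(self) -> None:
        if self.errors > self.length:
            raise ValueError("more planned errors than columns")


def random_dna(L: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=L)].tobytes().decode("ascii")


def mutate(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply ``n_edits`` uniform edits: equiprobable sub/ins/del.

    Substitutions and deletions hit distinct source columns; insertion
    positions are uniform over the columns of the growing mutated string.
    """
    if n_edits == 0:
        return seq
    ops = rng.integers(0, 3, size=n_edits)  # 0 sub, 1 ins, 2 del
    n_sub = int(np.sum(ops == 0))
    n_ins = int(np.sum(ops == 1))
    n_del = n_edits - n_sub - n_ins
    n_cols = n_sub + n_del
    if n_cols > len(seq):
        n_del = max(0, len(seq) - n_sub)
        n_cols = n_sub + n_del
    cols = rng.choice(len(seq), size=n_cols, replace=False) if n_cols else np.array([], int)
    sub_cols = set(int(c) for c in cols[:n_sub])
    del_cols = set(int(c) for c in cols[n_sub:])
    out = []
    for i, c in enumerate(seq):
        if i in del_cols:
            continue
        if i in sub_cols:
            alternatives = [b for b in "ACGT" if b != c]
            out.append(alternatives[rng.integers(0, 3)])
        else:
            out.append(c)
    for _ in range(n_ins):
        pos = int(rng.integers(0, len(out) + 1))
        out.insert(pos, "ACGT"[rng.integers(0, 4)])
    return "".join(out)


def simulate_pair(
    L: int,
    error_rate: float,
    density: int = 2000,
    length_range: tuple[int, int] = (50, 250),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, list[TruthRecord]]:
    """Simulate a (reference, query) pair with implanted local alignments.

    ``floor(L / density)`` substrings of A are mutated at ``error_rate`` and
    written over non-overlapping positions of B.  Fully reproducible from
    ``seed``.  Raises if the implants cannot be packed without overlap.
    """
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError("bad length_range")
    if density <= hi:
        raise ValueError("density must exceed the maximum implant length")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    a = random_dna(L, rng)
    b_arr = np.frombuffer(random_dna(L, rng).encode("ascii"), dtype=np.uint8).copy()

    count = L // density
    taken: list[tuple[int, int]] = []
    truth: list[TruthRecord] = []
    for _ in range(count):
        length = int(rng.integers(lo, hi + 1))
        src = int(rng.integers(0, L - length + 1))
        fragment = mutate(a[src : src + length], int(error_rate * length), rng)
        placed = False
        for _attempt in range(1000):
            pos = int(rng.integers(0, L - len(fragment) + 1))
            end = pos + len(fragment)
            if all(end <= s or pos >= e for s, e in taken):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not pack {count} implants into {L} bp without overlap; "
                "increase density or sequence length"
            )
        taken.append((pos, end))
        b_arr[pos:end] = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)
        truth.append(
            TruthRecord(src, src + length, pos, end, length,
                        int(error_rate * length))
        )
    truth.sort(key=lambda t: t.implant_start)
    return a, b_arr.tobytes().decode("ascii"), truth


# -- truth table I/O ---------------------------------------------------------

_TRUTH_COLS = ["source_start", "source_end", "implant_start", "implant_end",
               "length", "errors"]


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth], columns=_TRUTH_COLS)


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TruthRecord(**{c: int(row[c]) for c in _TRUTH_COLS})
            for _, row in df.iterrows()]


# -- evaluation --------------------------------------------------------------


@dataclass
class EvaluationResult:
    missed_fraction: float
    table: pd.DataFrame  # one row per truth record with found flag + overlap

    @property
    def missed_percent(self) -> float:
        return 100.0 * self.missed_fraction


def evaluate(
    found_intervals: Sequence[tuple[int, int]],
    truth: Sequence[TruthRecord],
    min_overlap: int = 10,
) -> EvaluationResult:
    """Score reported query-side intervals against the implant truth.

    A truth record is found iff some reported interval overlaps its implant
    interval by at least ``min_overlap`` bp (strict >=).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rows = []
    n_missed = 0
    ivals = list(found_intervals)
    for t in truth:
        best = 0
        for s, e in ivals:
            best = max(best, min(e, t.implant_end) - max(s, t.implant_start))
        found = best >= min_overlap
        n_missed += not found
        rows.append(
            dict(implant_start=t.implant_start, implant_end=t.implant_end,
                 length=t.length, errors=t.errors,
                 best_overlap=max(0, best), found=found)
        )
    table = pd.DataFrame(rows)
    frac = n_missed / len(truth) if truth else 0.0
    return EvaluationResult(frac, table)
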