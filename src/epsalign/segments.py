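"""Splitting sequence sets into overlapping segments and per-segment stats.

Long references and queries are cut into approximately equal segments that
overlap by a configurable margin so that no local match is lost at a border:
with overlap ``2*l_min`` (the default used by the pipeline) any match up to
twice the minimum length falls whole into some segment, and longer matches
leave fragments of at least ``l_min`` in each piece for consolidation to
re-merge.

Per-segment repetitiveness is the fraction of duplicated k-mers: a segment of
length L_i with C_i distinct k-mers has variability V_i = C_i / (L_i - k + 1)
and repetitiveness R_i = 1 - V_i, used to deprioritise repeat-rich bins for
abundant queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np

from .shapes import SeedShape, canonical_kmer_stream


@dataclass(frozen=True)
class Segment:
    sequence_id: str
    segment_index: int  # global index across the whole set (bin id for refs)
    start: int          # 0-based half-open on the parent sequence
    end: int
    role: str = "reference"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def split(
    parents: Sequence[tuple[str, int]],
    target_segments: int,
    overlap: int,
    role: str = "reference",
) -> list[Segment]:
    """Cut each parent into overlapping segments of approximately equal length.

    The per-parent segment count is allocated proportionally to length (at
    least one each); a parent of length L cut into n pieces gets segments of
    length ceil((L + (n-1)*overlap) / n), consecutive starts spaced by
    length - overlap.  Parents not longer than the overlap stay whole.
    """
    if target_segments < 1:
        raise ValueError("target_segments must be >= 1")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    total = sum(length for _, length in parents)
    out: list[Segment] = []
    idx = 0
    for pid, L in parents:
        if L <= 0:
            continue
        n = max(1, round(target_segments * L / total)) if total else 1
        if L <= overlap:
            n = 1
        seg_len = ceil((L + (n - 1) * overlap) / n)
        stride = seg_len - overlap
        if stride < 1:
            n, seg_len, stride = 1, L, L
        for i in range(n):
            start = i * stride
            end = min(start + seg_len, L)
            if start >= L:
                break
            out.append(Segment(pid, idx, start, end, role))
            idx += 1
            if end == L:
                break
    return out


@dataclass(frozen=True)
class SegmentStats:
    """Distinct-k-mer census of one segment."""

    distinct_count: int
    window_count: int
    variability: float    # V_i = C_i / (L_i - k + 1)
    repetitiveness: float  # R_i = 1 - V_i
    defined: bool = True

    @classmethod
    def undefined(cls) -> "SegmentStats":
        return cls(0, 0, float("nan"), float("nan"), defined=False)


def segment_stats(seq: str | np.ndarray, shape: SeedShape) -> SegmentStats:
    """V_i and R_i for one segment's residues; undefined below the shape span."""
    stream = canonical_kmer_stream(seq, shape)
    if len(stream) == 0:
        return SegmentStats.undefined()
    c = int(np.unique(stream.valid_values).size)
    c = max(c, 1)  # an all-N segment still holds one degenerate k-mer class
    v = c / len(stream)
    return SegmentStats(c, len(stream), v, 1.0 - v)


def to_bed(segments: Sequence[Segment]) -> str:
    """BED (0-based half-open) rendering of a segment table."""
    lines = [
        f"{s.sequence_id}\t{s.start}\t{s.end}\tsegment_{s.segment_index}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
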