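"""SWIFT-style q-gram filter: diagonal parallelogram counting.

Second, lossless prefilter level.  The query segments of one cart are indexed
by exact (ungapped) q-grams; the reference bin is scanned and every shared
q-gram votes on its alignment-matrix diagonal d = ref_pos - query_pos.  An
epsilon-match confines its q-gram hits to a narrow diagonal band (each indel
shifts the diagonal by one) and a short query extent, so counting votes in
overlapping parallelograms — a diagonal bucket crossed with an l_min-long
query window — and applying the counting-lemma threshold yields candidate
regions guaranteed to intersect every true match.  Qualifying parallelograms
that overlap are merged before emission.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log2
from typing import Mapping

import numpy as np

from .params import EpsilonSpec, lemma_threshold, max_lossless_word_size
from .shapes import ungapped_qgram_values


def default_q(spec: EpsilonSpec, cap: int = 32, floor: int = 4,
              segment_length: int | None = None) -> int:
    """Default SWIFT word size, clamped to [floor, cap].

    Every q up to the largest lossless word size keeps the filter lossless
    (its counting-lemma threshold is >= 1), but they differ in specificity:
    a shorter q has a much higher lemma threshold, which can beat a longer q
    whose threshold has degenerated to one.  Given the segment length, pick
    the q minimising the estimated chance of a random window reaching the
    threshold; without it, fall back to the largest lossless q.
    """
    from .params import fpr  # local import: params does not depend on swift

    q_max = max(floor, min(max_lossless_word_size(spec.l_min, spec.e_max), cap))
    if segment_length is None:
        return q_max
    l = spec.l_min
    n_trials = max(1, segment_length // l)
    best_q, best_cost = q_max, float("inf")
    for q in range(q_max, floor - 1, -1):
        tau = lemma_threshold(l, spec.e_max, q)
        if tau < 1:
            continue
        p = min(1.0, (segment_length - q + 1) / 4**q)
        cost = 1.0 - (1.0 - fpr(l - q + 1, p, tau)) ** n_trials
        if cost < 0.5:
            return q  # largest q specific enough: fewest hit pairs to count
        if cost < best_cost:
            best_q, best_cost = q, cost
    return best_q


@dataclass(frozen=True)
class CandidateRegion:
    """A diagonal parallelogram surviving the SWIFT count threshold.

    Coordinates are segment-local: query interval [qs, qe) on the query
    segment, diagonal band [dmin, dmax] with d = ref_pos - query_pos on the
    scanned reference frame (forward or reverse-complemented for strand -).
    """

    query_id: object
    qs: int
    qe: int
    dmin: int
    dmax: int
    strand: str = "+"


class QGramIndex:
    """Exact positional q-gram index over a batch of query segments."""

    def __init__(self, segments: Mapping[object, np.ndarray], q: int):
        if q < 4:
            raise ValueError("q-gram size must be >= 4")
        self.q = q
        self.keys = list(segments.keys())
        vals_all, segs_all, pos_all = [], [], []
        for si, key in enumerate(self.keys):
            codes = segments[key]
            vals, valid = ungapped_qgram_values(codes, q)
            keep = np.flatnonzero(valid)
            vals_all.append(vals[keep])
            segs_all.append(np.full(len(keep), si, dtype=np.int32))
            pos_all.append(keep.astype(np.int64))
        if vals_all:
            values = np.concatenate(vals_all)
            segs = np.concatenate(segs_all)
            pos = np.concatenate(pos_all)
        else:
            values = np.empty(0, np.uint64)
            segs = np.empty(0, np.int32)
            pos = np.empty(0, np.int64)
        order = np.argsort(values, kind="stable")
        self.values = values[order]
        self.seg_of = segs[order]
        self.pos_of = pos[order]

    def __len__(self) -> int:
        return len(self.values)

    def lookup(self, value: int) -> list[tuple[object, int]]:
        """All (segment key, position) occurrences of one q-gram value."""
        lo = np.searchsorted(self.values, np.uint64(value), side="left")
        hi = np.searchsorted(self.values, np.uint64(value), side="right")
        return [
            (self.keys[self.seg_of[i]], int(self.pos_of[i])) for i in range(lo, hi)
        ]


def build_qgram_index(segments: Mapping[object, np.ndarray], q: int) -> QGramIndex:
    return QGramIndex(segments, q)


def _match_pairs(ref_codes: np.ndarray, index: QGramIndex):
    """Vectorised join of reference q-grams against the index.

    Returns (segment row, query position, reference position) arrays.
    """
    rvals, rvalid = ungapped_qgram_values(ref_codes, index.q)
    keep = np.flatnonzero(rvalid)
    rvals = rvals[keep]
    if rvals.size == 0 or len(index) == 0:
        z = np.empty(0, np.int64)
        return z.astype(np.int32), z, z
    lo = np.searchsorted(index.values, rvals, side="left")
    hi = np.searchsorted(index.values, rvals, side="right")
    counts = hi - lo
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        z = np.empty(0, np.int64)
        return z.astype(np.int32), z, z
    reps = counts[nz]
    total = int(reps.sum())
    # flat indices into the sorted index arrays for every occurrence
    offs = np.repeat(np.cumsum(reps) - reps, reps)
    flat = np.repeat(lo[nz], reps) + (np.arange(total) - offs)
    segs = index.seg_of[flat]
    qpos = index.pos_of[flat]
    rpos = np.repeat(keep[nz], reps)
    return segs, qpos, rpos


def swift_scan(
    ref_codes: np.ndarray,
    index: QGramIndex,
    spec: EpsilonSpec,
    threshold: int | None = None,
    strand: str = "+",
    query_pad: int | None = None,
    diag_pad: int | None = None,
) -> list[CandidateRegion]:
    """Scan one reference bin against the cart's q-gram index.

    Hits are bucketed by diagonal (bucket width a power of two at least
    e_max + 1; each hit also votes in the bucket covering diagonals up to
    e_max below it, so every (e_max+1)-wide diagonal window is fully counted
    somewhere).  Within a bucket, every query window of l_min residues with at
    least ``threshold`` hits qualifies; overlapping qualifying windows are
    merged, and regions that overlap in both query and diagonal space are
    unioned across buckets.
    """
    q = index.q
    l_min, e_band = spec.l_min, spec.e_max
    if threshold is None:
        threshold = max(1, lemma_threshold(l_min, e_band, q))
    if query_pad is None:
        # a full l_min so that the lemma-qualifying window around any hit
        # cluster lies wholly inside the region: the aligner then always sees
        # an above-threshold piece and its adaptive widening can take over
        query_pad = l_min
    if diag_pad is None:
        diag_pad = e_band + 2

    segs, qpos, rpos = _match_pairs(ref_codes, index)
    if segs.size == 0:
        return []
    diag = rpos - qpos
    z = max(1, ceil(log2(e_band + 1))) if e_band > 0 else 1
    b0 = diag >> z
    b1 = (diag + e_band) >> z

    # duplicate each hit into its second bucket where distinct, then sort all
    # hits once by (segment, bucket, query position) and walk the slices
    dup = b0 != b1
    seg_all = np.concatenate([segs, segs[dup]])
    bkt_all = np.concatenate([b0, b1[dup]])
    q_all = np.concatenate([qpos, qpos[dup]])
    d_all = np.concatenate([diag, diag[dup]])
    order = np.lexsort((q_all, bkt_all, seg_all))
    seg_all, bkt_all = seg_all[order], bkt_all[order]
    q_all, d_all = q_all[order], d_all[order]
    starts = np.flatnonzero(
        np.concatenate(
            ([True], (seg_all[1:] != seg_all[:-1]) | (bkt_all[1:] != bkt_all[:-1]))
        )
    )
    bounds_idx = np.append(starts, len(seg_all))

    regions: list[CandidateRegion] = []
    span_hits = l_min - q  # max start-position extent of hits in one window
    per_seg_raw: dict[int, list[tuple[int, int, int, int]]] = {}
    for s0, s1 in zip(bounds_idx[:-1], bounds_idx[1:]):
        if s1 - s0 < threshold:
            continue
        qb = q_all[s0:s1]
        db = d_all[s0:s1]
        n = len(qb)
        # two-pointer: window starting at hit i covers hits with
        # qpos <= qb[i] + span_hits
        hi_idx = np.searchsorted(qb, qb + span_hits, side="right")
        qualify = np.flatnonzero(hi_idx - np.arange(n) >= threshold)
        if qualify.size == 0:
            continue
        raw = per_seg_raw.setdefault(int(seg_all[s0]), [])

        def bounds(a: int, b: int) -> tuple[int, int, int, int]:
            return (int(qb[a]), int(qb[b - 1]) + q,
                    int(db[a:b].min()), int(db[a:b].max()))

        # group qualifying windows whose hit ranges touch
        start = int(qualify[0])
        end = int(hi_idx[qualify[0]])
        for i in qualify[1:]:
            if i <= end:  # overlapping/abutting hit ranges
                end = max(end, int(hi_idx[i]))
            else:
                raw.append(bounds(start, end))
                start, end = int(i), int(hi_idx[i])
        raw.append(bounds(start, end))

    for si, raw in per_seg_raw.items():
        for qs, qe, dmin, dmax in _merge_regions(raw, e_band):
            regions.append(
                CandidateRegion(
                    query_id=index.keys[si],
                    qs=max(0, qs - query_pad),
                    qe=qe + query_pad,
                    dmin=dmin - diag_pad,
                    dmax=dmax + diag_pad,
                    strand=strand,
                )
            )
    return regions


def _merge_regions(raw: list[tuple[int, int, int, int]], e_band: int):
    """Union regions that overlap in query extent and diagonal extent."""
    if not raw:
        return []
    tol = e_band + 1
    items = sorted(raw)
    merged: list[list[int]] = []
    changed = True
    current = [list(r) for r in items]
    while changed:
        changed = False
        current.sort()
        merged = []
        for r in current:
            hit = False
            for m in merged:
                if r[0] <= m[1] and m[0] <= r[1] and r[2] <= m[3] + tol and m[2] <= r[3] + tol:
                    m[0] = min(m[0], r[0])
                    m[1] = max(m[1], r[1])
                    m[2] = min(m[2], r[2])
                    m[3] = max(m[3], r[3])
                    hit = True
                    changed = True
                    break
            if not hit:
                merged.append(list(r))
        current = merged
    return [tuple(m) for m in merged]
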