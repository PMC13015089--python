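"""Producer/consumer orchestration of the two-level prefilter and aligner.

Workflow: the reference is split into overlapping segments (one IBF bin
each); query segments are prefiltered against the IBF — a bin is a candidate
for a query segment iff some l_min-residue window of the segment shares at
least ``t`` k-mers with the bin.  Abundant queries hitting more than half of
all bins are restricted to the most variable (least repetitive) half.
Candidate (query segment, bin) pairs are batched into per-bin carts; full
carts enter a FIFO queue and are consumed — each consumer job builds an
exact q-gram index over the cart's query segments, runs the SWIFT diagonal
filter against the bin (both strands) and aligns the surviving candidate
regions.  Finally all matches are consolidated.

The concurrency contract is exactly-once processing of every candidate pair,
FIFO cart dispatch and results independent of worker count, cart capacity
and queue bound; the scheduler here is deterministic and sequential, which
satisfies the contract (a ``workers`` knob is accepted and logged for
interface compatibility and does not change results).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np

from .align import (
    AlignConfig,
    EvalueModel,
    LocalMatch,
    align_region,
    consolidate,
    evalue,
    is_epsilon_match,
)
from .ibf import InterleavedBloomFilter, build_ibf
from .params import (
    EpsilonSpec,
    FilterParams,
    KmerStatsModel,
    deduce_params,
    lemma_threshold,
)
from .segments import Segment, SegmentStats, segment_stats, split
from .shapes import SeedShape, canonical_kmer_stream, encode, revcomp_codes
from .swift import QGramIndex, default_q, swift_scan

logger = logging.getLogger("epsalign")


@dataclass
class SearchConfig:
    """Resolved configuration of one search run (all values logged)."""

    min_length: int = 50
    errors: int = 5
    shape: SeedShape | None = None        # None: deduce programmatically
    threshold: int | None = None          # None: deduce with the shape
    bins: int = 64
    fpr: float = 0.0005
    hash_count: int = 2
    overlap: int | None = None            # None: 2 * min_length
    cart_capacity: int = 8
    max_full_carts: int = 32
    workers: int = 1
    chunk_size: int = 1_000_000
    repeat_fraction: float = 0.5
    seed: int = 0
    align: AlignConfig = field(default_factory=AlignConfig)
    annotate_evalues: bool = True

    @property
    def spec(self) -> EpsilonSpec:
        return EpsilonSpec(self.min_length, self.errors)

    @property
    def effective_overlap(self) -> int:
        return 2 * self.min_length if self.overlap is None else self.overlap


@dataclass
class ReferenceIndex:
    """IBF plus segment table and per-bin repetitiveness statistics."""

    ibf: InterleavedBloomFilter
    segments: list[Segment]
    stats: list[SegmentStats]
    shape: SeedShape
    overlap: int

    @property
    def bin_count(self) -> int:
        return len(self.segments)


def resolve_params(
    ref_length: int, config: SearchConfig, bin_length: int | None = None
) -> FilterParams:
    """Deduce (shape, threshold) unless the user pinned them."""
    spec = config.spec
    if config.shape is not None:
        t = config.threshold
        if t is None:
            k = config.shape.weight
            t = max(1, lemma_threshold(spec.l_min, spec.e_max, k)) \
                if k <= spec.l_min else 1
        return FilterParams(config.shape, t, lossless=False)
    if bin_length is None:
        bin_length = max(1, ceil(ref_length / config.bins) + config.effective_overlap)
    model = KmerStatsModel(max(ref_length, bin_length), bin_length)
    params, _grid = deduce_params(model, spec, ibf_fpr=config.fpr)
    if config.threshold is not None:
        params = FilterParams(params.shape, config.threshold, lossless=False)
    return params


def build_index(
    ref_records: Sequence[tuple[str, str]],
    config: SearchConfig,
    shape: SeedShape,
) -> ReferenceIndex:
    """Segment the reference, census each bin and build the IBF."""
    parents = [(rid, len(seq)) for rid, seq in ref_records]
    segs = split(parents, config.bins, config.effective_overlap, role="reference")
    seqs = dict(ref_records)
    bin_sets = []
    stats = []
    for seg in segs:
        codes = encode(seqs[seg.sequence_id][seg.start : seg.end])
        stream = canonical_kmer_stream(codes, shape)
        bin_sets.append(np.unique(stream.valid_values))
        stats.append(segment_stats(codes, shape))
    ibf = build_ibf(bin_sets, target_fpr=config.fpr, hash_count=config.hash_count)
    logger.info(
        "index: %d bins, %d bits/bin, h=%d, shape=%s",
        ibf.bin_count, ibf.bits_per_bin, ibf.hash_count, shape,
    )
    return ReferenceIndex(ibf, segs, stats, shape, config.effective_overlap)


def prefilter_query_segment(
    ibf: InterleavedBloomFilter,
    seg_codes: np.ndarray,
    params: FilterParams,
    spec: EpsilonSpec,
) -> dict[int, int]:
    """Candidate bins reaching the shared-k-mer threshold in some window.

    Counts shared k-mers in every l_min-residue window of the segment (exact
    sliding window, stride 1) and returns a mapping of candidate bin id to
    the maximum window count — the evidence strength, used downstream to
    break repetitiveness ties.  The key set is a superset of the bins
    containing true epsilon-matches whenever the parameters are lossless and
    the IBF adds no false positives.
    """
    stream = canonical_kmer_stream(seg_codes, params.shape)
    if len(stream) == 0:
        return {}
    window = max(1, spec.l_min - params.shape.span + 1)
    counts = ibf.sliding_window_counts(stream.values, stream.valid, window)
    if counts.size == 0:
        return {}
    peak = counts.max(axis=0)
    return {
        int(b): int(peak[b])
        for b in np.flatnonzero(peak >= params.threshold)
    }


def repeat_filter(
    candidates: set[int] | dict[int, int],
    stats: Sequence[SegmentStats],
    bin_count: int,
    fraction: float = 0.5,
) -> set[int]:
    """Favor variable bins for abundant queries.

    If a query hits more than ``fraction`` of all bins, keep only the
    ceil(fraction * bin_count) candidates with the smallest repetitiveness;
    queries matching few bins are searched in all of them.  When
    ``candidates`` carries per-bin evidence counts (a mapping), ties in
    repetitiveness are broken toward the stronger evidence, so bins with
    genuine shared-k-mer signal survive the cut ahead of chance hits.
    Repetitiveness is compared at a 0.05 granularity: genuine repeat
    structure moves R_i by far more than that, while sub-percent differences
    between non-repetitive bins are sampling noise that should not outrank
    the k-mer evidence.
    """
    limit = fraction * bin_count
    if len(candidates) <= limit:
        return set(candidates)
    keep = ceil(limit)
    evidence = candidates if isinstance(candidates, dict) else {}

    def rank(b: int) -> tuple:
        r = stats[b].repetitiveness if stats[b].defined else 1.0
        return (round(r / 0.05), -evidence.get(b, 0), b)

    return set(sorted(candidates, key=rank)[:keep])


@dataclass
class Cart:
    """A batch of query segments bound for the same reference bin."""

    bin_id: int
    capacity: int
    segments: list[int] = field(default_factory=list)

    @property
    def full(self) -> bool:
        return len(self.segments) >= self.capacity

    def add(self, seg_index: int) -> None:
        if self.full:
            raise RuntimeError("cart over capacity")
        self.segments.append(seg_index)


class CartQueue:
    """FIFO of full carts with a bounded number of queued carts."""

    def __init__(self, max_full_carts: int):
        if max_full_carts < 1:
            raise ValueError("max_full_carts must be >= 1")
        self.max_full_carts = max_full_carts
        self._queue: deque[Cart] = deque()

    def __len__(self) -> int:
        return len(self._queue)

    @property
    def full(self) -> bool:
        return len(self._queue) >= self.max_full_carts

    def enqueue(self, cart: Cart) -> None:
        if self.full:
            raise RuntimeError("queue over capacity")
        self._queue.append(cart)

    def dequeue(self) -> Cart:
        return self._queue.popleft()


@dataclass
class PipelineReport:
    """Observability of the filter funnel plus the exactly-once trace."""

    candidate_pairs: list[tuple[int, int]] = field(default_factory=list)
    processed_pairs: list[tuple[int, int]] = field(default_factory=list)
    n_regions: int = 0
    n_raw_matches: int = 0
    n_matches: int = 0
    params: FilterParams | None = None


def _consume_cart(
    cart: Cart,
    index: ReferenceIndex,
    ref_seqs: Mapping[str, str],
    q_segments: list[Segment],
    q_codes: list[np.ndarray],
    spec: EpsilonSpec,
    cfg: AlignConfig,
    q: int,
    report: PipelineReport,
) -> list[LocalMatch]:
    """One consumer job: SWIFT filter + alignment of a cart against its bin."""
    bin_seg = index.segments[cart.bin_id]
    bin_codes = encode(
        ref_seqs[bin_seg.sequence_id][bin_seg.start : bin_seg.end]
    )
    batch = {si: q_codes[si] for si in cart.segments}
    gram_index = QGramIndex(batch, q)
    matches: list[LocalMatch] = []
    frames = [("+", bin_codes), ("-", revcomp_codes(bin_codes))]
    for strand, frame in frames:
        regions = swift_scan(frame, gram_index, spec, strand=strand)
        report.n_regions += len(regions)
        for region in regions:
            seg = q_segments[region.query_id]
            hits = align_region(frame, q_codes[region.query_id], region, spec, cfg)
            for h in hits:
                if not is_epsilon_match(h["length"], h["errors"], spec):
                    continue
                if strand == "+":
                    rs = bin_seg.start + h["r_start"]
                    re_ = bin_seg.start + h["r_end"]
                else:
                    Lb = len(bin_codes)
                    rs = bin_seg.start + (Lb - h["r_end"])
                    re_ = bin_seg.start + (Lb - h["r_start"])
                matches.append(
                    LocalMatch(
                        ref_id=bin_seg.sequence_id,
                        ref_start=rs, ref_end=re_,
                        query_id=seg.sequence_id,
                        query_start=seg.start + h["q_start"],
                        query_end=seg.start + h["q_end"],
                        strand=strand,
                        length=h["length"], errors=h["errors"],
                        score=h["score"],
                    )
                )
    for si in cart.segments:
        report.processed_pairs.append((si, cart.bin_id))
    return matches


def search(
    ref_records: Sequence[tuple[str, str]],
    query_records: Sequence[tuple[str, str]],
    config: SearchConfig,
    params: FilterParams | None = None,
    index: ReferenceIndex | None = None,
) -> tuple[list[LocalMatch], PipelineReport]:
    """Full search: deduce parameters, index, prefilter, verify, align, merge.

    Deterministic for a fixed configuration; worker count, cart capacity and
    queue bound do not change the consolidated result.
    """
    spec = config.spec
    ref_len = sum(len(s) for _, s in ref_records)
    if params is None:
        bin_len = None
        if index is not None:
            bin_len = max(s.length for s in index.segments)
        params = resolve_params(ref_len, config, bin_len)
    if index is None:
        index = build_index(ref_records, config, params.shape)
    elif index.shape != params.shape:
        raise ValueError("index was built with a different seed shape")
    logger.info(
        "search: spec=(%d,%d) shape=%s t=%d lossless=%s workers=%d "
        "cart_capacity=%d max_full_carts=%d chunk_size=%d",
        spec.l_min, spec.e_max, params.shape, params.threshold,
        params.lossless, config.workers, config.cart_capacity,
        config.max_full_carts, config.chunk_size,
    )
    report = PipelineReport(params=params)

    ref_seqs = dict(ref_records)
    query_seqs = dict(query_records)
    ref_bin_len = max(s.length for s in index.segments)
    q_target = max(1, ceil(sum(len(s) for _, s in query_records) / ref_bin_len))
    q_segments = split(
        [(qid, len(s)) for qid, s in query_records],
        q_target, config.effective_overlap, role="query",
    )
    q_codes = [
        encode(query_seqs[s.sequence_id][s.start : s.end]) for s in q_segments
    ]

    q = default_q(spec, segment_length=ref_bin_len)
    cfg = config.align
    matches: list[LocalMatch] = []
    open_carts: dict[int, Cart] = {}
    queue = CartQueue(config.max_full_carts)

    def consume(cart: Cart) -> None:
        matches.extend(
            _consume_cart(cart, index, ref_seqs, q_segments, q_codes,
                          spec, cfg, q, report)
        )

    # producer loop: prefilter each query segment, route into per-bin carts
    for si, seg in enumerate(q_segments):
        bins = prefilter_query_segment(index.ibf, q_codes[si], params, spec)
        bins = repeat_filter(bins, index.stats, index.bin_count,
                             config.repeat_fraction)
        for b in sorted(bins):
            report.candidate_pairs.append((si, b))
            cart = open_carts.get(b)
            if cart is None:
                cart = open_carts[b] = Cart(b, config.cart_capacity)
            cart.add(si)
            if cart.full:
                if queue.full:
                    consume(queue.dequeue())
                queue.enqueue(cart)
                del open_carts[b]
    # flush: remaining queued carts FIFO, then partial carts by bin id
    while len(queue):
        consume(queue.dequeue())
    for b in sorted(open_carts):
        consume(open_carts[b])

    report.n_raw_matches = len(matches)
    ref_codes = {rid: encode(s) for rid, s in ref_records}
    query_codes = {qid: encode(s) for qid, s in query_records}
    final = consolidate(matches, ref_codes, query_codes, spec, cfg)
    if config.annotate_evalues and final:
        model = EvalueModel.calibrate(
            m=ref_len, n_total=sum(len(s) for _, s in query_records), cfg=cfg
        )
        for m in final:
            m.evalue = evalue(m, model)
    report.n_matches = len(final)
    logger.info(
        "funnel: %d candidate pairs -> %d regions -> %d raw -> %d matches",
        len(report.candidate_pairs), report.n_regions,
        report.n_raw_matches, report.n_matches,
    )
    return final, report
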