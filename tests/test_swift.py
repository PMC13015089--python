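"""SWIFT-level q-gram index and diagonal parallelogram filtering."""

import numpy as np
import pytest

from epsalign.params import EpsilonSpec, lemma_threshold
from epsalign.shapes import encode
from epsalign.simulate import simulate_pair
from epsalign.swift import QGramIndex, build_qgram_index, default_q, swift_scan


class TestQGramIndex:
    def test_small_example(self):
        idx = build_qgram_index({0: encode("ACGTACGT")}, 4)
        assert len(idx) == 5
        hits = idx.lookup(_pack("ACGT"))
        assert sorted(p for _, p in hits) == [0, 4]

    def test_empty(self):
        assert len(build_qgram_index({}, 4)) == 0

    def test_lookup_agrees_with_naive_scan(self, dna_factory):
        seq = dna_factory(1000)
        q = 6
        idx = build_qgram_index({0: encode(seq)}, q)
        for probe_at in [0, 17, 500, 994]:
            word = seq[probe_at : probe_at + q]
            expected = [
                i for i in range(len(seq) - q + 1) if seq[i : i + q] == word
            ]
            got = sorted(p for _, p in idx.lookup(_pack(word)))
            assert got == expected

    def test_n_windows_excluded(self):
        idx = build_qgram_index({0: encode("ACGTNACGT")}, 4)
        assert len(idx) == 2  # only the two N-free windows

    def test_rejects_tiny_q(self):
        with pytest.raises(ValueError):
            build_qgram_index({0: encode("ACGTACGT")}, 3)


def _pack(word: str) -> int:
    v = 0
    for c in word:
        v = (v << 2) | "ACGT".index(c)
    return v


class TestDefaultQ:
    def test_lossless_range(self):
        for e in range(0, 6):
            spec = EpsilonSpec(50, e)
            q = default_q(spec, segment_length=16_000)
            assert 4 <= q <= 32
            assert lemma_threshold(50, e, q) >= 1

    def test_matches_largest_word_without_segment_length(self):
        assert default_q(EpsilonSpec(50, 2)) == 16
        assert default_q(EpsilonSpec(50, 5)) == 8


class TestSwiftScan:
    def test_identical_sequences_single_region(self, dna_factory):
        seq = dna_factory(200)
        spec = EpsilonSpec(50, 5)
        idx = build_qgram_index({0: encode(seq)}, 8)
        regions = swift_scan(encode(seq), idx, spec)
        assert len(regions) == 1
        r = regions[0]
        assert r.qs <= 0 + spec.l_min and r.qe >= 200 - spec.l_min
        assert r.dmin <= 0 <= r.dmax

    def test_no_shared_qgrams_empty(self):
        idx = build_qgram_index({0: encode("A" * 100)}, 8)
        regions = swift_scan(encode("C" * 100), idx, EpsilonSpec(50, 5))
        assert regions == []

    def test_regions_disjoint_after_merging(self, dna_factory):
        """No two emitted regions for one segment overlap in both query
        extent and diagonal range (no duplicate emission)."""
        a, b, _ = simulate_pair(3000, 0.04, density=500, seed=11)
        spec = EpsilonSpec(50, 2)
        idx = build_qgram_index({0: encode(b)}, 16)
        regions = swift_scan(encode(a), idx, spec)
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                q_overlap = r1.qs < r2.qe and r2.qs < r1.qe
                d_overlap = r1.dmin <= r2.dmax and r2.dmin <= r1.dmax
                assert not (q_overlap and d_overlap)

    @pytest.mark.parametrize("seed", range(10))
    def test_losslessness_on_implanted_matches(self, seed):
        """Every implanted epsilon(50,3)-match is covered by an emitted
        region (query interval intersected, true diagonal inside the band)
        at the counting-lemma threshold."""
        a, b, truth = simulate_pair(2000, 0.06, density=600, seed=seed)
        spec = EpsilonSpec(50, 3)
        q = default_q(spec, segment_length=2000)
        idx = build_qgram_index({0: encode(b)}, q)
        regions = swift_scan(encode(a), idx, spec)
        for t in truth:
            diag = t.source_start - t.implant_start
            hit = any(
                r.qs < t.implant_end and t.implant_start < r.qe
                and r.dmin - spec.e_max <= diag <= r.dmax + spec.e_max
                for r in regions
            )
            assert hit, f"implant at {t.implant_start} not covered"
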