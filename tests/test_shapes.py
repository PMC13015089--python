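"""Seed-shape parsing, strand symmetry and canonical k-mer extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epsalign.shapes import (
    DEFAULT_SHAPE,
    SeedShape,
    ShapeError,
    adjacent_shared_positions,
    canonical_kmer_stream,
    is_symmetric,
    parse_shape,
    revcomp,
    symmetric_shape_for_weight,
)

PH_ASYM = "111010010100110111"  # classic asymmetric high-sensitivity seed


@pytest.mark.parametrize(
    "text,span,weight",
    [(DEFAULT_SHAPE, 18, 12), ("1", 1, 1), ("11011", 5, 4)],
)
def test_parse_shape(text, span, weight):
    shape = parse_shape(text)
    assert shape.span == span
    assert shape.weight == weight
    assert str(shape) == text


@pytest.mark.parametrize("bad", ["", "102", "011", "110", "0", "abc"])
def test_parse_shape_rejects_malformed(bad):
    with pytest.raises(ShapeError):
        parse_shape(bad)


@pytest.mark.parametrize(
    "text,expected",
    [(DEFAULT_SHAPE, True), (PH_ASYM, False), ("1", True), ("11011", True)],
)
def test_symmetry(text, expected):
    assert is_symmetric(parse_shape(text)) is expected


def test_adjacent_shared_positions_gapped_seeds():
    """The symmetric default shares 5 positions worst case; the asymmetric
    seed's reverse-complement orientation shares 8 with its neighbour."""
    assert adjacent_shared_positions(
        parse_shape(DEFAULT_SHAPE), "canonical_worst_case") == 5
    assert adjacent_shared_positions(
        parse_shape(PH_ASYM), "canonical_worst_case") == 8


@pytest.mark.parametrize("k", [1, 2, 3, 5, 12])
def test_adjacent_shared_positions_ungapped(k):
    assert adjacent_shared_positions(SeedShape.ungapped(k), "same_strand") == k - 1


def test_gapped_seed_beats_ungapped_overlap():
    gapped = adjacent_shared_positions(parse_shape(DEFAULT_SHAPE),
                                       "canonical_worst_case")
    ungapped = adjacent_shared_positions(SeedShape.ungapped(12), "same_strand")
    assert gapped == 5 < ungapped == 11


def test_canonical_stream_acgt_palindrome():
    stream = canonical_kmer_stream("ACGT", parse_shape("11"))
    assert len(stream) == 3
    assert stream.values[0] == stream.values[2]  # AC and GT are complements
    assert stream.valid.all()


def test_canonical_stream_homopolymer():
    stream = canonical_kmer_stream("AAAAA", parse_shape("11"))
    assert len(stream) == 4
    assert len(set(stream.values.tolist())) == 1


def test_canonical_stream_short_and_empty():
    assert len(canonical_kmer_stream("", parse_shape("11"))) == 0
    assert len(canonical_kmer_stream("ACG", parse_shape("1111"))) == 0


def test_non_acgt_windows_flagged_invalid():
    shape = parse_shape("111")
    stream = canonical_kmer_stream("ACGTNACGT", shape)
    # windows covering index 4 (positions 2,3,4) are invalid
    assert list(np.flatnonzero(~stream.valid)) == [2, 3, 4]
    assert stream.valid_values.size == 4


def test_kmer_records_iterate():
    recs = list(canonical_kmer_stream("ACGTA", parse_shape("11")))
    assert [r.position for r in recs] == [0, 1, 2, 3]
    assert all(r.valid for r in recs)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=18, max_size=80))
def test_reverse_complement_invariance_symmetric_shape(seq):
    """For a symmetric shape the stream of revcomp(s) is the reversed value
    sequence of the stream of s (canonical k-mers are strand-free)."""
    shape = parse_shape(DEFAULT_SHAPE)
    fwd = canonical_kmer_stream(seq, shape)
    rev = canonical_kmer_stream(revcomp(seq), shape)
    assert np.array_equal(fwd.values, rev.values[::-1])
    assert np.array_equal(fwd.valid, rev.valid[::-1])


def test_revcomp_multiset_equality(dna_factory):
    shape = parse_shape(DEFAULT_SHAPE)
    for _ in range(100):
        s = dna_factory(50)
        a = sorted(canonical_kmer_stream(s, shape).values.tolist())
        b = sorted(canonical_kmer_stream(revcomp(s), shape).values.tolist())
        assert a == b


@pytest.mark.parametrize("w", [12, 13, 14, 16, 20])
def test_symmetric_family_weights(w):
    shape = symmetric_shape_for_weight(w)
    assert shape.weight == w
    assert is_symmetric(shape)
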