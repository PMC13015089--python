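"""Banded local alignment, epsilon acceptance, consolidation, E-values."""

import edlib
import numpy as np
import pytest

from epsalign.align import (
    AlignConfig,
    EvalueModel,
    LocalMatch,
    align_region,
    consolidate,
    edit_ops,
    evalue,
    is_epsilon_match,
    min_epsilon_score,
    trim_to_epsilon,
    waterman_eggert,
    OP_MATCH,
)
from epsalign.params import EpsilonSpec
from epsalign.shapes import encode, revcomp
from epsalign.simulate import simulate_pair
from epsalign.swift import CandidateRegion
from epsalign.pipeline import SearchConfig, search


SPEC55 = EpsilonSpec(50, 5)


class TestEpsilonPredicate:
    @pytest.mark.parametrize(
        "n,e,ok",
        [(50, 5, True), (49, 0, False), (100, 11, False), (100, 10, True),
         (50, 0, True), (51, 5, True)],
    )
    def test_boundaries(self, n, e, ok):
        assert is_epsilon_match(n, e, SPEC55) is ok

    def test_integer_arithmetic_no_float(self):
        # 3/30 == 0.1 exactly at rate e_max/l_min = 5/50; must accept n=30? no:
        # n below l_min is rejected regardless of rate
        assert not is_epsilon_match(30, 3, SPEC55)

    def test_rejects_nonsense(self):
        with pytest.raises(ValueError):
            is_epsilon_match(0, 0, SPEC55)


def full_band_region(nq: int, nr: int) -> CandidateRegion:
    return CandidateRegion(query_id=0, qs=0, qe=nq, dmin=-nq, dmax=nr, strand="+")


class TestAlignRegion:
    def test_identity_full_span(self, dna_factory):
        seq = dna_factory(60)
        hits = align_region(encode(seq), encode(seq),
                            full_band_region(60, 60), SPEC55)
        assert len(hits) == 1
        h = hits[0]
        assert (h["q_start"], h["q_end"], h["r_start"], h["r_end"]) == (0, 60, 0, 60)
        assert (h["length"], h["errors"]) == (60, 0)

    def test_error_rate_bound(self, rng, dna_factory):
        """7 substitutions in 60 bp exceed the 10% rate: any reported match
        must come from a sub-window that itself satisfies the rate."""
        seq = dna_factory(60)
        mutated = list(seq)
        for pos in rng.choice(60, size=7, replace=False):
            mutated[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
        hits = align_region(encode(seq), encode("".join(mutated)),
                            full_band_region(60, 60), SPEC55)
        for h in hits:
            assert is_epsilon_match(h["length"], h["errors"], SPEC55)
            assert not (h["length"] == 60 and h["errors"] == 7)

    def test_degenerate_band_empty(self, dna_factory):
        region = CandidateRegion(query_id=0, qs=30, qe=30, dmin=0, dmax=0)
        assert align_region(encode(dna_factory(60)), encode(dna_factory(60)),
                            region, SPEC55) == []

    def test_matches_reverify_with_edit_distance(self):
        """Claimed error counts are achievable: the edit distance of the
        reported interval pair never exceeds the stored error count."""
        a, b, _ = simulate_pair(2000, 0.06, density=500, seed=3)
        spec = EpsilonSpec(50, 3)
        hits = align_region(encode(a), encode(b),
                            full_band_region(len(b), len(a)), spec)
        assert hits
        for h in hits:
            d = edlib.align(b[h["q_start"]:h["q_end"]],
                            a[h["r_start"]:h["r_end"]],
                            task="distance")["editDistance"]
            assert d <= h["errors"]
            assert is_epsilon_match(h["length"], h["errors"], spec)


class TestTrim:
    def test_clean_window_kept_whole(self):
        ops = np.zeros(80, dtype=np.uint8)
        assert trim_to_epsilon(ops, SPEC55) == (0, 80, 0)

    def test_too_short_rejected(self):
        assert trim_to_epsilon(np.zeros(49, dtype=np.uint8), SPEC55) is None

    def test_boundary_error_included(self):
        # 49 matches + 1 trailing mismatch: the 50-col window at 1 error
        # satisfies 1*50 <= 5*50
        ops = np.concatenate([np.zeros(49, np.uint8), np.array([1], np.uint8)])
        assert trim_to_epsilon(ops, SPEC55) == (0, 50, 1)

    def test_longest_window_wins(self):
        # errors clustered at the front: the trailing clean stretch plus as
        # many error columns as the rate allows
        ops = np.concatenate([np.ones(10, np.uint8), np.zeros(90, np.uint8)])
        a, b, e = trim_to_epsilon(ops, SPEC55)
        assert b == 100
        assert e * 50 <= 5 * (b - a)
        assert (b - a) >= 90


def test_edit_ops_matches_edlib(dna_factory, rng):
    for _ in range(50):
        s1 = dna_factory(int(rng.integers(5, 80)))
        s2 = dna_factory(int(rng.integers(5, 80)))
        ops = edit_ops(encode(s1), encode(s2))
        mine = int(np.sum(ops != OP_MATCH))
        ref = edlib.align(s2, s1, mode="NW", task="distance")["editDistance"]
        assert mine == ref


class TestConsolidate:
    def _codes(self, a, b):
        return {"ref": encode(a)}, {"qry": encode(b)}

    def test_duplicates_collapse(self, dna_factory):
        a = dna_factory(200)
        m = LocalMatch("ref", 10, 70, "qry", 10, 70, "+", 60, 0, 60)
        ref, qry = self._codes(a, a)
        out = consolidate([m, LocalMatch(**m.__dict__)], ref, qry, SPEC55)
        assert len(out) == 1

    def test_disjoint_unchanged(self, dna_factory):
        a = dna_factory(400)
        m1 = LocalMatch("ref", 0, 60, "qry", 0, 60, "+", 60, 0, 60)
        m2 = LocalMatch("ref", 200, 260, "qry", 300, 360, "+", 60, 0, 60)
        ref, qry = self._codes(a, a)
        out = consolidate([m1, m2], ref, qry, SPEC55)
        assert {m.key for m in out} == {m1.key, m2.key}

    def test_contained_match_dropped(self, dna_factory):
        a = dna_factory(300)
        big = LocalMatch("ref", 0, 200, "qry", 0, 200, "+", 200, 2, 190)
        small = LocalMatch("ref", 50, 120, "qry", 50, 120, "+", 70, 3, 55)
        ref, qry = self._codes(a, a)
        out = consolidate([big, small], ref, qry, SPEC55)
        assert [m.key for m in out] == [big.key]

    def test_idempotent(self, dna_factory):
        a, b, _ = simulate_pair(2000, 0.04, density=500, seed=9)
        config = SearchConfig(min_length=50, errors=2, bins=2,
                              repeat_fraction=1.0)
        matches, _ = search([("ref", a)], [("qry", b)], config)
        ref, qry = {"ref": encode(a)}, {"qry": encode(b)}
        again = consolidate(matches, ref, qry, EpsilonSpec(50, 2))
        assert [m.key for m in again] == [m.key for m in matches]

    def test_split_long_match_reunited(self):
        """A 300 bp implant searched with segments splitting it yields one
        consolidated match covering it."""
        a, b, truth = simulate_pair(4000, 0.04, density=2000,
                                    length_range=(300, 300), seed=5)
        config = SearchConfig(min_length=50, errors=2, bins=8,
                              overlap=100, repeat_fraction=1.0)
        matches, _ = search([("ref", a)], [("qry", b)], config)
        for t in truth:
            covering = [
                m for m in matches
                if m.query_start <= t.implant_start + 10
                and m.query_end >= t.implant_end - 10
            ]
            assert len(covering) == 1


class TestStrandHandling:
    def test_reverse_complement_query_swaps_strand(self, dna_factory):
        a, b, truth = simulate_pair(3000, 0.02, density=800, seed=21)
        config = SearchConfig(min_length=50, errors=1, bins=2,
                              repeat_fraction=1.0)
        fwd, _ = search([("ref", a)], [("qry", b)], config)
        rev, _ = search([("ref", a)], [("qry", revcomp(b))], config)
        assert len(fwd) == len(rev) > 0
        L = len(b)
        flipped = sorted(
            (m.ref_start, m.ref_end, L - m.query_end, L - m.query_start,
             {"+": "-", "-": "+"}[m.strand])
            for m in rev
        )
        original = sorted(
            (m.ref_start, m.ref_end, m.query_start, m.query_end, m.strand)
            for m in fwd
        )
        assert flipped == original


class TestEvalue:
    def test_linear_in_search_space(self):
        m = LocalMatch("r", 0, 100, "q", 0, 100, "+", 100, 0, 100)
        e1 = evalue(m, EvalueModel.calibrate(10_000, 10_000))
        e2 = evalue(m, EvalueModel.calibrate(20_000, 10_000))
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_in_score(self):
        model = EvalueModel.calibrate(10_000, 10_000)
        scores = [40, 60, 80, 100]
        es = [
            evalue(LocalMatch("r", 0, s, "q", 0, s, "+", s, 0, s), model)
            for s in scores
        ]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_self_match_highly_significant(self):
        model = EvalueModel.calibrate(10_000, 10_000)
        m = LocalMatch("r", 0, 100, "q", 0, 100, "+", 100, 0, 100)
        assert evalue(m, model) < 1e-20

    def test_uncalibrated_rejected(self):
        with pytest.raises(ValueError):
            EvalueModel(lam=0.0, K=0.1, m=1, n_total=1)


def test_min_epsilon_score():
    assert min_epsilon_score(EpsilonSpec(50, 5), AlignConfig()) == 35
    assert min_epsilon_score(EpsilonSpec(50, 0), AlignConfig()) == 50


def test_waterman_eggert_reports_non_intersecting(dna_factory):
    """Two separated exact repeats give two alignments; paths never share
    cells (second alignment is found after masking the first)."""
    core = dna_factory(80)
    ref = dna_factory(40) + core + dna_factory(60) + core + dna_factory(40)
    raws = waterman_eggert(encode(ref), encode(core), AlignConfig(), 40)
    assert len(raws) == 2
    spans = sorted((r.r_start, r.r_end) for r in raws)
    assert spans[0][1] <= spans[1][0]
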