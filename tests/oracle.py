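"""Independent exhaustive reference for epsilon-match search.

Implements its own full-matrix Smith-Waterman / Waterman-Eggert DP (no
banding, no prefilters, no segmentation) over whole sequences, on both
strands, and reports matches through the same published window-extraction
definition as the library (`best_epsilon_window`).  Comparing the pipeline's
consolidated output against this oracle checks that segmentation, IBF
prefiltering, cart batching, SWIFT filtering, banding and consolidation
neither lose nor invent matches.  Match validity itself (error counts versus
the stored intervals) is verified separately against edlib.
"""

from __future__ import annotations

import numpy as np

from epsalign.align import (
    AlignConfig,
    RawAlignment,
    epsilon_windows,
    min_epsilon_score,
    _window_match,
)
from epsalign.params import EpsilonSpec
from epsalign.shapes import encode, revcomp


def _full_matrix_waterman_eggert(ref, query, cfg, min_score, max_alignments=64):
    """Plain row-by-row scalar-free DP, written independently of the library."""
    nq, nr = len(query), len(ref)
    forbidden = np.zeros((nq + 1, nr + 1), dtype=bool)
    out = []
    for _ in range(max_alignments):
        H = np.zeros((nq + 1, nr + 1), dtype=np.int32)
        P = np.zeros((nq + 1, nr + 1), dtype=np.uint8)
        for s in range(2, nq + nr + 1):
            lo = max(1, s - nr)
            hi = min(nq, s - 1)
            i = np.arange(lo, hi + 1)
            j = s - i
            qv = query[i - 1]
            rv = ref[j - 1]
            sub = np.where((qv == rv) & (qv < 4), cfg.match, cfg.mismatch)
            diag = H[i - 1, j - 1] + sub
            up = H[i - 1, j] + cfg.gap
            left = H[i, j - 1] + cfg.gap
            val = np.maximum(diag, np.maximum(up, left))
            ptr = np.where(val == diag, 1, np.where(val == up, 2, 3))
            dead = (val <= 0) | forbidden[i, j]
            H[i, j] = np.where(dead, 0, val)
            P[i, j] = np.where(dead, 0, ptr).astype(np.uint8)
        best = int(H.max())
        if best < min_score:
            break
        flat = int(np.argmax(H))
        i0, j0 = divmod(flat, nr + 1)
        i, j = i0, j0
        ops_rev = []
        cells = []
        d_lo = d_hi = j - i
        while H[i, j] > 0 and P[i, j] != 0:
            cells.append((i, j))
            d_lo = min(d_lo, j - i)
            d_hi = max(d_hi, j - i)
            move = P[i, j]
            if move == 1:
                ops_rev.append(
                    0 if (query[i - 1] == ref[j - 1] and query[i - 1] < 4) else 1
                )
                i, j = i - 1, j - 1
            elif move == 2:
                ops_rev.append(2)
                i -= 1
            else:
                ops_rev.append(3)
                j -= 1
        out.append(
            RawAlignment(i, i0, j, j0, np.array(ops_rev[::-1], np.uint8),
                         best, d_lo, d_hi)
        )
        for c in cells:
            forbidden[c] = True
    return out


def oracle_matches(ref_seq: str, query_seq: str, spec: EpsilonSpec,
                   cfg: AlignConfig = AlignConfig()):
    """All epsilon-matches of a sequence pair, both strands, exhaustively.

    Returns tuples (ref_start, ref_end, query_start, query_end, strand,
    length, errors) in forward-strand coordinates, containment-pruned.
    """
    ref = encode(ref_seq)
    qry = encode(query_seq)
    min_score = min_epsilon_score(spec, cfg)
    results = []
    for strand, frame in (("+", ref), ("-", encode(revcomp(ref_seq)))):
        L = len(frame)
        for raw in _full_matrix_waterman_eggert(frame, qry, cfg, min_score):
            _ext, chosen, wins = epsilon_windows(frame, qry, raw, spec, cfg)
            for trim in wins:
                qs, qe, rs, re_, n, e, _score = _window_match(chosen, trim, cfg)
                if strand == "-":
                    rs, re_ = L - re_, L - rs
                results.append((rs, re_, qs, qe, strand, n, e))
    results = _prune(results)
    return sorted(set(results))


def match_sets_equivalent(got, exp, tol: int) -> bool:
    """One-to-one correspondence with endpoint tolerance.

    Rate-maximal windows are not unique — their boundary columns are
    error-filled and can shift by a few positions depending on how much
    flanking context a view exposed — so matches are compared as a bijection
    with all four coordinates within ``tol`` and identical strand.
    """
    if len(got) != len(exp):
        return False
    remaining = list(exp)
    for g in got:
        for cand in remaining:
            if g[4] == cand[4] and all(
                abs(g[i] - cand[i]) <= tol for i in range(4)
            ):
                remaining.remove(cand)
                break
        else:
            return False
    return True


def _prune(results):
    # containment pruning mirrors the reported-set semantics
    pruned = []
    for m in results:
        dominated = any(
            o is not m
            and o[4] == m[4]
            and o[0] <= m[0] and m[1] <= o[1]
            and o[2] <= m[2] and m[3] <= o[3]
            and m[6] >= o[6]
            and (o[0], o[1], o[2], o[3]) != (m[0], m[1], m[2], m[3])
            for o in results
        )
        if not dominated:
            pruned.append(m)
    return sorted(set(pruned))
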