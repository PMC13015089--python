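"""Banded Waterman-Eggert local alignment and epsilon-match reporting.

Inside each candidate region the aligner runs an exact local-alignment DP
(match +1, mismatch -2, linear gap -2 by default) restricted to the region's
diagonal band, reports the best local alignment, trims it to its longest
sub-window satisfying the epsilon criteria (length >= l_min and
errors/length <= e_max/l_min, in integer arithmetic), then masks the
alignment's cells and repeats — the Waterman-Eggert scheme for
non-intersecting suboptimal local alignments.  Iteration stops once the best
score falls below the minimum any epsilon-match can have, which for scoring
(m, x, g) is (l_min - e_max)*m + e_max*min(x, g).

If an alignment touches its window or band boundary the region is widened
and realigned, so reported coordinates do not depend on how the prefilters
happened to draw the region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .params import EpsilonSpec
from .swift import CandidateRegion

OP_MATCH, OP_MISMATCH, OP_INS, OP_DEL = 0, 1, 2, 3
_CONSUMES_Q = {OP_MATCH: 1, OP_MISMATCH: 1, OP_INS: 1, OP_DEL: 0}
_CONSUMES_R = {OP_MATCH: 1, OP_MISMATCH: 1, OP_INS: 0, OP_DEL: 1}


@dataclass(frozen=True)
class AlignConfig:
    """Scoring and banding knobs for the local aligner.

    ``xdrop`` is kept as the margin used when deciding whether an alignment
    sits too close to its band edge (triggering adaptive band widening); the
    DP itself is exact.  ``band_pad`` widens the candidate region's diagonal
    band before aligning.
    """

    match: int = 1
    mismatch: int = -2
    gap: int = -2
    xdrop: int = 4
    band_pad: int = 8
    max_alignments: int = 64

    def __post_init__(self) -> None:
        if self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if self.match <= 0 or self.xdrop <= 0:
            raise ValueError("match reward and xdrop must be positive")


def is_epsilon_match(n: int, e: int, spec: EpsilonSpec) -> bool:
    """n >= l_min and e/n <= e_max/l_min, in exact integer arithmetic."""
    if n < 1 or e < 0:
        raise ValueError("need n >= 1 and e >= 0")
    return n >= spec.l_min and e * spec.l_min <= spec.e_max * n


def min_epsilon_score(spec: EpsilonSpec, cfg: AlignConfig) -> int:
    """Lowest local-alignment score any epsilon-match can have."""
    worst = min(cfg.mismatch, cfg.gap)
    return max(1, (spec.l_min - spec.e_max) * cfg.match + spec.e_max * worst)


@dataclass
class RawAlignment:
    """One traceback: half-open local coordinates plus the column op string."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    ops: np.ndarray  # uint8 column operations
    score: int
    diag_min: int = 0  # min/max of (ref_pos - query_pos) along the path
    diag_max: int = 0


def waterman_eggert(
    ref: np.ndarray,
    query: np.ndarray,
    cfg: AlignConfig,
    min_score: int,
    dlo: int | None = None,
    dhi: int | None = None,
) -> list[RawAlignment]:
    """All non-intersecting local alignments scoring at least ``min_score``.

    Exact DP over the (optionally band-restricted) matrix; after each
    traceback the path cells are forbidden and the matrix recomputed.
    Deterministic tie-break: the first maximal cell in row-major
    (query-major) order wins.
    """
    nq, nr = len(query), len(ref)
    if nq == 0 or nr == 0:
        return []
    if dlo is None:
        dlo = -nq
    if dhi is None:
        dhi = nr
    W = nr + 1
    H = np.zeros((nq + 1) * W, dtype=np.int32)
    P = np.zeros((nq + 1) * W, dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    forbidden = np.zeros((nq + 1) * W, dtype=bool)
    out: list[RawAlignment] = []

    q_arr = np.asarray(query, dtype=np.int16)
    r_arr = np.asarray(ref, dtype=np.int16)

    for _iter in range(cfg.max_alignments):
        H[:] = 0
        P[:] = 0
        for s in range(2, nq + nr + 1):
            i_lo = max(1, s - nr, -((dhi - s) // 2))  # ceil((s - dhi)/2)
            i_hi = min(nq, s - 1, (s - dlo) // 2)
            if i_lo > i_hi:
                continue
            i = np.arange(i_lo, i_hi + 1)
            idx = i * W + (s - i)
            qv = q_arr[i - 1]
            rv = r_arr[s - i - 1]
            sub = np.where((qv == rv) & (qv < 4), cfg.match, cfg.mismatch)
            diag = H[idx - W - 1] + sub
            up = H[idx - W] + cfg.gap
            left = H[idx - 1] + cfg.gap
            val = np.maximum(diag, np.maximum(up, left))
            ptr = np.where(
                val == diag, 1, np.where(val == up, 2, 3)
            ).astype(np.uint8)
            dead = (val <= 0) | forbidden[idx]
            val = np.where(dead, 0, val)
            ptr = np.where(dead, 0, ptr)
            H[idx] = val
            P[idx] = ptr

        best_flat = int(np.argmax(H))
        best = int(H[best_flat])
        if best < min_score:
            break
        i, j = divmod(best_flat, W)
        ops_rev: list[int] = []
        cells = []
        d_lo = d_hi = j - i
        while H[i * W + j] > 0 and P[i * W + j] != 0:
            cells.append(i * W + j)
            d_lo = min(d_lo, j - i)
            d_hi = max(d_hi, j - i)
            move = P[i * W + j]
            if move == 1:
                ops_rev.append(
                    OP_MATCH
                    if (q_arr[i - 1] == r_arr[j - 1] and q_arr[i - 1] < 4)
                    else OP_MISMATCH
                )
                i, j = i - 1, j - 1
            elif move == 2:
                ops_rev.append(OP_INS)
                i -= 1
            else:
                ops_rev.append(OP_DEL)
                j -= 1
        qe, re_ = divmod(best_flat, W)
        out.append(
            RawAlignment(
                q_start=i, q_end=qe, r_start=j, r_end=re_,
                ops=np.array(ops_rev[::-1], dtype=np.uint8), score=best,
                diag_min=d_lo, diag_max=d_hi,
            )
        )
        forbidden[cells] = True
    return out


def greedy_extend(
    ref: np.ndarray,
    query: np.ndarray,
    raw: RawAlignment,
    spec: EpsilonSpec,
) -> RawAlignment:
    """Extend a score-maximal alignment outward with error-tolerant columns.

    The score-maximal local alignment trims terminal error columns, but the
    epsilon criterion is about length at a bounded error *rate*, so a match
    may legitimately start or end on errors (e.g. length exactly l_min with
    an edit in its last column).  Both ends are therefore extended greedily
    — matching columns preferred, then whichever edit re-synchronises the
    next residues — for up to 3*e_max + 12 columns per side; the subsequent
    epsilon trim keeps only the portion that helps.
    """
    cap = 3 * spec.e_max + 12
    nq, nr = len(query), len(ref)

    def walk(i: int, j: int, step: int) -> list[int]:
        ops: list[int] = []
        for _ in range(cap):
            ni, nj = i + step, j + step
            fwd = step > 0
            qi, rj = (i, j) if fwd else (ni, nj)
            if not (0 <= qi < nq and 0 <= rj < nr):
                break
            if query[qi] == ref[rj] and query[qi] < 4:
                ops.append(OP_MATCH)
                i, j = ni, nj
                continue
            # probe which edit re-synchronises the following column
            qi2, rj2 = qi + step, rj + step
            diag_ok = 0 <= qi2 < nq and 0 <= rj2 < nr and query[qi2] == ref[rj2]
            del_ok = 0 <= rj2 < nr and query[qi] == ref[rj2]
            ins_ok = 0 <= qi2 < nq and query[qi2] == ref[rj]
            if diag_ok or not (del_ok or ins_ok):
                if not (0 <= qi < nq and 0 <= rj < nr):
                    break
                ops.append(OP_MISMATCH)
                i, j = ni, nj
            elif del_ok:
                ops.append(OP_DEL)
                j = j + step
            else:
                ops.append(OP_INS)
                i = i + step
        return ops

    fwd_ops = walk(raw.q_end, raw.r_end, +1)
    back_ops = walk(raw.q_start, raw.r_start, -1)
    if not fwd_ops and not back_ops:
        return raw
    ops = np.concatenate(
        [np.array(back_ops[::-1], np.uint8), raw.ops,
         np.array(fwd_ops, np.uint8)]
    )
    dq_f = sum(_CONSUMES_Q[o] for o in fwd_ops)
    dr_f = sum(_CONSUMES_R[o] for o in fwd_ops)
    dq_b = sum(_CONSUMES_Q[o] for o in back_ops)
    dr_b = sum(_CONSUMES_R[o] for o in back_ops)
    return RawAlignment(
        q_start=raw.q_start - dq_b, q_end=raw.q_end + dq_f,
        r_start=raw.r_start - dr_b, r_end=raw.r_end + dr_f,
        ops=ops, score=raw.score,
        diag_min=min(raw.diag_min, raw.r_start - dr_b - (raw.q_start - dq_b),
                     raw.r_end + dr_f - (raw.q_end + dq_f)),
        diag_max=max(raw.diag_max, raw.r_start - dr_b - (raw.q_start - dq_b),
                     raw.r_end + dr_f - (raw.q_end + dq_f)),
    )


def edit_ops(ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Column operations of a minimal-edit (unit cost) global alignment.

    The score-maximal local path can trade the tail of a true match for an
    indel shortcut into lucky flanking matches, destroying the clean window
    the epsilon trim needs; the edit-optimal path of the same interval pair
    never spends an indel where matches suffice.  Row-vectorised DP using the
    prefix-minimum trick for the horizontal (unit-gap) dependency.
    """
    nq, nr = len(query), len(ref)
    if nq == 0 or nr == 0:
        return np.full(max(nq, nr), OP_DEL if nq == 0 else OP_INS, np.uint8)
    D = np.empty((nq + 1, nr + 1), dtype=np.int32)
    D[0, :] = np.arange(nr + 1)
    D[:, 0] = np.arange(nq + 1)
    j_idx = np.arange(1, nr + 1)
    for i in range(1, nq + 1):
        sub = np.where((ref[:nr] == query[i - 1]) & (query[i - 1] < 4), 0, 1)
        m = np.minimum(D[i - 1, :nr] + sub, D[i - 1, 1:] + 1)
        # horizontal unit gaps chain: D[i,j] = min_{k<=j}(m[k] + (j-k)),
        # including the row border D[i,0] + j; a prefix minimum of m[k]-k
        prefix = np.minimum.accumulate(np.concatenate(([D[i, 0]], m - j_idx)))
        D[i, 1:] = prefix[1:] + j_idx
    # traceback, preferring diagonal, then deletion (ref gap consumer), then
    # insertion — deterministic
    i, j = nq, nr
    ops_rev: list[int] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = 0 if (ref[j - 1] == query[i - 1] and query[i - 1] < 4) else 1
            if D[i, j] == D[i - 1, j - 1] + sub:
                ops_rev.append(OP_MATCH if sub == 0 else OP_MISMATCH)
                i, j = i - 1, j - 1
                continue
        if j > 0 and D[i, j] == D[i, j - 1] + 1:
            ops_rev.append(OP_DEL)
            j -= 1
            continue
        ops_rev.append(OP_INS)
        i -= 1
    return np.array(ops_rev[::-1], dtype=np.uint8)


def trim_to_epsilon(ops: np.ndarray, spec: EpsilonSpec) -> tuple[int, int, int] | None:
    """Longest column window [a, b) that is an epsilon-match, or None.

    Returns (a, b, errors); ties broken toward the smaller start.
    """
    n = len(ops)
    if n < spec.l_min:
        return None
    err = np.concatenate(([0], np.cumsum((ops != OP_MATCH).astype(np.int64))))
    best: tuple[int, int, int] | None = None
    best_len = spec.l_min - 1
    for a in range(n - spec.l_min + 1):
        b_arr = np.arange(a + max(spec.l_min, best_len), n + 1)
        if b_arr.size == 0:
            continue
        ok = (err[b_arr] - err[a]) * spec.l_min <= spec.e_max * (b_arr - a)
        hits = np.flatnonzero(ok)
        if hits.size == 0:
            continue
        b = int(b_arr[hits[-1]])
        if b - a > best_len:
            best_len = b - a
            best = (a, b, int(err[b] - err[a]))
    return best


@dataclass
class LocalMatch:
    """A reported epsilon-match in parent (forward-strand) coordinates.

    ``strand == '-'`` means the reverse complement of the query interval
    aligns to the forward reference interval.  ``length`` counts alignment
    columns, ``errors`` counts edit (mismatch/indel) columns.
    """

    ref_id: str
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str
    length: int
    errors: int
    score: int
    evalue: float | None = None

    @property
    def key(self) -> tuple:
        return (self.ref_id, self.ref_start, self.ref_end, self.query_id,
                self.query_start, self.query_end, self.strand)

    def contains(self, other: "LocalMatch") -> bool:
        return (
            self.ref_id == other.ref_id
            and self.query_id == other.query_id
            and self.strand == other.strand
            and self.ref_start <= other.ref_start
            and other.ref_end <= self.ref_end
            and self.query_start <= other.query_start
            and other.query_end <= self.query_end
        )


def slide_gaps(ops: np.ndarray, ref: np.ndarray, query: np.ndarray,
               r0: int, q0: int, direction: int) -> np.ndarray:
    """Normalise indel placement by sliding gaps through matching context.

    An indel inside a repeat can sit anywhere within the repeated stretch
    without changing the edit count; its placement decides whether a clean
    window is split.  Slides every I/D column past adjacent match columns as
    far as possible in ``direction`` (+1 right, -1 left), swapping only when
    the re-paired column is still a match.
    """
    out = [int(o) for o in ops]
    n = len(out)
    if direction > 0:
        qi, rj = q0, r0
        for k in range(n - 1):
            a, b = out[k], out[k + 1]
            if a in (OP_DEL, OP_INS) and b == OP_MATCH \
                    and query[qi] == ref[rj] and query[qi] < 4:
                out[k], out[k + 1] = OP_MATCH, a
            qi += _CONSUMES_Q[out[k]]
            rj += _CONSUMES_R[out[k]]
    else:
        # states before each column are fixed by the prefix, which sliding
        # a gap leftward never revisits, so one precomputation suffices
        states = []
        qi, rj = q0, r0
        for o in out:
            states.append((qi, rj))
            qi += _CONSUMES_Q[o]
            rj += _CONSUMES_R[o]
        for k in range(n - 2, -1, -1):
            a, b = out[k], out[k + 1]
            i, j = states[k]
            if a == OP_MATCH and b == OP_DEL and query[i] == ref[j + 1] \
                    and query[i] < 4:
                out[k], out[k + 1] = OP_DEL, OP_MATCH
            elif a == OP_MATCH and b == OP_INS and query[i + 1] == ref[j] \
                    and query[i + 1] < 4:
                out[k], out[k + 1] = OP_INS, OP_MATCH
    return np.array(out, dtype=np.uint8)


def all_epsilon_windows(ops: np.ndarray,
                        spec: EpsilonSpec) -> list[tuple[int, int, int]]:
    """All disjoint epsilon windows of one op string, best-first recursion.

    A single score-maximal path can bridge two distinct matches when the
    bridge costs less than the second match scores; after taking the best
    window, the left and right remainders are searched recursively so no
    match hiding inside a bridged path is lost.
    """
    out: list[tuple[int, int, int]] = []
    stack = [(0, len(ops))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < spec.l_min:
            continue
        t = trim_to_epsilon(ops[lo:hi], spec)
        if t is None:
            continue
        a, b, e = t
        out.append((lo + a, lo + b, e))
        stack.append((lo, lo + a))
        stack.append((lo + b, hi))
    return sorted(out)


def epsilon_windows(
    ref: np.ndarray,
    query: np.ndarray,
    raw: RawAlignment,
    spec: EpsilonSpec,
    cfg: AlignConfig,
) -> tuple[RawAlignment, RawAlignment, list[tuple[int, int, int]]]:
    """Extend a raw alignment and enumerate its epsilon windows.

    Returns (extended score path, chosen variant, windows).  Considers the
    greedily extended score-maximal path and the minimal-edit
    re-alignment of a symmetrically widened interval around the raw path —
    the score optimum trims terminal error columns and can take indel
    shortcuts, while the widened edit path reconstructs end structure
    (including terminal indels) optimally — plus the gap-slid
    normalisations of the edit path.  The variant whose best window is
    longest wins.
    """
    ext = greedy_extend(ref, query, raw, spec)
    cap = 3 * spec.e_max + 12
    wq0, wq1 = max(0, raw.q_start - cap), min(len(query), raw.q_end + cap)
    wr0, wr1 = max(0, raw.r_start - cap), min(len(ref), raw.r_end + cap)
    eops = edit_ops(ref[wr0:wr1], query[wq0:wq1])
    wide_base = (wq0, wq1, wr0, wr1)
    variants: list[tuple[tuple[int, int, int, int], np.ndarray]] = [
        ((ext.q_start, ext.q_end, ext.r_start, ext.r_end), ext.ops),
        (wide_base, eops),
        (wide_base, slide_gaps(eops, ref, query, wr0, wq0, +1)),
        (wide_base, slide_gaps(eops, ref, query, wr0, wq0, -1)),
    ]
    best = None
    best_key = None
    for base, ops_v in variants:
        t = trim_to_epsilon(ops_v, spec)
        if t is None:
            continue
        key = (t[1] - t[0], -t[2])
        if best_key is None or key > best_key:
            best, best_key = (base, ops_v), key
    if best is None:
        return ext, ext, []
    (bq0, bq1, br0, br1), ops_b = best
    chosen = RawAlignment(bq0, bq1, br0, br1, ops_b, ext.score,
                          ext.diag_min, ext.diag_max)
    return ext, chosen, all_epsilon_windows(ops_b, spec)


def best_epsilon_window(
    ref: np.ndarray,
    query: np.ndarray,
    raw: RawAlignment,
    spec: EpsilonSpec,
    cfg: AlignConfig,
) -> tuple[RawAlignment, tuple[int, int, int]] | None:
    """The single longest epsilon window of a raw alignment, or None."""
    _ext, chosen, wins = epsilon_windows(ref, query, raw, spec, cfg)
    if not wins:
        return None
    best = max(wins, key=lambda t: (t[1] - t[0], -t[2]))
    return chosen, best


def _window_match(raw: RawAlignment, trim: tuple[int, int, int],
                  cfg: AlignConfig) -> tuple[int, int, int, int, int, int, int]:
    """Map a trimmed column window back to (q, r) intervals plus stats."""
    a, b, errors = trim
    ops = raw.ops
    qc = np.concatenate(([0], np.cumsum([_CONSUMES_Q[o] for o in ops])))
    rc = np.concatenate(([0], np.cumsum([_CONSUMES_R[o] for o in ops])))
    qs = raw.q_start + int(qc[a])
    qe = raw.q_start + int(qc[b])
    rs = raw.r_start + int(rc[a])
    re_ = raw.r_start + int(rc[b])
    win = ops[a:b]
    n_m = int(np.sum(win == OP_MATCH))
    n_x = int(np.sum(win == OP_MISMATCH))
    n_g = len(win) - n_m - n_x
    score = n_m * cfg.match + n_x * cfg.mismatch + n_g * cfg.gap
    return qs, qe, rs, re_, b - a, errors, score


def align_region(
    ref_codes: np.ndarray,
    query_codes: np.ndarray,
    region: CandidateRegion,
    spec: EpsilonSpec,
    cfg: AlignConfig = AlignConfig(),
) -> list[dict]:
    """Epsilon-matches inside one candidate region (local coordinates).

    Returns dicts with q_start/q_end/r_start/r_end (on the passed arrays),
    length, errors and score.  The window and band are widened and realigned
    whenever a reported alignment touches a boundary, so results are
    insensitive to the exact region the filters emitted.
    """
    nq, nr = len(query_codes), len(ref_codes)
    min_score = min_epsilon_score(spec, cfg)
    grow_q, grow_d = spec.l_min, cfg.band_pad
    for _round in range(8):
        qs = max(0, region.qs)
        qe = min(nq, region.qe)
        rs = max(0, min(nr, region.qs + region.dmin))
        re_ = max(0, min(nr, region.qe + region.dmax))
        if qe - qs <= 0 or re_ - rs <= 0:
            return []
        shift = rs - qs
        dlo = region.dmin - shift - cfg.band_pad
        dhi = region.dmax - shift + cfg.band_pad
        ref_win = ref_codes[rs:re_]
        q_win = query_codes[qs:qe]
        raws = waterman_eggert(ref_win, q_win, cfg, min_score, dlo, dhi)
        processed = [epsilon_windows(ref_win, q_win, raw, spec, cfg)
                     for raw in raws]
        margin = max(1, cfg.xdrop // cfg.match)
        touches = False
        for raw, _chosen, _wins in processed:
            if (raw.q_start == 0 and qs > 0) or (raw.q_end == qe - qs and qe < nq):
                touches = True
            if (raw.r_start == 0 and rs > 0) or (raw.r_end == re_ - rs and re_ < nr):
                touches = True
            if (raw.diag_min <= dlo + margin and dlo > -(qe - qs)) or \
               (raw.diag_max >= dhi - margin and dhi < re_ - rs):
                touches = True
        final_round = _round == 7
        whole = qs == 0 and qe == nq and rs == 0 and re_ == nr
        if not touches or whole or final_round:
            results = []
            for _ext, chosen, wins in processed:
                for trim in wins:
                    lqs, lqe, lrs, lre, n, e, score = _window_match(
                        chosen, trim, cfg)
                    results.append(
                        dict(
                            q_start=qs + lqs, q_end=qs + lqe,
                            r_start=rs + lrs, r_end=rs + lre,
                            length=n, errors=e, score=score,
                        )
                    )
            return results
        region = replace(
            region,
            qs=region.qs - grow_q, qe=region.qe + grow_q,
            dmin=region.dmin - grow_d, dmax=region.dmax + grow_d,
        )
        grow_q *= 2
        grow_d *= 2
    return []


# -- consolidation -----------------------------------------------------------


def _rc_frame(match: LocalMatch, ref_len: int) -> tuple[int, int]:
    """Reference interval of a minus-strand match in the revcomp frame."""
    return ref_len - match.ref_end, ref_len - match.ref_start


def _mergeable(a: LocalMatch, b: LocalMatch, ref_len: int,
               spec: EpsilonSpec, cfg: AlignConfig) -> bool:
    """Cheap test that two matches could be fragments of one split match:
    nearby in both query and reference, on compatible diagonals."""
    if (a.ref_id, a.query_id, a.strand) != (b.ref_id, b.query_id, b.strand):
        return False
    qgap = max(a.query_start, b.query_start) - min(a.query_end, b.query_end)
    if qgap > spec.l_min:
        return False
    if a.strand == "-":
        ars, are = _rc_frame(a, ref_len)
        brs, bre = _rc_frame(b, ref_len)
    else:
        ars, are, brs, bre = a.ref_start, a.ref_end, b.ref_start, b.ref_end
    rgap = max(ars, brs) - min(are, bre)
    if rgap > spec.l_min:
        return False
    d_a, d_b = ars - a.query_start, brs - b.query_start
    total = a.length + b.length + max(0, qgap)
    tol = spec.e_max * (total // spec.l_min + 2) + cfg.band_pad
    return abs(d_a - d_b) <= tol


def _try_merge(
    a: LocalMatch,
    b: LocalMatch,
    ref_codes: Mapping[str, np.ndarray],
    query_codes: Mapping[str, np.ndarray],
    spec: EpsilonSpec,
    cfg: AlignConfig,
) -> LocalMatch | None:
    """Re-align the union window of two fragments; accept if one match covers both."""
    from .shapes import revcomp_codes

    ref = ref_codes[a.ref_id]
    qry = query_codes[a.query_id]
    L = len(ref)
    if a.strand == "-":
        frame = revcomp_codes(ref)
        ars, are = _rc_frame(a, L)
        brs, bre = _rc_frame(b, L)
    else:
        frame = ref
        ars, are, brs, bre = a.ref_start, a.ref_end, b.ref_start, b.ref_end
    pad = spec.l_min
    rs = max(0, min(ars, brs) - pad)
    re_ = min(L, max(are, bre) + pad)
    qs = max(0, min(a.query_start, b.query_start) - pad)
    qe = min(len(qry), max(a.query_end, b.query_end) + pad)
    shift = rs - qs
    d_lo = min(ars - a.query_start, brs - b.query_start) - shift - 2 * pad
    d_hi = max(ars - a.query_start, brs - b.query_start) - shift + 2 * pad
    raws = waterman_eggert(
        frame[rs:re_], qry[qs:qe], cfg, min_epsilon_score(spec, cfg),
        dlo=d_lo, dhi=d_hi,
    )
    for raw in raws:
        w = best_epsilon_window(frame[rs:re_], qry[qs:qe], raw, spec, cfg)
        if w is None:
            continue
        raw, trim = w
        lqs, lqe, lrs, lre, n, e, score = _window_match(raw, trim, cfg)
        g_qs, g_qe = qs + lqs, qs + lqe
        g_rs, g_re = rs + lrs, rs + lre
        # fragment endpoints carry rate-filled extension columns of up to the
        # extension cap; the merged clean window need not cover those, and a
        # non-covered stretch below l_min cannot hide an independent match
        slack = 3 * spec.e_max + 12
        covers_q = g_qs <= min(a.query_start, b.query_start) + slack and \
            g_qe >= max(a.query_end, b.query_end) - slack
        covers_r = g_rs <= min(ars, brs) + slack and g_re >= max(are, bre) - slack
        if covers_q and covers_r and (g_qe - g_qs) >= max(
            a.query_end - a.query_start, b.query_end - b.query_start
        ):
            if a.strand == "-":
                g_rs, g_re = L - g_re, L - g_rs
            return LocalMatch(
                a.ref_id, g_rs, g_re, a.query_id, g_qs, g_qe,
                a.strand, n, e, score,
            )
    return None


def _maximize(
    match: LocalMatch,
    ref_codes: Mapping[str, np.ndarray],
    query_codes: Mapping[str, np.ndarray],
    spec: EpsilonSpec,
    cfg: AlignConfig,
) -> LocalMatch:
    """Re-align a match in a padded window until its epsilon window stops
    growing.  Fragments merged across segment borders can admit a longer
    rate-compliant window than the union of their own views exposed."""
    from .shapes import revcomp_codes

    current = match
    pad = spec.l_min
    for _ in range(8):
        ref = ref_codes[current.ref_id]
        qry = query_codes[current.query_id]
        L = len(ref)
        if current.strand == "-":
            frame = revcomp_codes(ref)
            frs, fre = _rc_frame(current, L)
        else:
            frame = ref
            frs, fre = current.ref_start, current.ref_end
        rs = max(0, frs - pad)
        re_ = min(L, fre + pad)
        qs = max(0, current.query_start - pad)
        qe = min(len(qry), current.query_end + pad)
        shift = rs - qs
        tol = spec.e_max * (current.length // spec.l_min + 2) + cfg.band_pad
        dlo = (frs - current.query_start) - shift - tol
        dhi = (fre - current.query_end) - shift + tol
        raws = waterman_eggert(frame[rs:re_], qry[qs:qe], cfg,
                               min_epsilon_score(spec, cfg), dlo, dhi)
        best = None
        for raw in raws:
            w = best_epsilon_window(frame[rs:re_], qry[qs:qe], raw, spec, cfg)
            if w is None:
                continue
            lqs, lqe, lrs, lre, n, e, score = _window_match(w[0], w[1], cfg)
            g_qs, g_qe = qs + lqs, qs + lqe
            g_rs, g_re = rs + lrs, rs + lre
            # only windows overlapping the current match are its extensions
            if g_qe <= current.query_start or g_qs >= current.query_end:
                continue
            if best is None or n > best[4]:
                best = (g_rs, g_re, g_qs, g_qe, n, e, score)
        if best is None or best[4] <= current.length:
            # a longer window may need more flanking context than the pad
            # exposed (error budgets shrink with the window); widen and retry
            if pad >= 8 * spec.l_min:
                return current
            pad *= 2
            continue
        g_rs, g_re, g_qs, g_qe, n, e, score = best
        if current.strand == "-":
            g_rs, g_re = L - g_re, L - g_rs
        current = LocalMatch(current.ref_id, g_rs, g_re, current.query_id,
                             g_qs, g_qe, current.strand, n, e, score)
        pad = spec.l_min
    return current


def consolidate(
    matches: Sequence[LocalMatch],
    ref_codes: Mapping[str, np.ndarray],
    query_codes: Mapping[str, np.ndarray],
    spec: EpsilonSpec,
    cfg: AlignConfig = AlignConfig(),
) -> list[LocalMatch]:
    """Deduplicate, merge border-split fragments, drop contained matches.

    Exact duplicates collapse to one; overlapping or abutting fragments of
    one longer match (created by segment borders) are merged when re-aligning
    their joined window still yields a single epsilon-match covering both;
    a match contained in another with no fewer errors is dropped.  The
    procedure is idempotent.
    """
    # exact duplicates
    seen: dict[tuple, LocalMatch] = {}
    for m in sorted(matches, key=lambda m: m.key):
        seen.setdefault(m.key, m)
    pool = list(seen.values())

    # merge split fragments per (ref, query, strand) group; after a merge the
    # grown match stays in place and is re-tried against its neighbours, and
    # whole passes repeat until stable (a merged match can enable another)
    changed = True
    while changed:
        changed = False
        pool.sort(key=lambda m: (m.ref_id, m.query_id, m.strand, m.query_start))
        i = 0
        while i < len(pool):
            j = i + 1
            while j < len(pool):
                a, b = pool[i], pool[j]
                if (a.ref_id, a.query_id, a.strand) != \
                        (b.ref_id, b.query_id, b.strand):
                    break
                if b.query_start - a.query_end > spec.l_min:
                    break
                if a.contains(b) or b.contains(a) or not _mergeable(
                    a, b, len(ref_codes[a.ref_id]), spec, cfg
                ):
                    j += 1
                    continue
                merged = _try_merge(a, b, ref_codes, query_codes, spec, cfg)
                if merged is not None:
                    pool[i] = _maximize(merged, ref_codes, query_codes,
                                        spec, cfg)
                    del pool[j]
                    changed = True
                else:
                    j += 1
            i += 1

    # containment and overlap dominance: reported matches behave like the
    # non-intersecting alignments of a single exhaustive search, so a match
    # deeply overlapping a longer one on a compatible diagonal is a border
    # fragment of it and is dropped
    def overlap_dominated(m: LocalMatch, other: LocalMatch) -> bool:
        if (m.ref_id, m.query_id, m.strand) != \
                (other.ref_id, other.query_id, other.strand):
            return False
        if (other.length, -other.errors, [*m.key]) <= \
                (m.length, -m.errors, [*other.key]):
            return False
        q_ov = min(m.query_end, other.query_end) - \
            max(m.query_start, other.query_start)
        r_ov = min(m.ref_end, other.ref_end) - max(m.ref_start, other.ref_start)
        need = min(spec.l_min, min(m.length, other.length)) // 2
        if q_ov < need or r_ov < need:
            return False
        L = len(ref_codes[m.ref_id])
        if m.strand == "-":
            d_m = _rc_frame(m, L)[0] - m.query_start
            d_o = _rc_frame(other, L)[0] - other.query_start
        else:
            d_m = m.ref_start - m.query_start
            d_o = other.ref_start - other.query_start
        tol = spec.e_max * (max(m.length, other.length) // spec.l_min + 2) \
            + cfg.band_pad
        return abs(d_m - d_o) <= tol

    out: list[LocalMatch] = []
    for m in pool:
        dominated = any(
            other is not m and (
                (other.contains(m) and m.errors >= other.errors
                 and not (m.contains(other) and m.key < other.key))
                or overlap_dominated(m, other)
            )
            for other in pool
        )
        if not dominated:
            out.append(m)
    out.sort(key=lambda m: m.key)
    return out


# -- E-values ----------------------------------------------------------------


@dataclass(frozen=True)
class EvalueModel:
    """Karlin-Altschul parameters for the linear-gap scoring, annotation only.

    lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1 for the ungapped
    match/mismatch scores; K uses the leading-order lattice approximation
    K = lambda / E[S exp(lambda S)] clamped to (0, 1].  Gap costs are folded
    in only through the alignment score itself, so E-values are order-of-
    magnitude annotations, never used for filtering.
    """

    lam: float
    K: float
    m: int        # total reference length
    n_total: int  # total query length

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("uncalibrated E-value model")

    @classmethod
    def calibrate(cls, m: int, n_total: int, cfg: AlignConfig = AlignConfig(),
                  p_match: float = 0.25) -> "EvalueModel":
        def f(lam: float) -> float:
            return (p_match * exp(lam * cfg.match)
                    + (1 - p_match) * exp(lam * cfg.mismatch) - 1.0)

        lam = float(brentq(f, 1e-9, 20.0))
        deriv = (p_match * cfg.match * exp(lam * cfg.match)
                 + (1 - p_match) * cfg.mismatch * exp(lam * cfg.mismatch))
        K = min(1.0, max(1e-6, lam / deriv))
        return cls(lam, K, m, n_total)


def evalue(match: LocalMatch, model: EvalueModel) -> float:
    """E = K * m * n * exp(-lambda * S): expected chance alignments >= S."""
    return model.K * model.m * model.n_total * exp(-model.lam * match.score)
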