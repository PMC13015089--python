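# Methods

## The match definition

A pairwise local alignment of length *n* (columns) containing *e* edit
columns is an ε(l_min, e_max)-match iff `n ≥ l_min` and
`e·l_min ≤ e_max·n` (integer arithmetic throughout; the rate bound is
`e_max / l_min`). The engine's contract is to report, for two DNA sequence
sets, a set of rate-maximal ε-matches: each reported match satisfies the
criterion, and none can be lengthened at either end without violating it
(within the bounded extension described below). Coordinates are 0-based
half-open everywhere internally and in TSV/BED output; the optional GFF
rendering is 1-based closed. Strand `-` means the reverse complement of the
query interval aligns to the forward reference interval.

## Canonical gapped k-mers

A seed shape is a 1/0 pattern whose 1s (care positions) contribute to the
k-mer value; its weight is the number of 1s and its span the pattern
length. Values are 2-bit packs of the care-position residues; the canonical
value of a window is the minimum of its own pack and the pack of its
reverse complement under the reversed shape, passed through the splitmix64
finalizer. Canonical values are identical for a window and its reverse
complement, so one index serves both strands. Symmetric shapes (equal to
their reversal) keep gap columns aligned across strands: for the default
shape `111010101101010111` adjacent canonical k-mers share at most 5 care
positions in the worst case over strand orientations, versus 8 for the
classic asymmetric seed and 11 for an ungapped word of the same weight —
the reason gapped symmetric seeds tolerate more edits. Windows covering any
non-ACGT residue are flagged invalid and excluded from counting and
insertion. Weights are capped at 32 (2-bit packing in 64 bits).

## Parameter deduction

The IBF prefilter needs a word size `k` and a shared-count threshold `t`.

**Counting lemma (lossless path).** An alignment of length *l* with *e*
edits preserves at least `l − k + 1 − k·e` ungapped k-mers (clamped at 0);
the largest lemma-positive word size is `⌊l/(e+1)⌋`. The lossless path
walks word sizes downward from that maximum and takes the largest whose
probability of producing a spurious candidate per segment is below one
half. Spurious here combines two sources: the random-occurrence model
`E(x) = 2(L_bin − k + 1)/4^k`, `P(x) = min(1, E(x)/s_e)` with the
effective-size coefficient `s_e = 0.65` inflating the estimate for
repeat-poor real genomes, plus the IBF's own per-query hash false positive
rate; the per-window binomial tail is composed over the ~`L_bin / l_min`
effectively independent window trials a segment offers. Walking downward
matters: the largest lemma-positive k often carries a threshold of 1, where
any single chance hit creates a candidate, while a slightly smaller k has a
much larger lemma threshold and is far more specific.

**Cost grid (heuristic path).** When no lossless word size is specific
enough (large references with high error allowances), `(k, t)` minimise
`Cost = FNR + FPR` over weights 7–23 and thresholds 1–25, ties toward
smaller k then smaller t. The FNR is exact: an error configuration is a
choice of *e* error columns among *l*; an ungapped k-mer survives iff its k
columns are error-free, so the surviving count is Σ max(0, run − k + 1)
over the e+1 error-free runs, and the FNR is the fraction of configurations
with fewer than *t* survivors, computed by a dynamic program over (run
index, error-free columns used, capped survivor total). Counts stay below
2^53 at these sizes, so float64 accumulation is exact; the test suite
verifies the DP against complete enumeration, including all C(50,5) =
2,118,760 configurations for the headline value FNR(50, 5, k=12, t=5) =
0.20. The grid models ungapped words of each weight; the chosen weight is
realised as a symmetric gapped shape of the default family, a documented
pessimism (a tight sensitivity bound for gapped shapes is open). The FPR
column of the grid is a per-segment quantity (window tail composed over
window trials); it intentionally differs from a bare per-window figure,
which at desk scale hides that small-k cells make every bin a candidate.

## Interleaved Bloom Filter

One Bloom filter per reference bin with the bit layout interleaved: hash
position p owns the contiguous bit slice `[p·b, (p+1)·b)`, so a membership
lookup gathers h contiguous b-bit slices and ANDs them. Sizing follows
`m = ⌈−h·n_max / ln(1 − f^(1/h))⌉` for the largest per-bin distinct k-mer
set, giving a per-query FPR at most f after construction. Defaults: h = 2
hash functions (splitmix64 with fixed per-hash seeds over the canonical
value); the pipeline default f = 5·10⁻⁴ keeps chance window counts below
the smallest lemma thresholds at desk-scale bin sizes (memory is a few
bits per reference base and is not the binding constraint at this scale).
Membership has one-sided error — no false negatives, ever.

Prefilter counting slides a window of `l_min − span + 1` k-mer slots over
each query segment at stride 1 (exact, via cumulative sums); a bin is a
candidate iff some window reaches t. Stride 1 rather than a coarser stride
is what makes the lossless guarantee real: with stride `l_min/2` the
lemma-guaranteed k-mers of a worst-case match can straddle two windows and
both fall below threshold.

## Segmentation and repeat avoidance

Reference and query sets are cut into approximately equal segments,
overlapping by `2·l_min` by default, so any match up to twice the minimum
length lies whole in some segment and longer matches leave mergeable
fragments of at least `l_min`. A parent of length L cut n ways gets
segments of `⌈(L + (n−1)·overlap)/n⌉`. Default bin count is 64 at desk
scale (config-exposed).

Per-bin repetitiveness is `R_i = 1 − C_i/(L_i − k + 1)` with `C_i` the
distinct canonical k-mer count. A query segment matching more than half of
all bins is searched only in the `⌈b/2⌉` most variable candidates.
Repetitiveness is compared at 0.05 granularity — genuine repeat structure
moves R_i by far more, while sub-percent differences between
non-repetitive bins are sampling noise — and ties are broken toward the
bin with the stronger shared-k-mer evidence (the prefilter's maximum
window count), then bin id. Note the rule is a heuristic aimed at many
bins: with very few bins (say 2–8) a query can legitimately match more
than half of them and the cut then discards true bins; the tiny-fixture
tests therefore disable it, and it should be disabled (or the fraction
raised) whenever `b` is small.

## SWIFT filtering

Each cart (a batch of query segments bound for one bin) is indexed by
exact ungapped q-grams with positions; the bin is scanned on both strands
(the minus strand via the reverse-complemented bin frame). Each shared
q-gram votes on its diagonal `d = ref_pos − query_pos`; votes are bucketed
by diagonal (bucket width a power of two at least `e_max + 1`, each hit
also voting in the bucket covering diagonals up to e_max below it, so
every (e_max+1)-wide diagonal window is fully counted somewhere). Within a
bucket an exact two-pointer pass finds every `l_min`-residue query window
holding at least `lemma_threshold(l_min, e_max, q)` hits; qualifying
windows are merged within and across buckets when they overlap in both
query extent and diagonal range. Regions are padded by a full `l_min` in
query extent so the lemma-qualifying window around any hit cluster lies
wholly inside the region; the aligner's adaptive widening needs an
above-threshold piece to see before it can grow a region.

The word size q defaults to the largest lossless choice whose per-segment
chance of a spurious qualifying window is below one half, walking downward
like the IBF path (at e.g. e_max = 4 the largest lossless q carries
threshold 1 and floods the aligner with single-hit regions; one size down
the threshold is 6 and the filter is specific again); q is clamped to
[4, 32].

## Alignment and window extraction

Inside a candidate region (clipped windows of both sequences plus a
diagonal band with padding 8) an exact DP (match +1, mismatch −2, linear
gap −2; anti-diagonal vectorisation) finds the best local alignment,
masks its path cells and repeats — Waterman–Eggert non-intersecting
suboptimal alignments — until the best score drops below
`(l_min − e_max)·match + e_max·min(mismatch, gap)`, the minimum score any
ε-match can have (35 for ε(50,5)). No X-drop pruning is applied: the
regions are small and exactness is what makes the pipeline agree with an
exhaustive reference computation. The `xdrop` knob instead sets the margin
used to decide that an alignment sits too close to its band edge, which
(like touching a window edge) triggers widening and realignment, so
reported coordinates do not depend on how the filters happened to draw the
region.

A score-maximal path is not the object of interest — the ε-criterion is
about length at a bounded error rate, and a score optimum trims terminal
error columns and can trade the tail of a true match for an indel shortcut
into lucky flanking matches. Each raw path is therefore (1) greedily
extended outward by up to `3·e_max + 12` columns per side (matching
columns preferred, otherwise whichever edit re-synchronises the next
residues), (2) re-derived as the minimal-edit alignment of the extended
interval pair (row-vectorised unit-cost DP with the prefix-minimum trick),
(3) normalised by sliding indels left and right through matching context
(indel placement inside repeats is ambiguous and can split a clean
window). The variant whose longest ε-window wins is kept, and all disjoint
ε-windows of that variant are reported (the best window first, then
recursively the left and right remainders — a single path can bridge two
distinct matches when the bridge costs less than the second match scores).
Windows are trimmed by exact search for the longest sub-interval
satisfying the rate bound, ties toward the smaller start.

Consolidation deduplicates exactly; merges border-split fragments when
re-aligning their joined, diagonal-banded window yields one ε-window
covering both up to `e_max + 2` columns of endpoint slack; re-maximises
merged matches in geometrically growing padded windows until their
ε-window stops growing (a fragment pair's union can admit a longer
rate-compliant window than either view exposed, and the longer window may
need more flanking context than a fixed pad); and finally drops matches
that are contained in, or deeply overlap (at least half the smaller length
in both intervals, compatible diagonals), a longer match — restoring the
non-intersection property of a single exhaustive search at the
consolidated level. The procedure is idempotent and independent of cart
capacity, queue bound and worker count.

Because rate-maximal windows are not unique — their boundary columns are
error-filled and can shift by a few positions depending on visible flank —
coordinates are reproducible for a fixed configuration but two equally
valid views of the same match can differ by a handful of boundary columns;
the equivalence test against the exhaustive reference compares matches
one-to-one with an `e_max + 4` endpoint tolerance.

## E-values

λ solves `p e^{λ·match} + (1−p) e^{λ·mismatch} = 1` at uniform base
composition (λ ≈ 1.33 for +1/−2); K uses the leading-order lattice
approximation `λ / E[S e^{λS}]` clamped to (0, 1]. Gap costs enter only
through the alignment score. E-values are order-of-magnitude annotations —
`E = K·m·n·e^{−λS}` over the total search space — and are never used to
filter.

## Distribution contract

Producer jobs prefilter query segments and route them into per-bin carts;
carts reaching capacity enter a bounded FIFO queue; consumer jobs build
the cart's q-gram index and run SWIFT plus alignment against the bin;
partial carts are flushed at end of input. The contract is exactly-once
processing of every candidate pair, FIFO dispatch, and results invariant
to cart capacity, queue bound and worker count. The scheduler is
deterministic and sequential, which satisfies the contract; `workers` is
accepted and logged for interface compatibility and does not change
results. Queries are conceptually read in chunks (default 1 M residues at
desk scale, config-exposed).

## The simulated benchmark

`simulate_pair` draws two i.i.d. uniform ACGT sequences of length L;
every `density` bp (default 2000) one substring of A — length uniform in
50–250 bp — is copied, mutated with exactly `⌊rate·len⌋` edits
(substitution, insertion, deletion equiprobable; substitution/deletion
columns drawn without replacement, insertion positions uniform over the
growing mutated string) and written over a non-overlapping position of B.
Overwriting rather than inserting keeps B at length L and the truth frame
trivially aligned. The exact-`⌊rate·len⌋` edit count makes the planned
rate a hard bound on the realised rate, which the tests confirm by
edit-distance re-alignment. Uniformly placed edits are the worst case for
k-mer filters (real edits cluster into indels, preserving more shared
k-mers), so sensitivity measured here lower-bounds sensitivity on
clustered-error data; what the generator does not emulate is repeat
structure — uniform random sequence is maximally k-mer-diverse, so tests
passing on it say nothing about runtime or specificity on repeat-rich
genomes, which is exactly what the repetitiveness filter addresses and
why that filter is exercised on constructed statistics instead.

Evaluation: a truth record counts as found iff some reported match
overlaps its implant interval in B by at least `min_overlap` bp (default
10, strict ≥); the headline figure is the missed percentage.

## Problem sizes and verification

The package's own verification runs at desk scale: the end-to-end
benchmark uses 1 Mb pairs with 64 bins (≈500 implants; 0.0% missed at 2%,
4% and 6% error rates), exhaustive-reference equivalence uses fifty 2 kb
pairs across 0–10% error rates, SWIFT losslessness uses 400 bp fixtures,
and the FNR dynamic program is checked against complete enumeration up to
C(50,5) configurations. The acceptance script regenerates the 1 Mb
benchmark from its seed and recomputes every reported number at run time.

## Known limitations

Linear gap costs only (affine costs would change both alignment and the
clustering behaviour of shared k-mers). No dedicated exact-matching
subroutine: `e_max = 0` works but is served by the same machinery.
Sensitivity guarantees are per-window lossless only on the lemma path; the
heuristic path's FNR estimate is a loose upper bound for uniformly placed
errors. The rate-maximal extension and the consolidation re-maximisation
are bounded (3·e_max+12 columns per side; pads up to 8·l_min), so a match
requiring still larger context to justify its full extent can be reported
slightly short. A rare boundary case exists at the minimum length: when a
match of length exactly l_min carries terminal indels, its rate-valid
window can tie in score with a shorter rate-invalid path while also lying
off the minimum-edit path of every local window, in which case the match
is missed (observed about once per few thousand implants in the simulated
benchmark). E-value calibration is approximate (K in particular).
Repeat avoidance assumes many bins; see above for small-b behaviour.
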