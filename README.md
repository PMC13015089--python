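# epsalign

All-vs-all **ε-match search**: find every pairwise local alignment between
two DNA sequence sets whose length is at least `l_min` and whose edit-column
rate stays within a bound — an alignment of length *n* with *e*
insertion/substitution/deletion columns is an **ε(l_min, e_max)-match** iff

```
n ≥ l_min   and   e / n ≤ e_max / l_min
```

This criterion (rather than an E-value cutoff) defines a crisp, complete set
of local alignments, which matters for genome-to-genome homology scans and
for re-analysing reads that standard mappers leave unmapped: heuristic
seed-and-extend tools can silently miss a large share of such matches when
edits are spread evenly across the alignment.

## How it works

Exhaustive local alignment is quadratic, so the engine narrows the search in
two increasingly specific stages before aligning anything:

1. **IBF prefilter.** The reference is split into overlapping segments (one
   per bin) and the *canonical gapped k-mers* of each segment — strand-free
   values from a symmetric seed shape such as `111010101101010111` — are
   indexed in an Interleaved Bloom Filter. A reference bin stays a candidate
   for a query segment only if some `l_min`-residue query window shares at
   least `t` k-mers with it. The pair (k-mer weight, threshold `t`) is
   deduced per dataset: a **lossless** setting from the k-mer counting lemma
   (an alignment of length *l* with *e* edits preserves at least
   `l + 1 − k(e + 1)` ungapped k-mers) whenever a word size exists that is
   both lemma-positive and unlikely to match by chance, otherwise the
   minimiser of `Cost(k, t) = FNR + FPR`, where the FNR is the exact
   fraction of error configurations that break the threshold (a
   run-composition dynamic program) and the FPR is a binomial tail under a
   random-sequence occurrence model.
2. **SWIFT filter.** Surviving (query segment, bin) pairs are verified with
   an exact positional q-gram index: shared words vote on alignment-matrix
   diagonals, and only parallelograms (diagonal band × query window)
   reaching the counting-lemma threshold become candidate regions — a
   lossless filter.
3. **Banded Waterman–Eggert alignment.** Candidate regions are aligned
   exactly (match +1, mismatch −2, linear gap −2) with non-intersecting
   suboptimal traceback, rate-maximal extension, and ε-trimming; fragments
   split by segment borders are re-merged during consolidation. Matches
   carry Karlin–Altschul E-value annotations (never used for filtering).

Abundant queries hitting more than half of all reference bins are searched
only in the most *variable* half, where variability of a segment is its
fraction of distinct k-mers, `V_i = C_i / (L_i − k + 1)` — a built-in
repeat-avoidance strategy.

## Worked example

Simulate a 100 kb random pair with fifty 50–250 bp local alignments
implanted at a 4% uniform edit rate, index, search, and score the result:

```
$ epsalign simulate --length 100000 --error-rate 0.04 --seed 11 --out-prefix demo
simulated 100000 bp pair with 50 implants at 4% errors

$ epsalign index --ref demo.ref.fasta --bins 16 --min-length 50 --errors 2 --out demo.idx.npz
indexed 1 sequence(s) into 16 bins (shape 1111111111111111, t=3)

$ epsalign search --ref demo.ref.fasta --query demo.query.fasta \
      --index demo.idx.npz --min-length 50 --errors 2 --bins 16 \
      --out demo.matches.tsv
INFO funnel: 51 candidate pairs -> 53 regions -> 53 raw -> 50 matches
50 match(es) written to demo.matches.tsv

$ epsalign evaluate --truth demo.truth.tsv --matches demo.matches.tsv
missed 0.00% (0/50)

$ head -4 demo.matches.tsv
ref_id  ref_start  ref_end  query_id  query_start  query_end  strand  length  errors  score  evalue
ref     626        689      query     83794        83859      +       65      2       59     7.10528e-25
ref     2267       2471     query     75752        75957      +       208     8       184    3.18593e-97
ref     6130       6294     query     64724        64885      +       164     6       146    3.14147e-75
```

The parameters were deduced automatically: with one allowed error per 50 bp
the lossless path picks ungapped 16-mers with the lemma threshold `t = 3`,
and the funnel log shows the two filter levels reducing 16 bins × 7 query
segments to 53 aligned regions. Every reported row is an ε(50,2)-match in
0-based half-open coordinates; `errors` counts edit columns and `evalue`
annotates significance. All 50 implanted alignments are recovered.

For a large reference at a high error allowance the deduction switches to
the heuristic cost minimisation:

```
$ epsalign deduce --ref-len 50000000 --bins 64 --min-length 50 --errors 5
shape=111101010111010101111 weight=15 t=4 path=heuristic
```

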