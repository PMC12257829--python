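# Methods

## Model and definitions

DNA k-mers over {A, C, G, T} are treated as double-stranded molecules: a
k-mer `x` and its reverse complement `rc(x)` are two orientations of the same
object, represented by the canonical code `cc(x) = max(enc(x), enc(rc(x)))`.
`enc` maps a k-mer to a base-4 integer with the lexicographic digit order
A=0, C=1, G=2, T=3 and the leftmost character most significant. The maximum
(rather than the equally valid minimum) is fixed so that the documented
worked values (`enc(TACG) = 198`, `cc(TACG) = cc(CGTA) = 198`) hold
throughout the package. `k` is restricted to 2…31 so a code plus one mark bit
fits a 64-bit word; `k` is always carried explicitly next to a code and never
inferred from the value.

The canonical Hamming distance is `H(x, y) = min(d(x, y), d(x, rc(y)))`.
Given a set `K` of distinct canonical k-mers with occurrence counts (counting
saturates at 2 — uniqueness only distinguishes "once" from "more than once"),
a member is **weak** if another member lies at `H = 1`, **strong** otherwise.
Strongly unique = count 1 and strong; weakly unique = count 1 and weak;
non-unique = count ≥ 2.

## The expanded array

All marking algorithms run on a single substrate: the lexicographically
sorted array of all members of `K` in both orientations. Entries are stored
as `code << 1 | markbit` in unsigned 64-bit words, so sorting stored values
orders by code and the mark never perturbs comparisons (every character or
suffix extraction shifts bit 0 away first). Self-reverse-complementary
k-mers — possible only for even k — are stored once; the array holds
*distinct* k-mers, and the single entry represents both orientations. This
storage convention (mark in the LSB) is used uniformly by both algorithm
families, which keeps the driver and the on-disk format to one convention.

## Marking algorithms

**FourWay.** A recursive 4-way merge. At 1-based depth `d`, all k-mers of the
current interval share their first `d−1` characters; four cursors, one per
value of the `d`-th character, advance in increasing order of the length-
`(k−d)` suffixes. A 4-bit vector v (A=1, C=2, G=4, T=8) records which active
cursors hold the minimal suffix; `v & (v−1) ≠ 0` detects a tie, i.e. k-mers
differing only at position `d`, which are marked weak. The interval is then
cut at the `d`-th character and recursion proceeds at `d+1`. The recursion is
implemented with an explicit stack (no call-depth limits) whose scratch
buffers are allocated once per top-level call: profiles showed that per-block
allocations, not comparisons, dominated on large sparse inputs.

**Second-half processing.** Since both orientations are present, every weak
pair is discoverable twice, with the single difference once in each half
(position `p` in one orientation maps to `k+1−p` in the other;
`min_p max(p, k+1−p) = ⌊k/2⌋+1`). The default therefore partitions the array
into maximal blocks sharing their `⌊k/2⌋`-prefix (one linear scan) and starts
each block at depth `⌊k/2⌋+1`, touching only second-half positions. This
exact start depth is required for full coverage — including the middle
position of odd k — and is locked in by constructed-pair tests. The full
recursion from depth 1 remains available behind a flag and must (and does)
produce identical results.

**FourWay+Pairwise.** When an interval holds at most `τ` elements, recursion
book-keeping costs more than comparing, so the interval is finished by the
bit-parallel all-pairs test. Default `τ = 30`, robust across k; `τ = 1`
disables the hybrid. The threshold is a pure speed knob: outputs are
identical for every `τ ≥ 1` (tested over τ ∈ {1, 2, 24, 30, 100}).

**Quarter.** Each k-mer splits into the `ℓ = ⌊k/2⌋` prefix, a third quarter
`s1` of length `⌈(k−ℓ)/2⌉` and a last quarter `s2` of length `⌊(k−ℓ)/2⌋`
(the third quarter takes the extra position on ties, so the middle position
of odd k is always in `s1`; e.g. 25 = 12 + 7 + 6). If `H(x, y) = 1`, at least
one orientation pairing has its difference in `s1` or `s2`. Phase 1 tests all
pairs inside maximal runs sharing the `(ℓ+|s1|)`-prefix (difference in
`s2`); phase 2 swaps the `s1`/`s2` sections within each ℓ-prefix block,
re-sorts locally, and repeats the bucket scan with the `(ℓ+|s2|)`-prefix.
Phase 2 operates on a scratch copy carrying original indices so marks map
back positionally — contract-equivalent to re-sorting in place, but directly
verifiable (the stored order is bit-identical before and after). Large
buckets at small k are processed with the same quadratic loop; that regime is
accepted, not special-cased.

**Naive oracles.** Full pairwise comparison (all `n(n−1)/2` pairs with the
bit-parallel test; distinct canonical codes have `H ≥ 1`, so `H ≤ 1` is
exact) and neighborhood generation (all `3k` substitution neighbors,
canonicalized, binary-searched). The two define the same weak set by
independent routes and anchor every equivalence test. Neighbor
canonicalization is mandatory — a substituted k-mer may be stored under its
reverse complement. In baseline-benchmark mode the neighborhood method may
skip already-marked members and stop at the first hit; since hits always mark
both partners this cannot change the final set, and oracle mode keeps the
exhaustive behaviour for a simple postcondition.

**Self-rc guard.** A k-mer can lie at plain Hamming distance 1 from its *own*
reverse complement (e.g. CTTAG vs CTAAG). Both orientations are the same
canonical k-mer, so this is not a weak pair — weakness requires a distinct
partner — yet every expanded-array method would naively mark it. All marking
kernels therefore skip a candidate group of exactly two entries that are
mutual reverse complements (a group of three or more always gives each member
a distinct partner). The naive pairwise oracle is immune by construction,
which is how this case was isolated.

## Orientation propagation and parallel contract

Marking discovers each weak pair only in the orientation whose difference is
second-half; a sequential post-pass therefore unifies marks: a canonical
k-mer is weak iff either orientation is marked. The reverse complement of
each marked entry is located by binary search in the sorted array (no
auxiliary index); a missing rc is a hard error, as it violates orientation
closure. Because blocks never span a `g`-prefix boundary (`g ≤ ⌊k/2⌋`),
chunks own disjoint slices and marks are slice-local, so any chunk order,
thread count, input split `s`, and algorithm produce a bit-identical result —
tested as a full cross-product. Defaults: algorithm `fourway-pairwise`,
`τ = 30`, `g = min(5, ⌊k/2⌋)`, `s = 0`, one thread.

## Input handling

FASTA records are scanned once (single strand — canonicalization folds
orientations); every length-k window consisting solely of A/C/G/T contributes
one canonical occurrence, and any other character breaks the window entirely
(no wildcard expansion). Counting is an in-memory sort/unique with counts
clipped at 2; external k-mer counters are intentionally out of scope. Large
inputs can be expanded in `4^s` prefix-defined chunks to bound peak memory;
chunks concatenate to exactly the unsplit array.

## Synthetic data

`gen_all_weak` assembles disjoint quadruples {x, y, rc(x), rc(y)} where y is
x with one nucleotide replaced by its complement (`H(x, y) = 1` by
construction); quadruples with internal collisions (e.g. y = rc(x)) or
overlapping previously accepted codes are redrawn. This makes the weak
fraction exactly 1.0 and the entry count a multiple of 4; other target sizes
are rejected rather than approximated. `gen_all_strong` oversamples a random
orientation-closed array, removes every weak k-mer (removal cannot create
weakness), and keeps whole canonical groups until exactly n entries remain,
retrying with a larger oversampling factor when necessary. `gen_random`
draws distinct canonical codes uniformly, with an optional Bernoulli count-2
probability for classification tests. All generators flow from a single
seeded generator and are byte-reproducible.

What the generators do *not* emulate: genomic composition bias, repeat
structure, or the k-mer-count spectrum of real sequencing data. Passing the
extremal and random suites shows the algorithms are exactly correct on
arbitrary code sets — which is the property that transfers to real data,
since the algorithms are deterministic and distribution-free — but measured
weak fractions on synthetic data say nothing about real genomes.

## Numerical and implementation choices

Kernels are numba-compiled and operate on int64 views of the public uint64
arrays: every stored value fits in 63 bits (2k+1 ≤ 63), and signed views
avoid unsigned/signed promotion pitfalls while preserving order. The scalar
Python API is implemented independently of the kernels in plain integer
arithmetic; the two routes are cross-checked in tests, together with a
character-level string oracle. Degenerate inputs (empty sets, singleton
intervals, records shorter than k, blocks of all-invalid bases) are handled
explicitly and tested; block profiles report NaN fractions for blocks with
zero valid k-mer starts rather than inventing a denominator.

Problem sizes in the test and acceptance suites (500 random sets up to
n = 2000; extremal arrays of 10^4; determinism on 10^5; scaling at 10^6 vs
2·10^6 25-mers) were chosen as the smallest sizes at which each property is
meaningfully exercised — equivalence is exact at any size, and the scaling
measurement needs arrays well beyond cache.

## Known limitations

- Alphabet fixed to A/C/G/T; IUPAC codes break windows. `k ≤ 31`.
- Hamming distance 1 only; larger radii need a different approach.
- Counting is in-memory; billion-scale inputs would need an external counter
  feeding the binary array format.
- The Quarter method degrades on small k (large buckets), as expected of its
  design; FourWay+Pairwise is the default for this reason.
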