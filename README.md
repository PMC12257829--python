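# strongmark

Identify **weak** and **strong** canonical k-mers in DNA sequence collections,
and classify k-mers into strongly unique / weakly unique / non-unique.

## The problem

Alignment-free methods (read placement, xenograft sorting, metagenomic
profiling, error correction) rely on k-mers that identify a single location.
Plain uniqueness is fragile: one substitution can turn a unique k-mer into a
different k-mer that exists elsewhere in the collection. A *strongly unique*
k-mer is unique **and** has no Hamming-distance-1 neighbor anywhere in the
collection, so no single base change can produce misleading information.

Formally, k-mers are handled as double-stranded molecules: `x` and its
reverse complement `rc(x)` share one canonical code
`cc(x) = max(enc(x), enc(rc(x)))`, where `enc` reads the sequence as a base-4
integer (A=0, C=1, G=2, T=3). The canonical Hamming distance is
`H(x, y) = min(d(x, y), d(x, rc(y)))`. Given a set `K` of distinct canonical
k-mers, a member `x` is **weak** if some other `y ∈ K` has `H(x, y) = 1`, and
**strong** otherwise; a k-mer with count 1 that is strong is **strongly
unique**.

## Algorithms

All fast algorithms run on one substrate: the sorted *expanded array* holding
every member of `K` in both orientations, with the least significant bit of
each 64-bit entry reserved for the weak mark (`code << 1 | mark`).

- **FourWay** — a recursive 4-way merge over the sorted array: at depth `d`
  four cursors (one per value of the `d`-th character) advance in order of
  their length-(k−d) suffixes; tied minimal suffixes expose k-mers differing
  only at position `d`. Runs in `O(nk)` on integer codes.
- **FourWay+Pairwise** — the same recursion, but intervals of at most `τ`
  elements (default 30) are finished by a bit-parallel all-pairs test; much
  faster in practice, identical output for every `τ ≥ 1`.
- **Quarter** — split each k-mer into a `⌊k/2⌋`-prefix and two quarters `s1`,
  `s2`; all-pairs testing inside buckets sharing the `(⌊k/2⌋+|s1|)`-prefix
  catches differences in `s2`, and a swap of `s1`/`s2` with local re-sorting
  catches differences in `s1`.

Because the array contains both orientations, checking only second-half
positions suffices — the reverse-complement pair carries first-half
differences — and a final *orientation propagation* step unifies the marks.
Two naive baselines (full pairwise comparison; 3k-neighbor generation with
lookup) serve as oracles: every algorithm produces the exact same weak set.

The Hamming test itself is branch-free on 2k-bit codes: with `u = p XOR q`,
`h = (u | (u >> 1)) & 0101…01` has one set bit per differing position, and
`h & (h − 1) == 0` decides `d ≤ 1` without a population count.

## Worked example

```python
import strongmark as sm

kset = sm.count_canonical_kmers("genome.fa", k=25)      # counts saturate at 2
result = sm.run_marking(kset, algorithm="fourway-pairwise", threads=4)
classes = sm.classify(kset, result)
print(classes.class_counts())
```

Running `python examples/mark_weak_kmers.py` (a 38 bp toy sequence, k=9)
prints:

```
26 distinct canonical 9-mers counted (counts saturate at 2)
          pairwise: 9 weak, 17 strong
      neighborhood: 9 weak, 17 strong
           fourway: 9 weak, 17 strong
  fourway-pairwise: 9 weak, 17 strong
           quarter: 9 weak, 17 strong
```

Nine canonical 9-mers have a one-substitution partner in the sequence (weak);
the remaining seventeen are strong — every algorithm agrees exactly. The
other scripts in `examples/` cover the integer codec, the extremal synthetic
datasets, and block-wise uniqueness profiles.

A thin CLI wraps the same pipeline:

```bash
strongmark build --fasta genome.fa -k 25 --out genome.arr
strongmark mark  --input genome.arr --algorithm fourway-pairwise --out result
strongmark synth --mode all-weak -n 10000 -k 21 --seed 1 --out weak.arr
strongmark stats --fasta genome.fa -k 25 --out profile
```

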