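"""Synthetic k-mer datasets with controlled weakness structure.

Three generators cover the regimes used for validation and benchmarking:

* ``all_weak`` — every canonical k-mer in the output has a canonical
  Hamming-distance-1 partner in the output (weak fraction exactly 1.0);
* ``all_strong`` — no canonical k-mer has such a partner (exactly 0.0);
* ``random`` — uniform distinct canonical codes, for oracle-driven tests.

The extremal arrays emulate the structure of the benchmark datasets:
random codes, a complement-substitution neighbor per element for the weak
case, weak-removal for the strong case.  ``n`` counts entries of the final
expanded array (both orientations).  All randomness flows from the spec's
single seed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .build import CanonicalKmerSet, ExpandedArray, canonical_codes, rc_codes

__all__ = ["SyntheticSpec", "gen_all_weak", "gen_all_strong", "gen_random"]


class InfeasibleSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    n: entries in the final expanded array (all_weak / all_strong) or
    distinct canonical k-mers (random); k: k-mer length; seed: RNG seed;
    mode: all_weak | all_strong | random.
    """

    n: int
    k: int
    seed: int
    mode: str = "random"
    # probability that a random-mode k-mer gets count 2 instead of 1
    p_count2: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("all_weak", "all_strong", "random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n < 0 or (self.mode == "all_weak" and self.n < 2):
            raise InfeasibleSpecError("all_weak needs n >= 2 (pairs required)")
        if self.n > 4**self.k:
            raise InfeasibleSpecError(f"n={self.n} exceeds 4^k for k={self.k}")


def _rand_codes(rng: np.random.Generator, m: int, k: int) -> np.ndarray:
    return rng.integers(0, 4**k, size=m, dtype=np.uint64)


def _complement_neighbors(rng: np.random.Generator, codes: np.ndarray, k: int) -> np.ndarray:
    """Replace one uniformly chosen nucleotide of each code with its complement."""
    pos = rng.integers(0, k, size=len(codes), dtype=np.uint64)
    return codes ^ (np.uint64(3) << (np.uint64(2) * pos))


def gen_all_weak(spec: SyntheticSpec) -> ExpandedArray:
    """Expanded array of exactly n entries in which every canonical k-mer
    is weak.

    Built from disjoint quadruples {x, y, rc(x), rc(y)} where y is x with
    one nucleotide complemented, so H(x, y) = 1 by construction.  Groups
    whose four codes are not distinct (palindromic or colliding cases) or
    that touch already-accepted codes are rejected and redrawn, which
    keeps the pairing property exact through deduplication and trimming.
    """
    if spec.mode != "all_weak":
        raise ValueError("spec.mode must be 'all_weak'")
    n, k = spec.n, spec.k
    if n % 4 != 0:
        raise InfeasibleSpecError(
            "all_weak targets a multiple of 4 entries (pair of k-mers, both orientations)"
        )
    rng = np.random.default_rng(spec.seed)
    accepted: set[int] = set()
    out = np.empty(n, dtype=np.uint64)
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 50:
            raise InfeasibleSpecError("could not assemble enough disjoint weak pairs")
        need = (n - filled) // 4
        xs = _rand_codes(rng, max(need + 16, int(need * 1.1)), k)
        ys = _complement_neighbors(rng, xs, k)
        rxs = rc_codes(xs, k)
        rys = rc_codes(ys, k)
        for x, y, rx, ry in zip(xs, ys, rxs, rys):
            group = {int(x), int(y), int(rx), int(ry)}
            if len(group) != 4 or not accepted.isdisjoint(group):
                continue
            accepted.update(group)
            out[filled : filled + 4] = sorted(group)
            filled += 4
            if filled >= n:
                break
    arr = ExpandedArray(k, np.sort(out) << np.uint64(1))
    arr.check_invariants()
    return arr


def gen_all_strong(spec: SyntheticSpec, oversample: float = 1.6, max_retries: int = 6) -> ExpandedArray:
    """Expanded array of exactly n entries with no weak canonical k-mer.

    An oversized random orientation-closed array is generated, its weak
    k-mers are identified and removed (strongness is monotone under
    removal, so this cannot create new weak pairs), and whole canonical
    pairs are kept until exactly n entries remain.  Retries with a larger
    oversampling factor if removal ate too much.
    """
    from .driver import mark_expanded

    if spec.mode != "all_strong":
        raise ValueError("spec.mode must be 'all_strong'")
    n, k = spec.n, spec.k
    rng = np.random.default_rng(spec.seed)
    factor = oversample
    for _ in range(max_retries):
        raw = _rand_codes(rng, int(n * factor / 2) + 8, k)
        fwd = np.unique(canonical_codes(raw, k))
        arr = ExpandedArray(k, np.unique(np.concatenate([fwd, rc_codes(fwd, k)])) << np.uint64(1))
        res = mark_expanded(arr, algorithm="fourway-pairwise")
        strong_canon = res.strong
        # keep whole canonical groups (code + rc, palindromes once)
        kept: list[int] = []
        total = 0
        rcs = rc_codes(strong_canon, k)
        for c, r in zip(strong_canon, rcs):
            size = 1 if c == r else 2
            if total + size > n:
                continue
            kept.append(int(c))
            if c != r:
                kept.append(int(r))
            total += size
            if total == n:
                break
        if total == n:
            out = ExpandedArray(k, np.sort(np.array(kept, dtype=np.uint64)) << np.uint64(1))
            out.check_invariants()
            return out
        factor *= 1.5
    raise InfeasibleSpecError("oversampling insufficient to reach n strong entries")


def gen_random(spec: SyntheticSpec) -> CanonicalKmerSet:
    """n distinct canonical codes drawn uniformly; counts are 1, or 2 with
    probability ``p_count2`` (for uniqueness-classification tests)."""
    if spec.mode != "random":
        raise ValueError("spec.mode must be 'random'")
    n, k = spec.n, spec.k
    rng = np.random.default_rng(spec.seed)
    if n == 0:
        return CanonicalKmerSet(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint8))
    codes = np.empty(0, dtype=np.uint64)
    attempts = 0
    while len(codes) < n:
        attempts += 1
        if attempts > 64:
            raise InfeasibleSpecError(f"cannot draw {n} distinct canonical {k}-mers")
        fresh = canonical_codes(_rand_codes(rng, 2 * (n - len(codes)) + 16, k), k)
        codes = np.unique(np.concatenate([codes, fresh]))
    # deterministic trim: keep a random subset of exactly n
    codes = np.sort(rng.choice(codes, size=n, replace=False))
    counts = np.where(rng.random(n) < spec.p_count2, 2, 1).astype(np.uint8)
    return CanonicalKmerSet(k, codes, counts)
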