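"""Build the sorted, orientation-closed code array from FASTA or code sets.

The marking algorithms all operate on one substrate: the *expanded array*,
a lexicographically sorted array holding every canonical k-mer of the input
set in both orientations (self-reverse-complementary k-mers once).  Each
entry is stored as ``(code << 1) | markbit`` in a uint64, so sorting stored
values orders by code and the low bit is free for the weak mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from . import codec
from ._kernels import scan_canonical_kernel

__all__ = [
    "CanonicalKmerSet",
    "ExpandedArray",
    "Interval",
    "count_canonical_kmers",
    "expand_and_sort",
    "subinterval_starts",
    "prefix_chunk_bounds",
    "chunked_expand",
    "rc_codes",
    "canonical_codes",
]

_ALPHA_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ALPHA_LUT[_c] = _i
    _ALPHA_LUT[_c + 32] = _i  # lowercase


class InvalidParameterError(ValueError):
    pass


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of an array of codes (uint64)."""
    x = codes.astype(np.uint64) ^ np.uint64((1 << (2 * k)) - 1)
    out = np.zeros_like(x)
    for _ in range(k):
        out = (out << np.uint64(2)) | (x & np.uint64(3))
        x = x >> np.uint64(2)
    return out


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized canonical code: elementwise max of code and its rc."""
    return np.maximum(codes.astype(np.uint64), rc_codes(codes, k))


class Interval(NamedTuple):
    """0-based half-open index range into an ExpandedArray."""

    start: int
    end: int

    def __len__(self) -> int:  # type: ignore[override]
        return self.end - self.start


@dataclass
class CanonicalKmerSet:
    """Distinct canonical k-mer codes with occurrence counts saturated at 2.

    Counting up to 2 suffices: uniqueness only distinguishes count 1 from
    count >= 2.
    """

    k: int
    codes: np.ndarray  # sorted distinct canonical codes, uint64
    counts: np.ndarray = field(default=None)  # uint8 in {1, 2}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        if self.counts is None:
            self.counts = np.ones(len(self.codes), dtype=np.uint8)
        self.counts = np.asarray(self.counts, dtype=np.uint8)

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class ExpandedArray:
    """Sorted orientation-closed array of stored values (code<<1 | mark)."""

    k: int
    stored: np.ndarray  # uint64

    def __post_init__(self) -> None:
        self.stored = np.asarray(self.stored, dtype=np.uint64)

    def __len__(self) -> int:
        return len(self.stored)

    def codes(self) -> np.ndarray:
        return self.stored >> np.uint64(1)

    def marks(self) -> np.ndarray:
        return (self.stored & np.uint64(1)).astype(bool)

    def clear_marks(self) -> None:
        self.stored &= ~np.uint64(1)

    def check_invariants(self) -> None:
        codes = self.codes()
        if len(codes) > 1 and not np.all(codes[1:] > codes[:-1]):
            raise ValueError("expanded array not strictly increasing")
        rcs = rc_codes(codes, self.k)
        missing = ~np.isin(rcs, codes, assume_unique=False)
        if np.any(missing):
            raise ValueError("expanded array not orientation-closed")


def sequence_to_digits(seq: str | bytes) -> np.ndarray:
    """Map a sequence to 0..3 digits; non-ACGT bases become 255 (window break)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="replace")
    return _ALPHA_LUT[np.frombuffer(seq, dtype=np.uint8)]


def _canonical_codes_of_record(seq, k: int) -> np.ndarray:
    vals = sequence_to_digits(seq)
    if len(vals) < k:
        return np.empty(0, dtype=np.uint64)
    out = np.empty(len(vals) - k + 1, dtype=np.int64)
    n = scan_canonical_kernel(vals, k, out)
    return out[:n].astype(np.uint64)


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a (possibly multi-record) FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq)


def count_canonical_kmers(fasta_path, k: int) -> CanonicalKmerSet:
    """Count canonical k-mers of every record of a FASTA file.

    Every length-k window consisting solely of A/C/G/T contributes the
    canonical code of the window; windows overlapping any other character
    are skipped.  Only one strand is scanned — canonicalization already
    folds the orientations.  Counts saturate at 2.
    """
    codec._check_k(k)
    chunks = [_canonical_codes_of_record(seq, k) for _, seq in iter_fasta(fasta_path)]
    if not chunks:
        raise IOError(f"no FASTA records found in {fasta_path}")
    return kmer_set_from_occurrences(np.concatenate(chunks), k)


def kmer_set_from_occurrences(occ_codes: np.ndarray, k: int) -> CanonicalKmerSet:
    """Collapse a (multi)set of canonical occurrence codes into a counted set."""
    if len(occ_codes) == 0:
        return CanonicalKmerSet(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint8))
    codes, counts = np.unique(np.asarray(occ_codes, dtype=np.uint64), return_counts=True)
    return CanonicalKmerSet(k, codes, np.minimum(counts, 2).astype(np.uint8))


def expand_and_sort(kset: CanonicalKmerSet) -> ExpandedArray:
    """Expand a canonical set into the sorted array of both orientations.

    Self-reverse-complementary k-mers (possible only for even k) appear
    once; all mark bits start at 0.
    """
    fwd = kset.codes.astype(np.uint64)
    rev = rc_codes(fwd, kset.k)
    allc = np.unique(np.concatenate([fwd, rev]))
    return ExpandedArray(kset.k, allc << np.uint64(1))


def subinterval_starts(arr: ExpandedArray, iv: Interval, d: int):
    """Start pointers (q_A, q_C, q_G, q_T, q_$) of the depth-d sub-intervals.

    Contract: all k-mers in iv share their first d-1 characters (not
    checked).  q_c is the first index in iv whose d-th character is >= c.
    """
    shift = np.uint64(2 * (arr.k - d) + 1)
    chars = (arr.stored[iv.start : iv.end] >> shift) & np.uint64(3)
    q = iv.start + np.searchsorted(chars, np.arange(4, dtype=np.uint64), side="left")
    return (int(q[0]), int(q[1]), int(q[2]), int(q[3]), iv.end)


def prefix_chunk_bounds(arr: ExpandedArray, g: int) -> list[Interval]:
    """Partition the array into 4**g intervals by the length-g prefix."""
    k = arr.k
    if not 0 <= g <= k // 2:
        raise InvalidParameterError(f"chunk prefix g={g} outside [0, {k // 2}]")
    if g == 0:
        return [Interval(0, len(arr))]
    edges = np.arange(4**g + 1, dtype=np.uint64) << np.uint64(2 * (k - g) + 1)
    idx = np.searchsorted(arr.stored, edges, side="left")
    return [Interval(int(idx[j]), int(idx[j + 1])) for j in range(4**g)]


def chunked_expand(kset: CanonicalKmerSet, s: int) -> Iterator[ExpandedArray]:
    """Yield the 4**s prefix-defined chunks of the expanded array.

    Chunk j holds exactly the forward and reverse-complement codes whose
    length-s prefix encodes j; concatenating the chunks in order
    reproduces ``expand_and_sort(kset)``.  s == 0 yields one full chunk.
    """
    k = kset.k
    if not 0 <= s <= k // 2:
        raise InvalidParameterError(f"input split s={s} outside [0, {k // 2}]")
    fwd = kset.codes.astype(np.uint64)
    rev = rc_codes(fwd, k)
    shift = np.uint64(2 * (k - s)) if s else None
    for j in range(4**s):
        if s == 0:
            yield expand_and_sort(kset)
            return
        jj = np.uint64(j)
        sel = np.concatenate([fwd[(fwd >> shift) == jj], rev[(rev >> shift) == jj]])
        yield ExpandedArray(k, np.unique(sel) << np.uint64(1))
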