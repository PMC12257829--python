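"""Bucketed pairwise marking (Quarter).

A k-mer is split into an ell = floor(k/2) prefix, a third quarter s1 and a
last quarter s2 (s1 is the longer one on ties, so the middle position of an
odd-length k-mer always falls into s1).  If two k-mers in the expanded
array are at canonical Hamming distance 1, at least one of the four
orientation pairings has its single difference in s1 or s2, so it suffices
to test, with the bit-parallel distance, (phase 1) all pairs sharing their
(ell+s1)-prefix — difference in s2 — and (phase 2) all pairs sharing their
ell-prefix and their s2 section.  Phase 2 is realised by swapping the s1
and s2 sections within each ell-prefix block, re-sorting the block locally,
and running the phase-1 bucket scan on the swapped codes.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from ._kernels import bucket_pairwise as _bucket_pairwise_kernel
from ._kernels import quarter_chunk
from .build import ExpandedArray

__all__ = [
    "PartitionSpec",
    "partition_lengths",
    "swap_sections",
    "bucket_pairwise_pass",
    "quarter_mark",
]


class UnsupportedKError(ValueError):
    pass


class PartitionSpec(NamedTuple):
    """Length split (ell, len_s1, len_s2) of a k-mer; ell+len_s1+len_s2 == k."""

    k: int
    ell: int
    len_s1: int
    len_s2: int


def partition_lengths(k: int) -> PartitionSpec:
    """Quarter split of k: ell = floor(k/2); the remainder is halved with
    the third quarter taking the extra position (e.g. 25 = 12 + 7 + 6)."""
    if k < 4:
        raise UnsupportedKError(f"quarter partition needs k >= 4, got {k}")
    ell = k // 2
    r = k - ell
    len_s1 = (r + 1) // 2
    len_s2 = r // 2
    return PartitionSpec(k, ell, len_s1, len_s2)


def swap_sections(code: int, spec: PartitionSpec) -> int:
    """Exchange the s1 and s2 sections of a code; the ell-prefix stays put.

    For unequal section widths the two blocks swap widths too, so the swap
    is an involution only in the even case; total length is preserved.
    """
    s1, s2 = spec.len_s1, spec.len_s2
    head = code >> (2 * (s1 + s2))
    a1 = (code >> (2 * s2)) & ((1 << (2 * s1)) - 1)
    a2 = code & ((1 << (2 * s2)) - 1)
    return (head << (2 * (s1 + s2))) | (a2 << (2 * s1)) | a1


def unswap_sections(code: int, spec: PartitionSpec) -> int:
    """Inverse of :func:`swap_sections` (sections come back at original widths)."""
    swapped = PartitionSpec(spec.k, spec.ell, spec.len_s2, spec.len_s1)
    return swap_sections(code, swapped)


def bucket_pairwise_pass(arr: ExpandedArray, prefix_len: int) -> None:
    """All-pairs hd<=1 testing within maximal runs sharing prefix_len
    characters; both members of each passing pair are marked in place."""
    view = arr.stored.view(np.int64)
    _bucket_pairwise_kernel(view, arr.k, 0, len(view), prefix_len)


def quarter_mark(arr: ExpandedArray, g: int = 0) -> None:
    """Run both Quarter phases over the expanded array.

    ``g`` distributes the work over 4**g prefix chunks; since g <=
    floor(k/2) = ell, no ell-prefix block straddles a chunk boundary and
    the result is chunking-invariant.
    """
    k = arr.k
    spec = partition_lengths(k)
    if not 0 <= g <= k // 2:
        raise ValueError(f"chunk prefix g={g} outside [0, {k // 2}]")
    view = arr.stored.view(np.int64)
    if g == 0:
        quarter_chunk(view, k, 0, len(view), spec.ell, spec.len_s1, spec.len_s2)
        return
    from .build import prefix_chunk_bounds

    for iv in prefix_chunk_bounds(arr, g):
        quarter_chunk(view, k, iv.start, iv.end, spec.ell, spec.len_s1, spec.len_s2)
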