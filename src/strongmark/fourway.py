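"""Recursive 4-way comparison marking (FourWay) and its pairwise hybrid.

The sorted expanded array is processed like a 4-way merge: at depth d all
k-mers of the current interval share their first d-1 characters, and four
cursors — one per value of the d-th character — advance together through
the interval in order of the length-(k-d) suffixes.  Whenever two or more
cursors carry the same minimal suffix, the k-mers under them differ only
at position d, i.e. form a weak group; they are marked and the cursors
advance.  The interval is then cut at the d-th character and the four
sub-intervals are processed at depth d+1.

Because the array holds both orientations of every k-mer, any pair at
canonical Hamming distance 1 is seen twice, once with the difference in
each half; processing only positions > floor(k/2) therefore suffices and
is the default.  The hybrid variant stops recursing once an interval has
at most ``tau`` elements and runs the bit-parallel all-pairs test instead;
the threshold changes speed, never output.

This module exposes a slow, inspectable pointer-state implementation of
one merge step (:func:`min_suffix_step`) alongside the compiled kernels
used for real inputs; the two are equivalence-tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import fourway_chunk
from .build import ExpandedArray, Interval, subinterval_starts

__all__ = [
    "DEFAULT_TAU",
    "PointerState",
    "MinSetVector",
    "min_suffix_step",
    "fourway_interval",
    "fourway_mark",
]

DEFAULT_TAU = 30  # interval length at which the hybrid switches to pairwise

_CHAR_BIT = {0: 1, 1: 2, 2: 4, 3: 8}  # A=1, C=2, G=4, T=8


@dataclass
class MinSetVector:
    """4-bit vector over {A:1, C:2, G:4, T:8} flagging the minimal cursors."""

    v: int

    def is_weak_group(self) -> bool:
        # population count >= 2, tested without counting
        return self.v & (self.v - 1) != 0


@dataclass
class PointerState:
    """Cursor state of one 4-way merge over an interval at depth d."""

    d: int  # 1-based position under comparison
    q: tuple  # frozen sub-interval starts (q_A, q_C, q_G, q_T, q_$)
    p: list = field(default=None)  # moving cursors per character

    def __post_init__(self) -> None:
        if self.p is None:
            self.p = list(self.q[:4])

    def active(self, c: int) -> bool:
        return self.p[c] < self.q[c + 1]

    def n_active(self) -> int:
        return sum(self.active(c) for c in range(4))

    @classmethod
    def at_interval(cls, arr: ExpandedArray, iv: Interval, d: int) -> "PointerState":
        return cls(d=d, q=subinterval_starts(arr, iv, d))


def min_suffix_step(arr: ExpandedArray, state: PointerState) -> MinSetVector:
    """One merge step: find the minimal-suffix cursors, mark ties, advance.

    Requires at least two active cursors (the caller's loop guard).
    Returns the min-set vector; marking and cursor advancement happen in
    place on ``arr`` and ``state``.
    """
    k = arr.k
    b = k - state.d
    suffmask = np.uint64((1 << (2 * b)) - 1)
    v = 0
    best = None
    for c in range(4):
        if state.active(c):
            s = int((arr.stored[state.p[c]] >> np.uint64(1)) & suffmask)
            if best is None or s < best:
                best = s
                v = _CHAR_BIT[c]
            elif s == best:
                v |= _CHAR_BIT[c]
    vec = MinSetVector(v)
    if vec.is_weak_group():
        # a 2-group of an entry and its own rc is one canonical k-mer,
        # not a weak pair; skip marking in that case only
        members = [state.p[c] for c in range(4) if v & _CHAR_BIT[c]]
        skip = False
        if len(members) == 2:
            from . import codec

            x1 = int(arr.stored[members[0]] >> np.uint64(1))
            x2 = int(arr.stored[members[1]] >> np.uint64(1))
            skip = x2 == codec.rc_code(x1, k)
        if not skip:
            for i in members:
                arr.stored[i] |= np.uint64(1)
    for c in range(4):
        if v & _CHAR_BIT[c]:
            state.p[c] += 1
    return vec


def fourway_interval(arr: ExpandedArray, iv: Interval, d: int, tau: int = DEFAULT_TAU) -> None:
    """Mark weak k-mers of ``iv`` whose single difference lies at position >= d.

    Contract: all k-mers in iv share their first d-1 characters.  With
    tau > 1, intervals of at most tau elements are finished by the
    all-pairs bit-parallel test instead of deeper recursion.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    view = arr.stored.view(np.int64)
    fourway_chunk(view, arr.k, iv.start, iv.end, tau, d)


def fourway_mark(
    arr: ExpandedArray,
    tau: int = DEFAULT_TAU,
    g: int = 0,
    second_half_only: bool = True,
) -> None:
    """Run FourWay (hybrid for tau > 1) over the whole expanded array.

    By default the array is cut into maximal blocks sharing their
    length-floor(k/2) prefix and each block is processed from depth
    floor(k/2)+1, covering exactly the second-half positions; first-half
    differences are caught through the reverse-complement pair and unified
    by orientation propagation.  ``second_half_only=False`` recurses from
    depth 1 instead (slower; used to validate the coverage argument).
    ``g`` partitions the work into 4**g prefix chunks; it never changes
    the result because blocks cannot straddle chunk boundaries (g <=
    floor(k/2)).
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    k = arr.k
    if not 0 <= g <= k // 2:
        raise ValueError(f"chunk prefix g={g} outside [0, {k // 2}]")
    start_depth = (k // 2) + 1 if second_half_only else 1
    view = arr.stored.view(np.int64)
    if g == 0 or not second_half_only:
        fourway_chunk(view, k, 0, len(view), tau, start_depth)
        return
    from .build import prefix_chunk_bounds

    for iv in prefix_chunk_bounds(arr, g):
        fourway_chunk(view, k, iv.start, iv.end, tau, start_depth)
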