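"""Numba kernels for the marking algorithms and the oracles.

All kernels operate on ``int64`` views of the public ``uint64`` arrays:
every quantity handled here fits in 63 bits (a stored entry is
``code << 1 | markbit`` with ``code < 4**31``), and signed arithmetic
avoids numpy's uint64/int64 promotion pitfalls inside compiled code.

Stored-array convention (see :class:`strongmark.build.ExpandedArray`):
bit 0 is the weak-mark bit, bits 1..2k+1 are the k-mer code, so ordering
by stored value equals ordering by code, and character/suffix extraction
always shifts the mark bit away first.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "fourway_chunk",
    "quarter_chunk",
    "bucket_pairwise",
    "pairwise_range",
    "pairwise_oracle_kernel",
    "neighborhood_oracle_kernel",
    "scan_canonical_kernel",
    "block_counts_kernel",
    "rc_kernel",
]


@njit(cache=True, nogil=True)
def rc_kernel(code, k):
    """Reverse-complement of a 2k-bit code (scalar, int64)."""
    comp = code ^ ((1 << (2 * k)) - 1)
    out = 0
    for _ in range(k):
        out = (out << 2) | (comp & 3)
        comp >>= 2
    return out


@njit(cache=True, nogil=True)
def pairwise_range(stored, k, lo, hi, low):
    """All-pairs hd<=1 test on stored[lo:hi]; marks both members of a hit.

    ``low`` is the 0101..01 mask over 2k bits.  Entries share enough of a
    prefix when this is called that the plain (non-canonical) test is the
    right one.  A hit between an entry and its own reverse complement is
    ignored: both orientations denote the same canonical k-mer, which is
    weak only through a *distinct* partner.
    """
    for i in range(lo, hi - 1):
        ci = stored[i] >> 1
        for j in range(i + 1, hi):
            cj = stored[j] >> 1
            u = ci ^ cj
            h = (u | (u >> 1)) & low
            if h & (h - 1) == 0 and cj != rc_kernel(ci, k):
                stored[i] |= 1
                stored[j] |= 1


@njit(cache=True, nogil=True)
def _fourway_region(stored, k, lo0, hi0, d0, tau, low, st_lo, st_hi, st_d, b, p):
    """Iterative 4-way recursion over [lo0, hi0) starting at depth d0.

    Depth d is 1-based: entries in a frame share their first d-1
    characters; the d-th character splits the interval into the four
    sub-intervals whose cursors are merged.  Frames of length <= tau
    (tau > 1) fall back to the all-pairs bit-parallel test.  The scratch
    arrays (stack and pointer buffers) are caller-owned so that the many
    tiny per-block invocations allocate nothing.
    """
    top = 0
    st_lo[top] = lo0
    st_hi[top] = hi0
    st_d[top] = d0
    top += 1
    while top > 0:
        top -= 1
        lo = st_lo[top]
        hi = st_hi[top]
        d = st_d[top]
        if hi - lo <= 1:
            continue
        if tau > 1 and hi - lo <= tau:
            pairwise_range(stored, k, lo, hi, low)
            continue
        shift = 2 * (k - d) + 1
        # sub-interval starts: b[c] = first index whose d-th char >= c
        b[0] = lo
        i = lo
        for c in range(3):
            while i < hi and ((stored[i] >> shift) & 3) <= c:
                i += 1
            b[c + 1] = i
        b[4] = hi
        bsuf = k - d
        suffmask = (1 << (2 * bsuf)) - 1
        nact = 0
        for c in range(4):
            p[c] = b[c]
            if b[c + 1] - b[c] > 0:
                nact += 1
        while nact >= 2:
            v = 0
            best = 0
            for c in range(4):
                if p[c] < b[c + 1]:
                    s = (stored[p[c]] >> 1) & suffmask
                    if v == 0 or s < best:
                        best = s
                        v = 1 << c
                    elif s == best:
                        v |= 1 << c
            if v & (v - 1) != 0:
                # >= 2 equal minimal suffixes: k-mers differing only at
                # position d.  A 2-group made of an entry and its own rc
                # is the same canonical k-mer, not a weak pair; any group
                # of >= 3 gives every member a distinct partner.
                nbits = 0
                for c in range(4):
                    if v & (1 << c):
                        nbits += 1
                skip = False
                if nbits == 2:
                    c1 = -1
                    c2 = -1
                    for c in range(4):
                        if v & (1 << c):
                            if c1 < 0:
                                c1 = c
                            else:
                                c2 = c
                    x1 = stored[p[c1]] >> 1
                    x2 = stored[p[c2]] >> 1
                    skip = x2 == rc_kernel(x1, k)
                if not skip:
                    for c in range(4):
                        if v & (1 << c):
                            stored[p[c]] |= 1
            for c in range(4):
                if v & (1 << c):
                    p[c] += 1
                    if p[c] >= b[c + 1]:
                        nact -= 1
        if d < k:
            for c in range(4):
                if b[c + 1] - b[c] > 1:
                    st_lo[top] = b[c]
                    st_hi[top] = b[c + 1]
                    st_d[top] = d + 1
                    top += 1


@njit(cache=True, nogil=True)
def fourway_chunk(stored, k, lo, hi, tau, start_depth):
    """FourWay over stored[lo:hi].

    With start_depth > 1, the range is first cut into maximal blocks
    sharing their first (start_depth - 1) characters by one linear scan;
    each block is processed from start_depth on.  start_depth == 1 runs
    the full recursion over every position.
    """
    low = (1 << (2 * k)) // 3  # 0101..01 over 2k bits
    if hi - lo <= 1:
        return
    cap = 4 * (k + 2) + 8
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    st_d = np.empty(cap, np.int64)
    b = np.empty(5, np.int64)
    p = np.empty(4, np.int64)
    if start_depth <= 1:
        _fourway_region(stored, k, lo, hi, 1, tau, low, st_lo, st_hi, st_d, b, p)
        return
    pshift = 2 * (k - (start_depth - 1)) + 1
    i = lo
    while i < hi:
        pref = stored[i] >> pshift
        j = i + 1
        while j < hi and (stored[j] >> pshift) == pref:
            j += 1
        if j - i > 1:
            if tau > 1 and j - i <= tau:
                pairwise_range(stored, k, i, j, low)
            else:
                _fourway_region(stored, k, i, j, start_depth, tau, low, st_lo, st_hi, st_d, b, p)
        i = j


@njit(cache=True, nogil=True)
def bucket_pairwise(stored, k, lo, hi, prefix_len):
    """One scan into maximal runs sharing prefix_len characters; all-pairs
    hd<=1 inside each run."""
    low = (1 << (2 * k)) // 3
    pshift = 2 * (k - prefix_len) + 1
    i = lo
    while i < hi:
        pref = stored[i] >> pshift
        j = i + 1
        while j < hi and (stored[j] >> pshift) == pref:
            j += 1
        if j - i > 1:
            pairwise_range(stored, k, i, j, low)
        i = j


@njit(cache=True, nogil=True)
def _swap_code(code, s1, s2):
    """Exchange the s1 (third-quarter) and s2 (last-quarter) sections."""
    head = code >> (2 * (s1 + s2))
    a1 = (code >> (2 * s2)) & ((1 << (2 * s1)) - 1)
    a2 = code & ((1 << (2 * s2)) - 1)
    return (head << (2 * (s1 + s2))) | (a2 << (2 * s1)) | a1


@njit(cache=True, nogil=True)
def _quarter_block(stored, k, a, bnd, ell, s1, s2, low):
    """Phase 2 on one ell-prefix block: swap s1/s2 on a scratch copy,
    sort it, bucket by the (ell+s2)-prefix, all-pairs test, map marks
    back through the carried original indices."""
    m = bnd - a
    sw = np.empty(m, np.int64)
    for t in range(m):
        sw[t] = _swap_code(stored[a + t] >> 1, s1, s2)
    order = np.argsort(sw)
    sws = sw[order]
    pshift = 2 * (k - (ell + s2))
    i = 0
    while i < m:
        pref = sws[i] >> pshift
        j = i + 1
        while j < m and (sws[j] >> pshift) == pref:
            j += 1
        for t1 in range(i, j - 1):
            for t2 in range(t1 + 1, j):
                u = sws[t1] ^ sws[t2]
                h = (u | (u >> 1)) & low
                if h & (h - 1) == 0:
                    # rc-pair guard on the *original* codes
                    x1 = stored[a + order[t1]] >> 1
                    x2 = stored[a + order[t2]] >> 1
                    if x2 != rc_kernel(x1, k):
                        stored[a + order[t1]] |= 1
                        stored[a + order[t2]] |= 1
        i = j


@njit(cache=True, nogil=True)
def quarter_chunk(stored, k, lo, hi, ell, s1, s2):
    """Quarter algorithm over stored[lo:hi].

    Phase 1 catches single differences in the last quarter s2 (shared
    ell+s1 prefix); phase 2 swaps s1/s2 within each ell-prefix block and
    repeats, catching differences in the third quarter s1.  First-half
    differences are covered by the reverse-complement pair.
    """
    low = (1 << (2 * k)) // 3
    if hi - lo <= 1:
        return
    bucket_pairwise(stored, k, lo, hi, ell + s1)
    pshift = 2 * (k - ell) + 1
    i = lo
    while i < hi:
        pref = stored[i] >> pshift
        j = i + 1
        while j < hi and (stored[j] >> pshift) == pref:
            j += 1
        if j - i > 1:
            _quarter_block(stored, k, i, j, ell, s1, s2, low)
        i = j


@njit(cache=True, nogil=True)
def pairwise_oracle_kernel(codes, rcs, k):
    """Naive full pairwise canonical-hd<=1 marking on canonical codes.

    Returns (weak flags, number of pair tests executed).
    """
    n = codes.shape[0]
    low = (1 << (2 * k)) // 3
    weak = np.zeros(n, np.uint8)
    tests = 0
    for i in range(n - 1):
        ci = codes[i]
        for j in range(i + 1, n):
            tests += 1
            u = ci ^ codes[j]
            h = (u | (u >> 1)) & low
            hit = h & (h - 1) == 0
            if not hit:
                u = ci ^ rcs[j]
                h = (u | (u >> 1)) & low
                hit = h & (h - 1) == 0
            if hit:
                weak[i] = 1
                weak[j] = 1
    return weak, tests


@njit(cache=True, nogil=True)
def neighborhood_oracle_kernel(codes, k, early_exit):
    """Generate the 3k substitution neighbors of each code, canonicalize,
    and binary-search the sorted code array; hits mark both partners."""
    n = codes.shape[0]
    weak = np.zeros(n, np.uint8)
    for i in range(n):
        if early_exit and weak[i]:
            continue
        x = codes[i]
        done = False
        for pos in range(k):
            sh = 2 * pos
            cur = (x >> sh) & 3
            cleared = x & ~(3 << sh)
            for bb in range(4):
                if bb == cur:
                    continue
                y = cleared | (bb << sh)
                ry = rc_kernel(y, k)
                ycc = y if y >= ry else ry
                if ycc == x:
                    continue  # neighbor is x's own rc, not a distinct member
                j = np.searchsorted(codes, ycc)
                if j < n and codes[j] == ycc:
                    weak[i] = 1
                    weak[j] = 1
                    if early_exit:
                        done = True
                        break
            if done:
                break
    return weak


@njit(cache=True, nogil=True)
def scan_canonical_kernel(vals, k, out):
    """Rolling scan over a 0..3 (valid) / >3 (break) byte array; appends
    the canonical code of every fully valid window to out.  Returns the
    number of codes written."""
    n = 0
    code = 0
    rc = 0
    run = 0
    mask = (1 << (2 * k)) - 1
    hsh = 2 * (k - 1)
    for idx in range(vals.shape[0]):
        v = vals[idx]
        if v > 3:
            run = 0
            code = 0
            rc = 0
            continue
        code = ((code << 2) | v) & mask
        rc = (rc >> 2) | ((3 - v) << hsh)
        run += 1
        if run >= k:
            out[n] = code if code >= rc else rc
            n += 1
    return n


@njit(cache=True, nogil=True)
def block_counts_kernel(vals, k, codes, labels, block_size, counts, nvalid):
    """Per-block class counts of k-mer start positions.

    counts is (nblocks, 3); nvalid is (nblocks,).  Returns -1 if an
    encountered canonical code is missing from the classification.
    """
    code = 0
    rc = 0
    run = 0
    mask = (1 << (2 * k)) - 1
    hsh = 2 * (k - 1)
    n = codes.shape[0]
    for idx in range(vals.shape[0]):
        v = vals[idx]
        if v > 3:
            run = 0
            code = 0
            rc = 0
            continue
        code = ((code << 2) | v) & mask
        rc = (rc >> 2) | ((3 - v) << hsh)
        run += 1
        if run >= k:
            c = code if code >= rc else rc
            j = np.searchsorted(codes, c)
            if j >= n or codes[j] != c:
                return -1
            start = idx - k + 1
            blk = start // block_size
            counts[blk, labels[j]] += 1
            nvalid[blk] += 1
    return 0
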