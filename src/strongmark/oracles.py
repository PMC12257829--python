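"""Naive baseline algorithms: ground truth for the fast marking methods.

Both enumerate the weak set of a canonical k-mer set directly from the
definition — a member is weak iff another member sits at canonical Hamming
distance exactly 1 — by two independent routes (all pairs, and 3k-neighbor
generation with lookup), so they double as a consistency check on each
other.  Quadratic or 3k-factor cost makes them oracles and small-scale
baselines, not production paths.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._kernels import neighborhood_oracle_kernel, pairwise_oracle_kernel
from .build import CanonicalKmerSet, rc_codes

__all__ = ["full_pairwise_mark", "neighborhood_mark"]

_QUADRATIC_GUARD = 10**5


def full_pairwise_mark(kset: CanonicalKmerSet, return_stats: bool = False):
    """Weak set by testing all n(n-1)/2 unordered pairs with H(x,y) <= 1.

    Distinct canonical codes have H >= 1, so the bit-parallel <=1 test is
    exact here.  With ``return_stats`` the number of executed pair tests
    is returned alongside the sorted weak code array.
    """
    n = len(kset)
    if n > _QUADRATIC_GUARD:
        warnings.warn(f"full pairwise marking is quadratic; n={n} will be slow")
    codes = np.ascontiguousarray(kset.codes, dtype=np.uint64)
    rcs = rc_codes(codes, kset.k)
    weak, tests = pairwise_oracle_kernel(
        codes.view(np.int64), rcs.view(np.int64), kset.k
    )
    weak_codes = codes[weak.astype(bool)]
    if return_stats:
        return weak_codes, int(tests)
    return weak_codes


def neighborhood_mark(kset: CanonicalKmerSet, early_exit: bool = False) -> np.ndarray:
    """Weak set by generating each member's 3k substitution neighbors,
    canonicalizing them, and looking them up in the sorted code array.

    Canonicalizing generated neighbors is essential: a substituted k-mer
    may be stored under its reverse complement.  A neighbor that
    canonicalizes onto the query itself (the query is one substitution
    away from its own rc) is not a distinct member and is ignored.
    ``early_exit`` skips already-marked members and stops at the first hit
    (baseline-benchmark mode); the resulting weak set is identical either
    way because hits always mark both partners.
    """
    codes = np.ascontiguousarray(kset.codes, dtype=np.uint64)
    weak = neighborhood_oracle_kernel(codes.view(np.int64), kset.k, early_exit)
    return codes[weak.astype(bool)]
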