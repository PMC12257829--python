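"""Integer encoding of DNA k-mers and bit-parallel Hamming distance tests.

A k-mer over {A, C, G, T} is stored as a base-4 integer with the
lexicographic digit map A=0, C=1, G=2, T=3 and the *first* character as the
most significant digit, e.g. ``encode("TACG") == (3012)_4 == 198``.
Equivalently the code is a 2k-bit pattern with two bits per nucleotide,
which is what makes the bit-parallel distance tests below work.

Because a DNA k-mer and its reverse complement denote the same
double-stranded molecule, both are represented by a single *canonical*
code, defined here as the maximum of the two encodings.  The canonical
Hamming distance between two k-mers is the minimum over the two relative
orientations: ``H(x, y) = min(d(x, y), d(x, rc(y)))``.

All functions in this module are plain-Python scalar operations; the array
kernels used by the marking algorithms live in :mod:`strongmark._kernels`.
The scalar and kernel routes are checked against each other (and against a
character-level oracle) in the test suite.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "MIN_K",
    "MAX_K",
    "KmerCode",
    "encode",
    "decode",
    "rc_code",
    "canonical_code",
    "hamming",
    "hd_at_most_1",
    "canonical_hamming",
]

MIN_K = 2
MAX_K = 31

_BASES = "ACGT"
_BASE_TO_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}

# per-nucleotide low-bit mask 0b0101...01 over 2k bits, built on demand
_LOW_BITS = {k: int("01" * k, 2) for k in range(MIN_K, MAX_K + 1)}


class KmerCode(NamedTuple):
    """A k-mer code together with its length.

    ``k`` is always carried explicitly; it is never inferred from the value
    (leading-A k-mers have small values).
    """

    value: int
    k: int


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside A, C, G, T."""


class InvalidKError(ValueError):
    """k outside the supported range [2, 31]."""


class InvalidCodeError(ValueError):
    """Integer code out of range for the stated k."""


class IncompatibleLengthError(ValueError):
    """Two codes with different k cannot be compared."""


def _check_k(k: int) -> None:
    if not MIN_K <= k <= MAX_K:
        raise InvalidKError(f"k must be in [{MIN_K}, {MAX_K}], got {k}")


def _check_code(code: int, k: int) -> None:
    _check_k(k)
    if not 0 <= code < 4**k:
        raise InvalidCodeError(f"code {code} out of range for k={k}")


def encode(seq: str) -> int:
    """Encode a DNA string of length k as its base-4 integer code."""
    _check_k(len(seq))
    value = 0
    for ch in seq.upper():
        try:
            value = (value << 2) | _BASE_TO_DIGIT[ch]
        except KeyError:
            raise InvalidAlphabetError(f"invalid nucleotide {ch!r}") from None
    return value


def decode(code: int, k: int) -> str:
    """Inverse of :func:`encode`: the DNA string for ``code`` at length ``k``."""
    _check_code(code, k)
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def rc_code(code: int, k: int) -> int:
    """Code of the reverse complement, computed entirely on the integer.

    Complementation is a XOR with all-ones over 2k bits (A<->T, C<->G swap
    both bits of a nucleotide); reversal walks the k two-bit groups.
    """
    _check_code(code, k)
    comp = code ^ ((1 << (2 * k)) - 1)
    out = 0
    for _ in range(k):
        out = (out << 2) | (comp & 3)
        comp >>= 2
    return out


def canonical_code(code: int, k: int) -> int:
    """Canonical code ``cc(x) = max(enc(x), enc(rc(x)))``.

    Orientation-invariant and idempotent: ``cc(x) == cc(rc(x))`` and
    ``cc(cc(x)) == cc(x)``.
    """
    return max(code, rc_code(code, k))


def _resolve_pair(p, q, k):
    """Accept plain ints with explicit k, or KmerCode pairs (k checked)."""
    if isinstance(p, KmerCode) or isinstance(q, KmerCode):
        pk = p.k if isinstance(p, KmerCode) else k
        qk = q.k if isinstance(q, KmerCode) else k
        if pk != qk or (k is not None and k not in (pk, qk)):
            raise IncompatibleLengthError(f"k mismatch: {pk} vs {qk}")
        return int(p[0]) if isinstance(p, KmerCode) else p, (
            int(q[0]) if isinstance(q, KmerCode) else q
        ), pk
    if k is None:
        raise InvalidKError("k must be given for plain integer codes")
    return p, q, k


def hamming(p: int, q: int, k: int | None = None) -> int:
    """Hamming distance between two k-mer codes, bit-parallel.

    ``u = p ^ q`` flags differing bits; ``h = (u | (u >> 1)) & 0101..01``
    collapses each nucleotide's two bits onto its low bit, so popcount(h)
    is the number of differing positions.
    """
    p, q, k = _resolve_pair(p, q, k)
    _check_code(p, k)
    _check_code(q, k)
    u = p ^ q
    h = (u | (u >> 1)) & _LOW_BITS[k]
    return h.bit_count()


def hd_at_most_1(p: int, q: int, k: int | None = None) -> bool:
    """True iff ``hamming(p, q) <= 1``, without a population count.

    ``h & (h - 1)`` clears the lowest set bit; it is zero exactly when h
    has at most one bit set, i.e. at most one position differs.
    """
    p, q, k = _resolve_pair(p, q, k)
    _check_code(p, k)
    _check_code(q, k)
    u = p ^ q
    h = (u | (u >> 1)) & _LOW_BITS[k]
    return h & (h - 1) == 0


def canonical_hamming(x: int, y: int, k: int | None = None) -> int:
    """Canonical Hamming distance ``H(x, y) = min(d(x, y), d(x, rc(y)))``."""
    x, y, k = _resolve_pair(x, y, k)
    return min(hamming(x, y, k), hamming(x, rc_code(y, k), k))
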