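"""Shared fixtures and independent string-level oracles.

The string oracles here deliberately avoid the package's integer codec:
reverse complement via str.translate, Hamming distance by character
comparison, weak sets by brute force over decoded strings.  They are the
ground truth the bit-level implementations are checked against.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import strongmark as sm
from strongmark.build import kmer_set_from_occurrences
from strongmark.synthetic import SyntheticSpec, gen_random

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_COMP = str.maketrans("ACGT", "TGCA")


def str_rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def str_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def str_canonical(s: str) -> str:
    """Canonical orientation by base-4 value, i.e. plain lexicographic max."""
    return max(s, str_rc(s))


def str_canonical_hamming(a: str, b: str) -> int:
    return min(str_hamming(a, b), str_hamming(a, str_rc(b)))


def str_weak_set(kmers: list[str]) -> set[str]:
    """Brute-force weak set of a canonical k-mer list, on strings."""
    weak = set()
    for a, b in itertools.combinations(kmers, 2):
        if str_canonical_hamming(a, b) == 1:
            weak.add(a)
            weak.add(b)
    return weak


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_kset():
    """Factory for seeded random canonical k-mer sets."""

    def make(n: int, k: int, seed: int = 0, p_count2: float = 0.0) -> sm.CanonicalKmerSet:
        n = min(n, max(1, 4**k // 4))
        return gen_random(SyntheticSpec(n=n, k=k, seed=seed, mode="random", p_count2=p_count2))

    return make


@pytest.fixture
def kset_from_strings():
    """Canonical k-mer set from explicit k-mer strings (occurrences)."""

    def make(kmers: list[str]) -> sm.CanonicalKmerSet:
        k = len(kmers[0])
        occ = np.array([sm.encode(str_canonical(s)) for s in kmers], dtype=np.uint64)
        return kmer_set_from_occurrences(occ, k)

    return make


@pytest.fixture
def write_fasta(tmp_path):
    def make(records: dict[str, str], name: str = "input.fa", wrap: int = 0):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n")
                if wrap:
                    for i in range(0, len(seq), wrap):
                        fh.write(seq[i : i + wrap] + "\n")
                else:
                    fh.write(seq + "\n")
        return path

    return make
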